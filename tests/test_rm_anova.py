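import numpy as np
import pytest

from zsens import (
    greenhouse_geisser_epsilon,
    pool_and_standardize,
    rm_anova_oneway,
    rm_anova_twoway_within,
    to_cube,
)
from zsens.exceptions import DesignError

from _oracles import gg_epsilon_oracle, oneway_anova_oracle, twoway_anova_oracle


class TestOneWay:
    def test_constant_rows_have_no_level_effect(self):
        y = np.array([[1.0, 1.0, 1.0], [4.0, 4.0, 4.0], [-2.0, -2.0, -2.0]])
        res = rm_anova_oneway(y)
        assert res.ss_effect == pytest.approx(0.0, abs=1e-12)
        assert res.F == 0.0
        assert res.p_uncorrected == 1.0

    def test_small_fixture_matches_brute_force_oracle(self):
        y = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 5.0], [0.0, 1.0, 2.0]])
        res = rm_anova_oneway(y)
        oracle = oneway_anova_oracle(y)
        assert res.F == pytest.approx(oracle["F"], rel=1e-10)
        assert res.p_uncorrected == pytest.approx(oracle["p"], abs=1e-10)
        assert (res.df_effect, res.df_error) == oracle["df"]
        assert res.ss_error == pytest.approx(oracle["ss_error"], rel=1e-10)

    def test_two_levels_have_unit_epsilon(self, rng):
        y = rng.normal(size=(6, 2))
        res = rm_anova_oneway(y)
        assert res.epsilon_gg == 1.0
        assert res.df_effect_gg == res.df_effect

    def test_ss_decomposition_conserved(self, rng):
        from conftest import random_matrix

        for _ in range(20):
            y = random_matrix(rng)
            res = rm_anova_oneway(y)
            oracle = oneway_anova_oracle(y)
            total = oracle["ss_subjects"] + res.ss_effect + res.ss_error
            assert total == pytest.approx(oracle["ss_total"], rel=1e-9)

    def test_gg_correction_conservative_for_clearly_nonnull_f(self, rng):
        # shrinking both df raises the p-value once F is clearly above 1
        # (near F ~ 1 the two tail probabilities can cross, so the guarantee
        # is asserted for F >= 2)
        from conftest import random_matrix

        seen = 0
        for _ in range(200):
            y = random_matrix(rng)
            res = rm_anova_oneway(y)
            assert res.epsilon_gg <= 1.0
            if res.F >= 2.0:
                seen += 1
                assert res.p_gg >= res.p_uncorrected - 1e-12
        assert seen > 0

    def test_degenerate_zero_error_flagged(self):
        # every subject identical: level effect present, zero error variance
        y = np.tile([1.0, 2.0, 4.0], (4, 1))
        res = rm_anova_oneway(y)
        assert res.degenerate
        assert np.isinf(res.F)
        assert res.p_uncorrected == 0.0

    @pytest.mark.parametrize("shape", [(1, 4), (5, 1)])
    def test_undersized_design_rejected(self, shape):
        with pytest.raises(DesignError):
            rm_anova_oneway(np.zeros(shape))


class TestGreenhouseGeisser:
    def test_compound_symmetry_gives_one(self):
        k = 5
        cov = np.full((k, k), 0.6) + np.eye(k) * 0.4
        assert greenhouse_geisser_epsilon(cov) == pytest.approx(1.0)

    def test_two_levels_give_one(self, rng):
        a = rng.normal(size=(10, 2))
        assert greenhouse_geisser_epsilon(np.cov(a, rowvar=False)) == pytest.approx(1.0)

    def test_random_covariances_match_contrast_basis_oracle(self, rng):
        for k in (3, 4, 5, 6):
            for _ in range(10):
                a = rng.normal(size=(k + 5, k)) @ np.diag(rng.uniform(0.5, 3.0, k))
                cov = np.cov(a, rowvar=False)
                assert greenhouse_geisser_epsilon(cov) == pytest.approx(
                    gg_epsilon_oracle(cov), abs=1e-10
                )

    def test_epsilon_bounded_below(self, rng):
        # a nearly rank-1 covariance drives epsilon towards its floor 1/(k-1)
        v = rng.normal(size=(4, 1))
        cov = v @ v.T + 1e-8 * np.eye(4)
        eps = greenhouse_geisser_epsilon(cov)
        assert 1.0 / 3 <= eps <= 1.0
        assert eps == pytest.approx(1.0 / 3, abs=1e-3)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(DesignError):
            greenhouse_geisser_epsilon(np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(DesignError):
            greenhouse_geisser_epsilon(np.ones((2, 3)))


class TestTwoWay:
    def test_zscored_input_forces_null_measure_effect(self, paperlike):
        z, _ = pool_and_standardize(paperlike)
        res = rm_anova_twoway_within(to_cube(z))
        assert res.measure.ss_effect <= 1e-10 * res.ss_total
        assert res.measure.F == pytest.approx(0.0, abs=1e-6)
        assert res.measure.p_uncorrected == pytest.approx(1.0, abs=1e-6)

    def test_identical_measures_collapse_to_oneway(self, rng):
        mat = rng.normal(size=(6, 4)) + rng.normal(size=(6, 1))
        cube = np.stack([mat, mat, mat], axis=-1)
        res = rm_anova_twoway_within(cube)
        one = rm_anova_oneway(mat)
        assert res.measure.ss_effect == pytest.approx(0.0, abs=1e-10)
        assert res.interaction.ss_effect == pytest.approx(0.0, abs=1e-10)
        assert res.time.F == pytest.approx(one.F, rel=1e-9)  # both SSs scale by m
        assert res.time.p_uncorrected == pytest.approx(one.p_uncorrected, abs=1e-9)

    def test_small_cube_matches_brute_force_oracle(self, rng):
        cube = rng.normal(size=(4, 3, 2)) + rng.normal(size=(4, 1, 1))
        res = rm_anova_twoway_within(cube)
        oracle = twoway_anova_oracle(cube)
        for mine, name in ((res.time, "time"), (res.measure, "measure"),
                           (res.interaction, "interaction")):
            assert mine.F == pytest.approx(oracle[name]["F"], rel=1e-9)
            assert mine.p_uncorrected == pytest.approx(oracle[name]["p"], abs=1e-9)

    def test_ss_conservation(self, rng):
        cube = rng.normal(size=(7, 4, 3))
        res = rm_anova_twoway_within(cube)
        oracle = twoway_anova_oracle(cube)
        parts = (
            res.ss_subjects
            + res.time.ss_effect + res.time.ss_error
            + res.measure.ss_effect + res.measure.ss_error
            + res.interaction.ss_effect + res.interaction.ss_error
        )
        assert parts == pytest.approx(oracle["ss_total"], rel=1e-9)
        assert res.ss_total == pytest.approx(oracle["ss_total"], rel=1e-9)

    def test_missing_cells_rejected(self):
        cube = np.zeros((3, 2, 2))
        cube[0, 0, 0] = np.nan
        with pytest.raises(DesignError):
            rm_anova_twoway_within(cube)


class TestReferenceImplementation:
    """Cross-check against pingouin, an established RM-ANOVA implementation."""

    def test_oneway_agrees_with_pingouin_on_random_fixtures(self, rng):
        import pandas as pd
        import pingouin as pg

        from conftest import random_matrix

        for _ in range(25):
            y = random_matrix(rng)
            n, k = y.shape
            long = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(n), k),
                    "session": np.tile(np.arange(k), n),
                    "value": y.ravel(),
                }
            )
            ref = pg.rm_anova(
                data=long, dv="value", within="session", subject="subject",
                correction=True,
            )
            res = rm_anova_oneway(y)
            assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
            assert res.p_uncorrected == pytest.approx(
                float(ref["p_unc"].iloc[0]), abs=1e-8
            )
            assert res.epsilon_gg == pytest.approx(float(ref["eps"].iloc[0]), abs=1e-8)
            assert res.p_gg == pytest.approx(float(ref["p_GG_corr"].iloc[0]), abs=1e-8)
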