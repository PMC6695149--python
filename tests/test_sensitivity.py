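import numpy as np
import pandas as pd
import pytest

from zsens import (
    from_cube,
    lsd_pairwise,
    magnitude_of_change,
    pool_and_standardize,
    rank_measures,
    rm_anova_oneway,
    summarize_sensitivity,
    to_wide,
    trend_tests,
)
from zsens.exceptions import ConsistencyError, DesignError
from zsens.sensitivity import SensitivitySummary, sensitivity_table


def _followup(z, alpha=0.05):
    oneway, trends, pairwise = {}, {}, {}
    for m in z.measures:
        wide = to_wide(z, m)
        oneway[m] = rm_anova_oneway(wide)
        trends[m] = trend_tests(wide, alpha=alpha, measure=m, max_degree=3)
        pairwise[m] = lsd_pairwise(wide, alpha=alpha, measure=m)
    return oneway, trends, pairwise


def _summary(measure="x", oneway_p=0.5, sig=False, trend_p=None, pair_p=None, dz=None):
    trend_p = trend_p if trend_p is not None else {"linear": 0.5}
    pair_p = pair_p if pair_p is not None else {(1, 2): 0.5}
    dz = dz if dz is not None else {(1, 2): 0.0}
    return SensitivitySummary(
        measure=measure,
        oneway_p=oneway_p,
        oneway_significant=sig,
        trend_p=trend_p,
        pairwise_p=pair_p,
        n_sig_contrasts=sum(p < 0.05 for p in trend_p.values()),
        n_sig_pairwise=sum(p < 0.05 for p in pair_p.values()),
        delta_z=dz,
    )


class TestMagnitudeOfChange:
    def test_reads_off_session_mean_difference(self, rng):
        # measure 1: means 0 then 0.6; measure 2: identical sessions
        n = 6
        cube = np.zeros((n, 2, 2))
        cube[:, 1, 0] = 0.6
        cube[:, :, 1] = 1.0
        data = from_cube(cube, measures=["shift", "flat"])
        dz = magnitude_of_change(data, 1, 2)
        assert dz["shift"] == pytest.approx(0.6)
        assert dz["flat"] == 0.0

    def test_invalid_session_raises_key_error(self, tiny_study):
        with pytest.raises(KeyError):
            magnitude_of_change(tiny_study, 1, 9)

    def test_recovers_injected_effect_at_large_n(self):
        from zsens import MeasureProfile, SimulationConfig, generate_study

        d = 0.6
        config = SimulationConfig(
            n_subjects=4000,
            n_sessions=4,
            profiles=(
                MeasureProfile("m", 0.0, 1.0, (0.0, d, d, d / 4)),
            ),
            seed=11,
        )
        z, _ = pool_and_standardize(generate_study(config))
        dz = magnitude_of_change(z, 1, 2)["m"]
        # z-scoring shrinks the native-scale shift by the pooled SD (>1 when
        # effects are present), so compare against the standardized truth
        raw = generate_study(config)
        vals = raw.frame["value"].to_numpy()
        expected = d / vals.std(ddof=1)
        assert dz == pytest.approx(expected, abs=4 / np.sqrt(4000))


class TestSummarize:
    def test_counts_and_bounds_on_pipeline_output(self, paperlike):
        z, _ = pool_and_standardize(paperlike)
        oneway, trends, pairwise = _followup(z)
        summaries = summarize_sensitivity(oneway, trends, pairwise, z)
        assert len(summaries) == 18
        for s in summaries:
            assert 0 <= s.n_sig_contrasts <= 3
            assert 0 <= s.n_sig_pairwise <= 6
            assert s.n_sig_contrasts == sum(p < 0.05 for p in s.trend_p.values())
            assert s.n_sig_pairwise == sum(p < 0.05 for p in s.pairwise_p.values())
            assert all(v >= 0 for v in s.delta_z.values())

    def test_counting_at_alpha(self, paperlike):
        z, _ = pool_and_standardize(paperlike)
        oneway, trends, pairwise = _followup(z)
        # fabricate known p's for one measure and recount
        m = z.measures[0]
        ps = {"linear": 0.01, "quadratic": 0.20, "cubic": 0.03}
        fake = [type(t)(**{**t.__dict__, "p": ps[t.trend]}) for t in trends[m]]
        trends[m] = fake
        s = next(
            x for x in summarize_sensitivity(oneway, trends, pairwise, z)
            if x.measure == m
        )
        assert s.n_sig_contrasts == 2

    def test_monotone_in_alpha(self, paperlike):
        z, _ = pool_and_standardize(paperlike)
        oneway, trends, pairwise = _followup(z)
        lo = summarize_sensitivity(oneway, trends, pairwise, z, alpha=0.01)
        hi = summarize_sensitivity(oneway, trends, pairwise, z, alpha=0.10)
        for a, b in zip(lo, hi):
            assert b.n_sig_contrasts >= a.n_sig_contrasts
            assert b.n_sig_pairwise >= a.n_sig_pairwise

    def test_mismatched_measures_rejected(self, paperlike):
        z, _ = pool_and_standardize(paperlike)
        oneway, trends, pairwise = _followup(z)
        oneway.pop(z.measures[0])
        with pytest.raises(ConsistencyError):
            summarize_sensitivity(oneway, trends, pairwise, z)


class TestRanking:
    def test_dominant_measure_ranks_first(self):
        strong = _summary(
            "strong", sig=True,
            trend_p={"linear": 0.001, "quadratic": 0.001},
            pair_p={(1, 2): 0.001}, dz={(1, 2): 0.9},
        )
        weak = _summary("weak")
        ranking = rank_measures([weak, strong])
        assert ranking.measures() == ["strong", "weak"]
        assert ranking.rank_of("strong") == 1

    def test_identical_summaries_share_rank(self):
        ranking = rank_measures([_summary("a"), _summary("b")])
        assert ranking.rank_of("a") == ranking.rank_of("b") == 1

    def test_invariant_to_input_order(self):
        summaries = [
            _summary("a", sig=True, dz={(1, 2): 0.5}),
            _summary("b", dz={(1, 2): 0.8}),
            _summary("c", sig=True, dz={(1, 2): 0.2}),
        ]
        fwd = rank_measures(summaries)
        rev = rank_measures(summaries[::-1])
        assert fwd.entries == rev.entries

    def test_empty_rejected(self):
        with pytest.raises(DesignError):
            rank_measures([])

    def test_table_layout(self):
        frame = sensitivity_table([_summary("a"), _summary("b")])
        assert list(frame["measure"]) == ["a", "b"]
        assert "n_sig_contrasts" in frame.columns
        assert "pairwise_t1_vs_t2_p" in frame.columns
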