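"""Fully within-subject repeated-measures ANOVA with Greenhouse–Geisser correction.

One-way design
--------------
For an ``n`` subjects x ``k`` levels matrix the total sum of squares is
partitioned as

    SS_total = SS_subjects + SS_level + SS_error,

with ``F = MS_level / MS_error`` on ``(k-1, (k-1)(n-1))`` degrees of freedom.
Removing SS_subjects is what makes the test within-subject: stable
between-subject differences never enter the error term.

Two-way design
--------------
For a subjects x sessions x measures cube, each within-subject effect is
tested against its own subject-by-effect interaction:

    time          vs  subject x time
    measure       vs  subject x measure
    time x measure vs subject x time x measure

Sphericity
----------
The F test assumes equal variances of all pairwise level differences
(sphericity). The Greenhouse–Geisser estimate

    eps = (sum lambda_i)^2 / ((k-1) * sum lambda_i^2)

over the eigenvalues ``lambda_i`` of the double-centered level covariance
matrix shrinks both degrees of freedom towards the lower bound ``1/(k-1)``;
``eps = 1`` iff sphericity holds. Every result carries both the uncorrected
and the corrected p-value; in the two-way design each effect gets its own
epsilon computed from that effect's contrast covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .exceptions import DesignError

_ZERO_SS = 1e-12  # relative threshold below which an SS is treated as null


@dataclass(frozen=True)
class AnovaResult:
    """One effect from a within-subject ANOVA, with GG-corrected inference."""

    effect: str
    ss_effect: float
    ss_error: float
    df_effect: float
    df_error: float
    ms_effect: float
    ms_error: float
    F: float
    p_uncorrected: float
    epsilon_gg: float
    df_effect_gg: float
    df_error_gg: float
    p_gg: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "effect": self.effect,
            "ss_effect": self.ss_effect,
            "ss_error": self.ss_error,
            "df_effect": self.df_effect,
            "df_error": self.df_error,
            "ms_effect": self.ms_effect,
            "ms_error": self.ms_error,
            "F": self.F,
            "p_uncorrected": self.p_uncorrected,
            "epsilon_gg": self.epsilon_gg,
            "df_effect_gg": self.df_effect_gg,
            "df_error_gg": self.df_error_gg,
            "p_gg": self.p_gg,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class TwoWayResult:
    """The three effects of the time x measure fully within-subject ANOVA."""

    time: AnovaResult
    measure: AnovaResult
    interaction: AnovaResult
    ss_subjects: float = 0.0
    ss_total: float = 0.0

    def __iter__(self):
        return iter((self.time, self.measure, self.interaction))


def greenhouse_geisser_epsilon(cov: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from a k x k level covariance matrix.

    Computed from the eigenvalues of the double-centered covariance
    ``P S P`` with ``P = I - J/k``, clamped to ``[1/(k-1), 1]``. Returns 1
    when the centered covariance is numerically zero (sphericity holds
    trivially, e.g. identical levels).
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise DesignError("covariance matrix must be square")
    if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-10):
        raise DesignError("covariance matrix must be symmetric")
    k = cov.shape[0]
    if k < 2:
        raise DesignError("need at least 2 levels")
    center = np.eye(k) - np.full((k, k), 1.0 / k)
    dc = center @ cov @ center
    lam = linalg.eigvalsh(dc)
    num = lam.sum() ** 2
    den = (k - 1) * (lam**2).sum()
    if den <= num * 1e-14 or den == 0.0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _epsilon_from_contrast_cov(m: np.ndarray, d: int) -> float:
    """Box epsilon from a d x d orthonormal-contrast-score covariance."""
    tr = np.trace(m)
    tr2 = np.trace(m @ m)
    if tr2 <= 1e-14 * max(tr**2, 1e-300):
        return 1.0
    return float(np.clip(tr**2 / (d * tr2), 1.0 / d, 1.0))


def _f_pvalue(F: float, df1: float, df2: float) -> float:
    return float(stats.f.sf(F, df1, df2))


def _make_result(
    effect: str,
    ss_effect: float,
    ss_error: float,
    df_effect: float,
    df_error: float,
    epsilon: float,
    ss_scale: float,
) -> AnovaResult:
    """Assemble an AnovaResult, handling zero-error-variance degeneracies.

    When MS_error vanishes the F ratio is undefined; a zero effect SS is
    reported as F=0, p=1 and a nonzero one as F=+inf, p=0, both flagged,
    so batch runs over many measures never abort.
    """
    ms_effect = ss_effect / df_effect
    ms_error = ss_error / df_error
    tol = _ZERO_SS * max(ss_scale, 1.0)
    degenerate = False
    if ms_error > 0 and ss_error > tol:
        F = ms_effect / ms_error
        p = _f_pvalue(F, df_effect, df_error)
        p_gg = _f_pvalue(F, epsilon * df_effect, epsilon * df_error)
    elif ss_effect <= tol:
        F, p, p_gg, degenerate = 0.0, 1.0, 1.0, True
    else:
        F, p, p_gg, degenerate = float("inf"), 0.0, 0.0, True
    return AnovaResult(
        effect=effect,
        ss_effect=ss_effect,
        ss_error=ss_error,
        df_effect=df_effect,
        df_error=df_error,
        ms_effect=ms_effect,
        ms_error=ms_error,
        F=F,
        p_uncorrected=p,
        epsilon_gg=epsilon,
        df_effect_gg=epsilon * df_effect,
        df_error_gg=epsilon * df_error,
        p_gg=p_gg,
        degenerate=degenerate,
    )


def rm_anova_oneway(values: np.ndarray, alpha: float = 0.05) -> AnovaResult:
    """One-way within-subject ANOVA on a subjects x levels matrix.

    Parameters
    ----------
    values
        ``n x k`` array, one row per subject, one column per (ordered) level.
    alpha
        Retained for interface symmetry; inference is reported as p-values.

    Returns
    -------
    AnovaResult for the level (time) effect, with GG epsilon estimated from
    the sample covariance of the level columns.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise DesignError("values must be a 2-D subjects x levels matrix")
    n, k = y.shape
    if n < 2 or k < 2:
        raise DesignError("need at least 2 subjects and 2 levels")
    if not np.all(np.isfinite(y)):
        raise DesignError("missing or non-finite cells are not supported")

    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_total = ((y - grand) ** 2).sum()
    ss_subjects = k * ((row_means - grand) ** 2).sum()
    ss_level = n * ((col_means - grand) ** 2).sum()
    ss_error = ss_total - ss_subjects - ss_level

    eps = 1.0 if k == 2 else greenhouse_geisser_epsilon(np.cov(y, rowvar=False))
    return _make_result(
        "time", ss_level, max(ss_error, 0.0), k - 1, (k - 1) * (n - 1), eps, ss_total
    )


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal basis orthogonal to the constant vector."""
    return linalg.helmert(k)


def rm_anova_twoway_within(cube: np.ndarray, alpha: float = 0.05) -> TwoWayResult:
    """Two-factor fully within-subject ANOVA on a subjects x sessions x measures cube.

    Decomposes SS_total into subjects, time, measure, time x measure and the
    three subject-crossed error strata; each effect is tested against its own
    subject-by-effect interaction and GG-corrected with an epsilon estimated
    from its own contrast covariance (Kronecker-product basis for the
    interaction).
    """
    y = np.asarray(cube, dtype=float)
    if y.ndim != 3:
        raise DesignError("cube must be subjects x sessions x measures")
    n, t, m = y.shape
    if n < 2 or t < 2 or m < 2:
        raise DesignError("need at least 2 subjects, 2 sessions and 2 measures")
    if not np.all(np.isfinite(y)):
        raise DesignError("missing or non-finite cells are not supported")

    grand = y.mean()
    m_i = y.mean(axis=(1, 2))  # subject means
    m_j = y.mean(axis=(0, 2))  # session means
    m_k = y.mean(axis=(0, 1))  # measure means
    m_ij = y.mean(axis=2)
    m_ik = y.mean(axis=1)
    m_jk = y.mean(axis=0)

    ss_total = ((y - grand) ** 2).sum()
    ss_subj = t * m * ((m_i - grand) ** 2).sum()
    ss_time = n * m * ((m_j - grand) ** 2).sum()
    ss_meas = n * t * ((m_k - grand) ** 2).sum()
    ss_subj_time = m * ((m_ij - m_i[:, None] - m_j[None, :] + grand) ** 2).sum()
    ss_subj_meas = t * ((m_ik - m_i[:, None] - m_k[None, :] + grand) ** 2).sum()
    ss_time_meas = n * ((m_jk - m_j[:, None] - m_k[None, :] + grand) ** 2).sum()
    ss_resid = (
        ss_total - ss_subj - ss_time - ss_meas
        - ss_subj_time - ss_subj_meas - ss_time_meas
    )
    ss_resid = max(ss_resid, 0.0)

    # Per-effect GG epsilon from that effect's contrast covariance.
    eps_time = (
        1.0 if t == 2
        else greenhouse_geisser_epsilon(np.cov(y.mean(axis=2), rowvar=False))
    )
    eps_meas = (
        1.0 if m == 2
        else greenhouse_geisser_epsilon(np.cov(y.mean(axis=1), rowvar=False))
    )
    ct = _orthonormal_contrasts(t)
    cm = _orthonormal_contrasts(m)
    scores = np.einsum("at,itm,bm->iab", ct, y, cm).reshape(n, (t - 1) * (m - 1))
    if n > 1:
        cov_int = np.cov(scores, rowvar=False)
        eps_int = _epsilon_from_contrast_cov(
            np.atleast_2d(cov_int), (t - 1) * (m - 1)
        )
    else:  # pragma: no cover - n >= 2 enforced above
        eps_int = 1.0

    time = _make_result(
        "time", ss_time, ss_subj_time, t - 1, (t - 1) * (n - 1), eps_time, ss_total
    )
    measure = _make_result(
        "measure", ss_meas, ss_subj_meas, m - 1, (m - 1) * (n - 1), eps_meas, ss_total
    )
    interaction = _make_result(
        "time x measure",
        ss_time_meas,
        ss_resid,
        (t - 1) * (m - 1),
        (t - 1) * (m - 1) * (n - 1),
        eps_int,
        ss_total,
    )
    return TwoWayResult(
        time=time,
        measure=measure,
        interaction=interaction,
        ss_subjects=ss_subj,
        ss_total=ss_total,
    )
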