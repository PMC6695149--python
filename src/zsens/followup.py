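"""Trend contrasts and unadjusted pairwise comparisons across sessions.

Orthogonal polynomial contrasts decompose the session (time) effect into
linear, quadratic, cubic, ... components on equally spaced levels; the
quadratic component captures the inverted-U stress/recovery profile
(departure from baseline under stress, return at recovery). Pairwise
session comparisons follow Fisher's LSD logic: plain paired t-tests with no
multiplicity adjustment, since the aim is to count which comparisons each
measure detects, not to control family-wise error.

By default every contrast and every pairwise comparison uses its own error
term (the variance of per-subject contrast scores / paired differences,
df = n-1), which is robust to sphericity violation; a pooled-error variant
using the omnibus MS_error on (k-1)(n-1) df is available via
``error_term="pooled"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import gcd

import numpy as np
from scipy import stats

from .exceptions import DesignError
from .rm_anova import rm_anova_oneway

TREND_NAMES = {1: "linear", 2: "quadratic", 3: "cubic"}


def trend_name(degree: int) -> str:
    return TREND_NAMES.get(degree, f"degree{degree}")


@dataclass(frozen=True)
class ContrastSet:
    """Integer orthogonal polynomial contrasts for k equally spaced levels.

    ``coefficients`` is a (k-1) x k integer matrix; row r is the degree-(r+1)
    polynomial contrast. Rows sum to zero and are mutually orthogonal,
    exactly, in integer arithmetic.
    """

    k: int
    coefficients: np.ndarray

    def row(self, degree: int) -> np.ndarray:
        if not 1 <= degree <= self.k - 1:
            raise DesignError(f"degree must be in 1..{self.k - 1}")
        return self.coefficients[degree - 1]


@dataclass(frozen=True)
class ContrastResult:
    measure: str
    trend: str
    degree: int
    estimate: float  # mean per-subject contrast score
    t: float
    df: int
    p: float
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class PairwiseResult:
    measure: str
    session_a: int
    session_b: int
    mean_diff: float
    t: float
    df: int
    p: float
    significant: bool
    degenerate: bool = False


def polynomial_contrast_coefficients(k: int) -> ContrastSet:
    """Orthogonal polynomial contrasts for k equally spaced levels.

    Gram–Schmidt of {t, t^2, ..., t^(k-1)} on points 1..k against the
    constant vector, carried out in exact rational arithmetic and scaled to
    the smallest integer representation (e.g. k=4 gives (-3,-1,1,3),
    (1,-1,-1,1), (-1,3,-3,1)).
    """
    if k < 2:
        raise DesignError("need at least 2 levels for polynomial contrasts")
    points = [Fraction(j) for j in range(1, k + 1)]
    basis: list[list[Fraction]] = [[Fraction(1)] * k]
    rows: list[list[int]] = []
    for degree in range(1, k):
        v = [p**degree for p in points]
        for b in basis:
            proj = sum(x * y for x, y in zip(v, b)) / sum(y * y for y in b)
            v = [x - proj * y for x, y in zip(v, b)]
        basis.append(v)
        lcm = 1
        for f in v:
            lcm = lcm * f.denominator // gcd(lcm, f.denominator)
        ints = [int(f * lcm) for f in v]
        g = 0
        for i in ints:
            g = gcd(g, abs(i))
        ints = [i // g for i in ints]
        # sign convention: positive coefficient at the last level
        last_nonzero = next(i for i in reversed(ints) if i != 0)
        if last_nonzero < 0:
            ints = [-i for i in ints]
        rows.append(ints)
    return ContrastSet(k=k, coefficients=np.array(rows, dtype=int))


def _one_sample_t(scores: np.ndarray) -> tuple[float, float, int, float, bool]:
    """(estimate, t, df, two-sided p, degenerate) for scores vs 0."""
    n = len(scores)
    est = float(scores.mean())
    sd = float(scores.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if est == 0.0:
            return est, 0.0, df, 1.0, False
        return est, float(np.sign(est)) * float("inf"), df, 0.0, True
    t = est / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return est, float(t), df, p, False


def test_trend(
    values: np.ndarray,
    contrast: np.ndarray,
    alpha: float = 0.05,
    measure: str = "",
    error_term: str = "separate",
) -> ContrastResult:
    """Test one polynomial trend on a subjects x levels matrix.

    Each subject's contrast score is ``L_i = sum_j c_j x_ij``; the trend is
    significant when the mean score differs from zero. With
    ``error_term="separate"`` (default) a one-sample t on the scores is
    used (df = n-1); with ``"pooled"`` the omnibus MS_error replaces the
    score variance (df = (k-1)(n-1)).
    """
    y = np.asarray(values, dtype=float)
    c = np.asarray(contrast, dtype=float)
    if y.ndim != 2 or y.shape[1] != len(c):
        raise DesignError("contrast length must equal the number of levels")
    n, k = y.shape
    degree = _infer_degree(c, k)
    scores = y @ c
    if error_term == "separate":
        est, t, df, p, degen = _one_sample_t(scores)
    elif error_term == "pooled":
        res = rm_anova_oneway(y)
        est = float(scores.mean())
        se = float(np.sqrt(res.ms_error * (c**2).sum() / n))
        df = int(res.df_error)
        if se == 0.0:
            t = 0.0 if est == 0.0 else float(np.sign(est)) * float("inf")
            p = 1.0 if est == 0.0 else 0.0
            degen = est != 0.0
        else:
            t = est / se
            p = 2.0 * float(stats.t.sf(abs(t), df))
            degen = False
    else:
        raise DesignError(f"unknown error_term {error_term!r}")
    return ContrastResult(
        measure=measure,
        trend=trend_name(degree),
        degree=degree,
        estimate=est,
        t=t,
        df=df,
        p=p,
        significant=p < alpha,
        degenerate=degen,
    )


def _infer_degree(c: np.ndarray, k: int) -> int:
    """Match a coefficient row to its polynomial degree (0 if not standard)."""
    ref = polynomial_contrast_coefficients(k).coefficients.astype(float)
    for r, row in enumerate(ref, start=1):
        cross = row @ c
        if np.isclose(abs(cross), np.linalg.norm(row) * np.linalg.norm(c)):
            return r
    return 0


def trend_tests(
    values: np.ndarray,
    alpha: float = 0.05,
    measure: str = "",
    max_degree: int | None = None,
    error_term: str = "separate",
) -> list[ContrastResult]:
    """All polynomial trend tests (degrees 1..k-1, optionally capped)."""
    k = np.asarray(values).shape[1]
    contrasts = polynomial_contrast_coefficients(k)
    degrees = range(1, k if max_degree is None else min(k, max_degree + 1))
    return [
        test_trend(
            values,
            contrasts.row(d),
            alpha=alpha,
            measure=measure,
            error_term=error_term,
        )
        for d in degrees
    ]


def lsd_pairwise(
    values: np.ndarray,
    alpha: float = 0.05,
    measure: str = "",
    error_term: str = "separate",
) -> list[PairwiseResult]:
    """Fisher's LSD paired comparisons for every pair of levels.

    For each unordered pair (a, b): paired differences d_i = x_ia - x_ib,
    t = mean(d) / (SD(d)/sqrt(n)), df = n-1, two-sided p. No multiplicity
    adjustment is applied — significance counts across pairs are themselves
    the quantity of interest downstream.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise DesignError("values must be a 2-D subjects x levels matrix")
    n, k = y.shape
    if n < 2:
        raise DesignError("need at least 2 subjects")
    pooled = rm_anova_oneway(y) if error_term == "pooled" else None
    results: list[PairwiseResult] = []
    for a, b in combinations(range(k), 2):
        d = y[:, a] - y[:, b]
        if error_term == "separate":
            est, t, df, p, degen = _one_sample_t(d)
        elif error_term == "pooled":
            est = float(d.mean())
            se = float(np.sqrt(2.0 * pooled.ms_error / n))
            df = int(pooled.df_error)
            if se == 0.0:
                t = 0.0 if est == 0.0 else float(np.sign(est)) * float("inf")
                p = 1.0 if est == 0.0 else 0.0
                degen = est != 0.0
            else:
                t = est / se
                p = 2.0 * float(stats.t.sf(abs(t), df))
                degen = False
        else:
            raise DesignError(f"unknown error_term {error_term!r}")
        results.append(
            PairwiseResult(
                measure=measure,
                session_a=a + 1,
                session_b=b + 1,
                mean_diff=est,
                t=t,
                df=df,
                p=p,
                significant=p < alpha,
                degenerate=degen,
            )
        )
    return results
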