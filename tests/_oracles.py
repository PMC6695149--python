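"""Independent brute-force oracles for the statistical routines.

Everything here is computed by a different route than the implementation:
sums of squares from explicit loops over cell/marginal means, epsilon from
an orthonormal contrast basis (the implementation diagonalizes the
double-centered covariance), and t statistics from explicit score vectors.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def oneway_anova_oracle(y: np.ndarray) -> dict:
    """Textbook within-subject one-way ANOVA via explicit mean loops."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = sum(y[i, j] for i in range(n) for j in range(k)) / (n * k)
    ss_total = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_subj = sum(k * (np.mean(y[i, :]) - grand) ** 2 for i in range(n))
    ss_level = sum(n * (np.mean(y[:, j]) - grand) ** 2 for j in range(k))
    ss_error = ss_total - ss_subj - ss_level
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_level / df1) / (ss_error / df2)
    return {
        "ss_total": ss_total,
        "ss_subjects": ss_subj,
        "ss_level": ss_level,
        "ss_error": ss_error,
        "F": F,
        "p": float(stats.f.sf(F, df1, df2)),
        "df": (df1, df2),
    }


def _orthonormal_contrast_basis(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows orthogonal to the constant vector.

    Built by QR-decomposing random vectors projected off the constant —
    deliberately not the Helmert construction nor an eigendecomposition.
    """
    rng = np.random.default_rng(12345)
    ones = np.ones(k) / np.sqrt(k)
    mat = np.column_stack([ones, rng.standard_normal((k, k - 1))])
    q, _ = np.linalg.qr(mat)
    c = q[:, 1:].T
    # fix signs for determinism (irrelevant to epsilon, tidy for debugging)
    signs = np.sign(c[:, 0])
    signs[signs == 0] = 1.0
    return c * signs[:, None]


def gg_epsilon_oracle(cov: np.ndarray) -> float:
    """Box/GG epsilon via the contrast-basis trace formula."""
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    c = _orthonormal_contrast_basis(k)
    m = c @ cov @ c.T
    eps = np.trace(m) ** 2 / ((k - 1) * np.trace(m @ m))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def twoway_anova_oracle(cube: np.ndarray) -> dict:
    """Fully within-subject two-way ANOVA via explicit marginal-mean loops."""
    y = np.asarray(cube, dtype=float)
    n, t, m = y.shape
    grand = y.mean()
    ss_total = sum(
        (y[i, j, l] - grand) ** 2
        for i in range(n) for j in range(t) for l in range(m)
    )
    ss_subj = sum(t * m * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_time = sum(n * m * (y[:, j, :].mean() - grand) ** 2 for j in range(t))
    ss_meas = sum(n * t * (y[:, :, l].mean() - grand) ** 2 for l in range(m))
    ss_st = sum(
        m * (y[i, j, :].mean() - y[i].mean() - y[:, j, :].mean() + grand) ** 2
        for i in range(n) for j in range(t)
    )
    ss_sm = sum(
        t * (y[i, :, l].mean() - y[i].mean() - y[:, :, l].mean() + grand) ** 2
        for i in range(n) for l in range(m)
    )
    ss_tm = sum(
        n * (y[:, j, l].mean() - y[:, j, :].mean() - y[:, :, l].mean() + grand) ** 2
        for j in range(t) for l in range(m)
    )
    ss_res = ss_total - ss_subj - ss_time - ss_meas - ss_st - ss_sm - ss_tm

    out = {}
    for name, ss_eff, ss_err, df1, df2 in (
        ("time", ss_time, ss_st, t - 1, (t - 1) * (n - 1)),
        ("measure", ss_meas, ss_sm, m - 1, (m - 1) * (n - 1)),
        ("interaction", ss_tm, ss_res, (t - 1) * (m - 1), (t - 1) * (m - 1) * (n - 1)),
    ):
        F = (ss_eff / df1) / (ss_err / df2)
        out[name] = {
            "ss_effect": ss_eff,
            "ss_error": ss_err,
            "F": F,
            "p": float(stats.f.sf(F, df1, df2)),
        }
    out["ss_total"] = ss_total
    return out


def trend_t_oracle(y: np.ndarray, contrast: np.ndarray) -> dict:
    """Explicit per-subject contrast-score t-test."""
    y = np.asarray(y, dtype=float)
    c = np.asarray(contrast, dtype=float)
    scores = np.array([sum(c[j] * y[i, j] for j in range(len(c))) for i in range(len(y))])
    n = len(scores)
    mean = scores.mean()
    sd = np.sqrt(sum((s - mean) ** 2 for s in scores) / (n - 1))
    t = mean / (sd / np.sqrt(n))
    return {
        "estimate": mean,
        "t": t,
        "df": n - 1,
        "p": 2 * float(stats.t.sf(abs(t), n - 1)),
    }


def paired_t_oracle(a: np.ndarray, b: np.ndarray) -> dict:
    """Explicit paired-difference t-test for one session pair."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = len(d)
    mean = d.mean()
    sd = np.sqrt(sum((x - mean) ** 2 for x in d) / (n - 1))
    t = mean / (sd / np.sqrt(n))
    return {
        "mean_diff": mean,
        "t": t,
        "df": n - 1,
        "p": 2 * float(stats.t.sf(abs(t), n - 1)),
    }
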