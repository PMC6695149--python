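"""Optional static bar charts of the sensitivity indices.

Requires matplotlib (install the ``plots`` extra). Each function returns
the Figure so callers can restyle or save it.
"""

from __future__ import annotations

from .sensitivity import SensitivitySummary


def _require_matplotlib():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "matplotlib is required for plotting; install the 'plots' extra"
        ) from exc
    return plt


def plot_significance_counts(
    summaries: list[SensitivitySummary], kind: str = "contrasts", path=None
):
    """Bar chart of per-measure significant-test counts.

    ``kind`` selects trend contrasts or pairwise comparisons; bars for
    measures whose one-way ANOVA was significant are drawn darker.
    """
    plt = _require_matplotlib()
    attr = {"contrasts": "n_sig_contrasts", "pairwise": "n_sig_pairwise"}[kind]
    names = [s.measure for s in summaries]
    counts = [getattr(s, attr) for s in summaries]
    colors = ["0.25" if s.oneway_significant else "0.7" for s in summaries]
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(names, counts, color=colors)
    ax.set_ylabel(f"significant {kind}")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_delta_z(
    summaries: list[SensitivitySummary], pair: tuple[int, int] = (1, 2), path=None
):
    """Bar chart of |dz| between one session pair, per measure.

    Measures with a significant pairwise comparison for that pair are
    drawn darker.
    """
    plt = _require_matplotlib()
    names = [s.measure for s in summaries]
    dz = [s.delta_z[pair] for s in summaries]
    alpha_sig = [s.pairwise_p.get(pair, 1.0) for s in summaries]
    colors = ["0.25" if p < 0.05 else "0.7" for p in alpha_sig]
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(names, dz, color=colors)
    ax.set_ylabel(f"|mean z change|, session {pair[0]} to {pair[1]}")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
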