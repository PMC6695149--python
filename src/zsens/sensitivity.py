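"""Per-measure sensitivity indices and ranking.

A measure's sensitivity to the study manipulation is summarized by three
classes of evidence, all computed on the standardized (z) scale so they are
comparable across measures with different native units:

* whether the per-measure one-way RM-ANOVA detects a session effect;
* how many follow-up tests are significant (trend contrasts out of k-1,
  pairwise comparisons out of k(k-1)/2);
* the absolute standardized change |mean z| between designated session
  pairs (by default baseline vs each stress session; baseline vs recovery
  is deliberately excluded, since a return to baseline is expected there
  and the comparison carries no sensitivity information).

Ranking uses a descending lexicographic key over exactly those evidence
classes: (one-way significant, total significance count, max |dz| over the
stress pairs). The key tuple is recorded on each ranked entry so the
ordering is auditable; ties share a rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data_io import StudyData
from .exceptions import ConsistencyError, DesignError
from .followup import ContrastResult, PairwiseResult
from .rm_anova import AnovaResult

DEFAULT_DELTA_Z_PAIRS: tuple[tuple[int, int], ...] = ((1, 2), (1, 3))


@dataclass(frozen=True)
class SensitivitySummary:
    """One measure's row of the sensitivity table."""

    measure: str
    oneway_p: float
    oneway_significant: bool
    trend_p: dict[str, float]
    pairwise_p: dict[tuple[int, int], float]
    n_sig_contrasts: int
    n_sig_pairwise: int
    delta_z: dict[tuple[int, int], float]
    expected_direction: int = 0


@dataclass(frozen=True)
class SensitivityRanking:
    """Measures ordered from most to least sensitive; ties share a rank."""

    entries: tuple[tuple[str, int, tuple], ...]  # (measure, rank, key)

    def measures(self) -> list[str]:
        return [m for m, _, _ in self.entries]

    def rank_of(self, measure: str) -> int:
        for m, rank, _ in self.entries:
            if m == measure:
                return rank
        raise KeyError(measure)


def magnitude_of_change(
    z: StudyData, from_session: int, to_session: int
) -> dict[str, float]:
    """|mean z at to_session - mean z at from_session| per measure.

    Input must be standardized data; the result is the standardized effect
    magnitude between the two sessions, the common scale on which measures
    in different native units can be compared.
    """
    sessions = set(z.sessions)
    for s in (from_session, to_session):
        if s not in sessions:
            raise KeyError(f"session {s} not present (have {sorted(sessions)})")
    frame = z.frame
    means = frame.groupby(["measure", "session"])["value"].mean()
    return {
        m: float(abs(means[(m, to_session)] - means[(m, from_session)]))
        for m in z.measures
    }


def summarize_sensitivity(
    oneway: dict[str, AnovaResult],
    trends: dict[str, list[ContrastResult]],
    pairwise: dict[str, list[PairwiseResult]],
    z: StudyData,
    alpha: float = 0.05,
    delta_z_pairs: tuple[tuple[int, int], ...] = DEFAULT_DELTA_Z_PAIRS,
    directions: dict[str, int] | None = None,
    use_gg: bool = True,
) -> list[SensitivitySummary]:
    """Assemble one :class:`SensitivitySummary` per measure.

    Significance counts are computed at ``alpha`` over *all* trend and
    pairwise p-values, regardless of whether the measure's one-way ANOVA
    was itself significant. The one-way decision uses the GG-corrected p
    by default (``use_gg=False`` switches to the uncorrected p).
    """
    measure_sets = [set(oneway), set(trends), set(pairwise), set(z.measures)]
    if any(s != measure_sets[0] for s in measure_sets[1:]):
        raise ConsistencyError("one-way, trend, pairwise and z inputs cover different measures")

    dz_by_pair = {
        pair: magnitude_of_change(z, *pair) for pair in delta_z_pairs
    }
    directions = directions or {}
    summaries: list[SensitivitySummary] = []
    for m in z.measures:
        res = oneway[m]
        p_one = res.p_gg if use_gg else res.p_uncorrected
        trend_p = {c.trend: c.p for c in trends[m]}
        pair_p = {(r.session_a, r.session_b): r.p for r in pairwise[m]}
        summaries.append(
            SensitivitySummary(
                measure=m,
                oneway_p=p_one,
                oneway_significant=p_one < alpha,
                trend_p=trend_p,
                pairwise_p=pair_p,
                n_sig_contrasts=sum(p < alpha for p in trend_p.values()),
                n_sig_pairwise=sum(p < alpha for p in pair_p.values()),
                delta_z={pair: dz_by_pair[pair][m] for pair in delta_z_pairs},
                expected_direction=int(directions.get(m, 0)),
            )
        )
    return summaries


def rank_measures(
    summaries: list[SensitivitySummary],
    delta_z_pairs: tuple[tuple[int, int], ...] | None = None,
) -> SensitivityRanking:
    """Rank measures by descending (one-way sig, significance count, max |dz|).

    ``delta_z_pairs`` restricts which stored |dz| entries enter the key
    (default: all pairs present in the summaries). Ties share a rank;
    ranking is invariant to the input order of the summaries.
    """
    if not summaries:
        raise DesignError("cannot rank an empty summary list")

    def key(s: SensitivitySummary) -> tuple:
        pairs = delta_z_pairs if delta_z_pairs is not None else tuple(s.delta_z)
        dz = max((s.delta_z[p] for p in pairs), default=0.0)
        return (
            int(s.oneway_significant),
            s.n_sig_contrasts + s.n_sig_pairwise,
            dz,
        )

    decorated = sorted(
        ((key(s), s.measure) for s in summaries),
        key=lambda kv: (tuple(-x for x in kv[0][:2]) + (-kv[0][2],), kv[1]),
    )
    entries: list[tuple[str, int, tuple]] = []
    rank = 0
    prev_key = None
    for i, (k, m) in enumerate(decorated, start=1):
        if k != prev_key:
            rank = i
            prev_key = k
        entries.append((m, rank, k))
    return SensitivityRanking(entries=tuple(entries))


def sensitivity_table(summaries: list[SensitivitySummary]) -> pd.DataFrame:
    """Sensitivity summaries as a flat table (one row per measure).

    Column layout mirrors the reporting convention: one-way p, trend p's,
    the six (for k=4) pairwise p's, the two significance counts and the
    |dz| magnitudes.
    """
    rows = []
    for s in summaries:
        row: dict = {
            "measure": s.measure,
            "oneway_p": s.oneway_p,
            "oneway_significant": s.oneway_significant,
        }
        for trend, p in s.trend_p.items():
            row[f"trend_{trend}_p"] = p
        for (a, b), p in sorted(s.pairwise_p.items()):
            row[f"pairwise_t{a}_vs_t{b}_p"] = p
        row["n_sig_contrasts"] = s.n_sig_contrasts
        row["n_sig_pairwise"] = s.n_sig_pairwise
        for (a, b), dz in sorted(s.delta_z.items()):
            row[f"delta_z_t{a}_to_t{b}"] = dz
        row["expected_direction"] = s.expected_direction
        rows.append(row)
    return pd.DataFrame(rows)
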