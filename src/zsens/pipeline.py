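"""End-to-end analysis pipeline and report bundle.

The pipeline runs the full procedure in a fixed order:

1. read and validate long-format data;
2. complete-case subject filtering (balanced design);
3. pooled z-score standardization per measure;
4. QC gate: raw-vs-z one-way ANOVA equivalence (aborts on failure unless
   ``strict_qc=False``);
5. omnibus two-way (time x measure) within-subject ANOVA on the z data;
6. per-measure follow-up: one-way ANOVA, polynomial trends, LSD pairs;
7. sensitivity summaries and ranking.

The analysis path contains no randomness: identical inputs produce
identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .data_io import StudyData, filter_complete_cases, to_cube, to_wide
from .exceptions import PipelineError, ZsensError
from .followup import lsd_pairwise, trend_tests
from .rm_anova import TwoWayResult, rm_anova_oneway, rm_anova_twoway_within
from .sensitivity import (
    DEFAULT_DELTA_Z_PAIRS,
    SensitivityRanking,
    SensitivitySummary,
    rank_measures,
    sensitivity_table,
    summarize_sensitivity,
)
from .standardize import QCReport, qc_equivalence_check, qc_report_frame, pool_and_standardize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything that parameterizes one pipeline run."""

    alpha: float = 0.05
    sd_ddof: int = 1  # 1 = sample SD (n-1); 0 = population SD
    error_term: str = "separate"  # or "pooled"
    delta_z_pairs: tuple[tuple[int, int], ...] = DEFAULT_DELTA_Z_PAIRS
    measure_directions: dict[str, int] | None = None
    strict_qc: bool = True
    use_gg: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ZsensError("alpha must be in (0, 1)")
        if self.error_term not in ("separate", "pooled"):
            raise ZsensError("error_term must be 'separate' or 'pooled'")

    def hash(self) -> str:
        payload = json.dumps(
            {**asdict(self), "delta_z_pairs": [list(p) for p in self.delta_z_pairs]},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ReportBundle:
    """All artefacts produced by one pipeline run."""

    config: PipelineConfig
    data: StudyData
    z_data: StudyData
    qc: list[QCReport]
    omnibus: TwoWayResult
    oneway: dict[str, object]
    summaries: list[SensitivitySummary]
    ranking: SensitivityRanking
    n_dropped_subjects: int = 0


def run_pipeline(data: StudyData, config: PipelineConfig | None = None) -> ReportBundle:
    """Execute the full standardize-and-compare procedure on ``data``."""
    config = config or PipelineConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ZsensError as exc:
            raise PipelineError(f"stage '{name}': {exc}") from exc

    n_before = data.n_subjects
    balanced = stage("complete-case filter", filter_complete_cases, data)
    z_data, records = stage(
        "standardization", pool_and_standardize, balanced, config.sd_ddof
    )
    qc = stage(
        "qc-equivalence",
        qc_equivalence_check,
        balanced,
        z_data,
        config.alpha,
        ddof=config.sd_ddof,
    )
    failing = [r.measure for r in qc if not r.passed]
    if failing:
        msg = f"stage 'qc-equivalence': QC failed for measure(s) {failing}"
        if config.strict_qc:
            raise PipelineError(msg)
        logger.warning(msg)

    omnibus = stage(
        "two-way ANOVA", rm_anova_twoway_within, to_cube(z_data), config.alpha
    )
    oneway, trends, pairwise = {}, {}, {}
    for m in z_data.measures:
        wide = to_wide(z_data, m)
        oneway[m] = stage(f"one-way ANOVA [{m}]", rm_anova_oneway, wide, config.alpha)
        trends[m] = stage(
            f"trend contrasts [{m}]",
            trend_tests,
            wide,
            config.alpha,
            m,
            3,  # report up to the cubic, the highest trend of interest
            config.error_term,
        )
        pairwise[m] = stage(
            f"LSD pairwise [{m}]",
            lsd_pairwise,
            wide,
            config.alpha,
            m,
            config.error_term,
        )
    summaries = stage(
        "sensitivity summary",
        summarize_sensitivity,
        oneway,
        trends,
        pairwise,
        z_data,
        config.alpha,
        config.delta_z_pairs,
        config.measure_directions,
        config.use_gg,
    )
    ranking = stage("ranking", rank_measures, summaries, config.delta_z_pairs)
    return ReportBundle(
        config=config,
        data=balanced,
        z_data=z_data,
        qc=qc,
        omnibus=omnibus,
        oneway=oneway,
        summaries=summaries,
        ranking=ranking,
        n_dropped_subjects=n_before - balanced.n_subjects,
    )


def _omnibus_frame(omnibus: TwoWayResult) -> pd.DataFrame:
    rows = [r.as_dict() for r in omnibus]
    frame = pd.DataFrame(rows)
    frame["p_uncorrected_display"] = frame["p_uncorrected"].round(3)
    frame["p_gg_display"] = frame["p_gg"].round(3)
    return frame


def write_reports(bundle: ReportBundle, out_dir, seed: int | None = None) -> dict[str, Path]:
    """Write the QC, omnibus, sensitivity and ranking reports to ``out_dir``.

    Returns a name -> path map of everything written. Reports embed the
    package version and a hash of the configuration; byte-identical for
    identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "package": "zsens",
        "version": __version__,
        "config_hash": bundle.config.hash(),
        "alpha": bundle.config.alpha,
        "seed": seed,
        "n_subjects": bundle.data.n_subjects,
        "n_sessions": bundle.data.n_sessions,
        "n_measures": len(bundle.data.measures),
        "n_dropped_subjects": bundle.n_dropped_subjects,
    }
    paths: dict[str, Path] = {}

    paths["qc"] = out / "qc.csv"
    qc_report_frame(bundle.qc).to_csv(paths["qc"], index=False)

    paths["omnibus"] = out / "omnibus.csv"
    _omnibus_frame(bundle.omnibus).to_csv(paths["omnibus"], index=False)

    paths["sensitivity"] = out / "sensitivity.csv"
    table = sensitivity_table(bundle.summaries)
    # full precision retained; add 3-decimal display columns for p-values
    for col in [c for c in table.columns if c.endswith("_p") or c == "oneway_p"]:
        table[f"{col}_display"] = table[col].round(3)
    table.to_csv(paths["sensitivity"], index=False)

    paths["ranking"] = out / "ranking.json"
    ranking_payload = {
        "meta": meta,
        "key": "(oneway_significant, n_sig_contrasts + n_sig_pairwise, max_delta_z)",
        "ranking": [
            {"measure": m, "rank": rank, "key": list(key)}
            for m, rank, key in bundle.ranking.entries
        ],
    }
    paths["ranking"].write_text(json.dumps(ranking_payload, indent=2) + "\n")

    paths["log"] = out / "run_log.txt"
    lines = [f"{k}: {v}" for k, v in meta.items()]
    lines.append(f"qc_all_passed: {all(r.passed for r in bundle.qc)}")
    paths["log"].write_text("\n".join(lines) + "\n")
    return paths
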