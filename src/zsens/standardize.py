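"""Pooled z-score standardization and the standardization QC gate.

Measures collected in different native units (seconds, questionnaire points,
ug/dL ...) cannot be compared directly. Each measure's observations are
pooled over *all* subjects and sessions — deliberately ignoring the
repeated-measures structure — to form a grand mean and grand SD, and every
value is re-expressed as ``z = (X - mean) / sd``. After the transform every
measure sits on the same unitless scale with mean 0 and SD 1.

Because z-scoring is a positive affine map, it cannot change any ANOVA F or
p statistic; :func:`qc_equivalence_check` verifies exactly that, measure by
measure, before any cross-measure analysis is trusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import StudyData, to_wide
from .exceptions import ConsistencyError, DegenerateMeasureError
from .rm_anova import rm_anova_oneway

#: "identical F and p" is interpreted as equality up to float round-off
QC_TOL = 1e-9


@dataclass(frozen=True)
class StandardizationRecord:
    """Grand mean and SD used to z-score one measure."""

    measure: str
    grand_mean: float
    grand_sd: float
    n_pooled: int


@dataclass(frozen=True)
class QCReport:
    """Raw-vs-z ANOVA equivalence check for one measure."""

    measure: str
    F_raw: float
    F_z: float
    p_raw: float
    p_z: float
    max_abs_F_diff: float
    max_abs_p_diff: float
    z_mean: float
    z_sd: float
    passed: bool


def pool_and_standardize(
    data: StudyData, ddof: int = 1
) -> tuple[StudyData, list[StandardizationRecord]]:
    """Convert every measure to z-scores over its pooled observations.

    Parameters
    ----------
    data
        Balanced study data in native units.
    ddof
        Delta degrees of freedom for the grand SD. The default 1 (sample SD)
        is a convention only: both choices are positive affine maps, so all
        downstream F and p statistics are identical; only the z magnitudes
        differ by sqrt(n/(n-1)).

    Returns
    -------
    (z_data, records)
        The standardized StudyData and one :class:`StandardizationRecord`
        per measure.

    Raises
    ------
    DegenerateMeasureError
        If a measure has zero pooled variance (constant values).
    """
    frame = data.frame.copy()
    records: list[StandardizationRecord] = []
    for measure in data.measures:
        mask = frame["measure"] == measure
        x = frame.loc[mask, "value"].to_numpy()
        mean = float(x.mean())
        sd = float(x.std(ddof=ddof))
        if sd <= 0.0 or not np.isfinite(sd):
            raise DegenerateMeasureError(
                f"measure {measure!r} has zero pooled variance; cannot standardize"
            )
        frame.loc[mask, "value"] = (x - mean) / sd
        records.append(
            StandardizationRecord(
                measure=measure, grand_mean=mean, grand_sd=sd, n_pooled=len(x)
            )
        )
    return StudyData(frame=frame, measures=data.measures), records


def qc_equivalence_check(
    raw: StudyData,
    z: StudyData,
    alpha: float = 0.05,
    tol: float = QC_TOL,
    ddof: int = 1,
) -> list[QCReport]:
    """Verify that z-scoring left per-measure RM-ANOVA inference unchanged.

    For each measure, runs the one-way within-subject ANOVA across sessions
    on the raw and on the standardized data and requires F and p to agree
    within ``tol``, and the z-scores to have mean 0 and SD 1 within ``tol``.
    """
    if (
        raw.measures != z.measures
        or raw.subjects != z.subjects
        or raw.sessions != z.sessions
    ):
        raise ConsistencyError("raw and standardized data describe different designs")

    reports: list[QCReport] = []
    for measure in raw.measures:
        res_raw = rm_anova_oneway(to_wide(raw, measure), alpha=alpha)
        zmat = to_wide(z, measure)
        res_z = rm_anova_oneway(zmat, alpha=alpha)
        zvals = zmat.ravel()
        z_mean = float(zvals.mean())
        z_sd = float(zvals.std(ddof=ddof))  # same ddof convention as the transform
        f_diff = abs(res_raw.F - res_z.F)
        p_diff = abs(res_raw.p_uncorrected - res_z.p_uncorrected)
        passed = (
            f_diff <= tol * max(1.0, abs(res_raw.F))
            and p_diff <= tol
            and abs(z_mean) <= tol
            and abs(z_sd - 1.0) <= tol
        )
        reports.append(
            QCReport(
                measure=measure,
                F_raw=res_raw.F,
                F_z=res_z.F,
                p_raw=res_raw.p_uncorrected,
                p_z=res_z.p_uncorrected,
                max_abs_F_diff=f_diff,
                max_abs_p_diff=p_diff,
                z_mean=z_mean,
                z_sd=z_sd,
                passed=passed,
            )
        )
    return reports


def qc_report_frame(reports: list[QCReport]) -> pd.DataFrame:
    """QC reports as a DataFrame (one row per measure), ready for CSV."""
    return pd.DataFrame(
        [
            {
                "measure": r.measure,
                "F_raw": r.F_raw,
                "p_raw": r.p_raw,
                "F_z": r.F_z,
                "p_z": r.p_z,
                "z_mean": r.z_mean,
                "z_sd": r.z_sd,
                "passed": r.passed,
            }
            for r in reports
        ]
    )
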