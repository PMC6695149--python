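"""Long-format study data: reading, validation, completeness filtering, pivoting.

The central container is :class:`StudyData`, a validated long-format table
with one row per (subject, session, measure) cell. All statistical routines
in this package require a *balanced* design — every retained subject observed
at every session for every measure — which mirrors the complete-case rule of
multi-metric repeated-measures studies. Missing data are handled only by
listwise subject deletion (:func:`filter_complete_cases`); there is no
imputation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyDesignError,
    FormatError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject", "session", "measure", "value")


@dataclass(frozen=True)
class StudyData:
    """A validated long-format repeated-measures dataset.

    Parameters
    ----------
    frame
        DataFrame with columns ``subject`` (str), ``session`` (int, 1..T),
        ``measure`` (str) and ``value`` (float). At most one row per
        (subject, session, measure) key.
    measures
        Measure identifiers in canonical order (first appearance by default).
    """

    frame: pd.DataFrame
    measures: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.measures:
            object.__setattr__(
                self, "measures", tuple(self.frame["measure"].unique())
            )

    # -- basic design descriptors -------------------------------------------------
    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["subject"].unique()))

    @property
    def sessions(self) -> tuple[int, ...]:
        return tuple(sorted(self.frame["session"].unique()))

    @property
    def n_subjects(self) -> int:
        return self.frame["subject"].nunique()

    @property
    def n_sessions(self) -> int:
        return self.frame["session"].nunique()

    @property
    def n_measures(self) -> int:
        return len(self.measures)

    def is_balanced(self) -> bool:
        """True when every subject has exactly one value per (session, measure)."""
        expected = self.n_subjects * self.n_sessions * self.n_measures
        return len(self.frame) == expected

    def __len__(self) -> int:
        return len(self.frame)


def _validate_frame(frame: pd.DataFrame, source: str = "<frame>") -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"{source}: missing required column '{col}'")

    frame = frame.loc[:, list(REQUIRED_COLUMNS)].copy()
    frame["subject"] = frame["subject"].astype(str)
    frame["measure"] = frame["measure"].astype(str)

    for col, caster in (("session", "Int64"), ("value", float)):
        try:
            if col == "session":
                coerced = pd.to_numeric(frame[col], errors="coerce")
            else:
                coerced = pd.to_numeric(frame[col], errors="coerce")
        except (TypeError, ValueError) as exc:  # pragma: no cover - defensive
            raise ParseError(f"{source}: cannot parse column '{col}': {exc}")
        bad = coerced.isna() | ~np.isfinite(coerced.astype(float))
        if bad.any():
            row = int(frame.index[bad][0]) + 2  # 1-based + header line
            raise ParseError(
                f"{source}: non-numeric or non-finite '{col}' at file row {row}"
            )
        frame[col] = coerced

    non_int = frame["session"] != frame["session"].astype(int)
    if non_int.any():
        row = int(frame.index[non_int][0]) + 2
        raise ParseError(f"{source}: non-integer session at file row {row}")
    frame["session"] = frame["session"].astype(int)
    frame["value"] = frame["value"].astype(float)

    dup = frame.duplicated(subset=["subject", "session", "measure"])
    if dup.any():
        key = frame.loc[dup.idxmax(), ["subject", "session", "measure"]]
        raise ValidationError(
            "duplicate observation for (subject={}, session={}, measure={})".format(
                key["subject"], key["session"], key["measure"]
            )
        )

    # Re-index sessions to 1..T in label order when not already consecutive.
    labels = sorted(frame["session"].unique())
    canonical = list(range(1, len(labels) + 1))
    if labels != canonical:
        mapping = dict(zip(labels, canonical))
        warnings.warn(
            f"sessions {labels} re-indexed to 1..{len(labels)} in label order",
            stacklevel=2,
        )
        frame["session"] = frame["session"].map(mapping)

    return frame.reset_index(drop=True)


def from_frame(frame: pd.DataFrame, measures: tuple[str, ...] | None = None) -> StudyData:
    """Validate a raw DataFrame and wrap it as :class:`StudyData`."""
    validated = _validate_frame(frame)
    if measures is None:
        measures = tuple(validated["measure"].unique())
    else:
        unknown = set(validated["measure"].unique()) - set(measures)
        if unknown:
            raise ValidationError(f"measures not in supplied ordering: {sorted(unknown)}")
        measures = tuple(measures)
    return StudyData(frame=validated, measures=measures)


def read_long_csv(path) -> StudyData:
    """Read a long-format CSV (``subject,session,measure,value``).

    Sessions are coerced to integers, values to floats; duplicate
    (subject, session, measure) keys are rejected.
    """
    try:
        frame = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: cannot read CSV: {exc}") from exc
    validated = _validate_frame(frame, source=str(path))
    return StudyData(frame=validated)


def write_long_csv(data: StudyData, path) -> None:
    """Write a StudyData back to the standard long CSV dialect."""
    data.frame.to_csv(path, index=False)


def filter_complete_cases(data: StudyData) -> StudyData:
    """Drop every subject missing any (session, measure) cell.

    Implements the complete-case (listwise deletion) rule: only subjects
    with a full session x measure grid are retained. Raises
    :class:`EmptyDesignError` if no subject survives.
    """
    n_cells = data.n_sessions * len(data.measures)
    counts = data.frame.groupby("subject").size()
    complete = counts.index[counts == n_cells]
    dropped = counts.index.difference(complete)
    if len(complete) == 0:
        raise EmptyDesignError("no subject has complete data for every session and measure")
    if len(dropped):
        logger.info(
            "complete-case filter dropped %d of %d subjects: %s",
            len(dropped), len(counts), ", ".join(map(str, dropped)),
        )
    kept = data.frame[data.frame["subject"].isin(complete)].reset_index(drop=True)
    return StudyData(frame=kept, measures=data.measures)


def to_wide(data: StudyData, measure: str) -> np.ndarray:
    """Pivot one measure to a subjects x sessions value matrix.

    Rows are ordered by subject identifier, columns by session index.
    """
    if measure not in data.measures:
        raise KeyError(f"unknown measure: {measure!r}")
    sub = data.frame[data.frame["measure"] == measure]
    wide = sub.pivot(index="subject", columns="session", values="value")
    wide = wide.sort_index().reindex(columns=sorted(wide.columns))
    if wide.isna().any().any():
        raise ValidationError(f"measure {measure!r} is not balanced; filter complete cases first")
    return wide.to_numpy(dtype=float)


def to_cube(data: StudyData) -> np.ndarray:
    """Stack all measures into a subjects x sessions x measures array.

    Subject rows sorted by identifier, sessions by index, measures in
    ``data.measures`` order. Requires a balanced design.
    """
    mats = [to_wide(data, m) for m in data.measures]
    return np.stack(mats, axis=-1)


def from_cube(
    cube: np.ndarray,
    subjects=None,
    measures=None,
) -> StudyData:
    """Inverse of :func:`to_cube` — build StudyData from a balanced array."""
    n, t, m = cube.shape
    if subjects is None:
        subjects = [f"s{i+1:03d}" for i in range(n)]
    if measures is None:
        measures = [f"m{j+1:02d}" for j in range(m)]
    idx = pd.MultiIndex.from_product(
        [list(subjects), range(1, t + 1), list(measures)],
        names=["subject", "session", "measure"],
    )
    frame = pd.DataFrame({"value": cube.reshape(-1)}, index=idx).reset_index()
    return from_frame(frame, measures=tuple(measures))
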