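"""Cohort container, record validation and CSV I/O.

A cohort is one joint (hip or knee), one instrument, and one paired
observation per patient: pre-operative score, 6-month post-operative
score, the five-level transition answer ("Overall, how are the problems
now in the joint on which you had surgery, compared to before the
operation?"), age, gender, 12 comorbidity flags, and the data-collection
period. Analysis is complete-case: rows with missing or out-of-range
values are rejected with row-numbered diagnostics, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, SchemaError, ValidationError
from .instruments import INSTRUMENTS, InstrumentSpec

logger = logging.getLogger(__name__)

__all__ = [
    "TRANSITION_LEVELS",
    "IMPROVED_LEVELS",
    "STABLE_LEVEL",
    "COMORBIDITIES",
    "PERIODS",
    "JOINTS",
    "COLUMNS",
    "PatientRecord",
    "PairedCohort",
    "RowDiagnostic",
    "read_cohort",
    "write_cohort",
    "validate_frame",
    "stratify_by_transition",
]

TRANSITION_LEVELS: tuple[str, ...] = (
    "much better",
    "a little better",
    "about the same",
    "a little worse",
    "much worse",
)
#: levels counted as anchor-rated improvement ("total improved subjects")
IMPROVED_LEVELS: tuple[str, ...] = TRANSITION_LEVELS[:2]
#: the "stable" anchor level used by the responsiveness index
STABLE_LEVEL: str = "about the same"

COMORBIDITIES: tuple[str, ...] = (
    "heart_disease",
    "high_blood_pressure",
    "stroke",
    "circulation",
    "lung_disease",
    "diabetes",
    "kidney",
    "nervous_system",
    "liver_disease",
    "cancer",
    "depression",
    "arthritis",
)

PERIODS: tuple[str, ...] = ("2009-2011", "2012-2015")
JOINTS: tuple[str, ...] = ("hip", "knee")
GENDERS: tuple[str, ...] = ("male", "female")

COLUMNS: tuple[str, ...] = (
    "patient_id",
    "joint",
    "instrument",
    "pre_score",
    "post_score",
    "transition",
    "age",
    "gender",
    *COMORBIDITIES,
    "period",
)


@dataclass(frozen=True)
class PatientRecord:
    """One paired pre/post observation with its covariates."""

    patient_id: str
    joint: str
    pre_score: float
    post_score: float
    transition: str
    age: float
    gender: str
    comorbidities: dict[str, int]
    period: str

    @property
    def change_score(self) -> float:
        """Post minus pre; positive values are improvement."""
        return self.post_score - self.pre_score


@dataclass(frozen=True)
class RowDiagnostic:
    """Why a CSV row was rejected."""

    row: int  # 1-based data-row number (header excluded)
    reason: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}: {self.reason}"


@dataclass
class PairedCohort:
    """A validated complete-case cohort of paired observations.

    The records live in a :class:`pandas.DataFrame` with the canonical
    :data:`COLUMNS`; ``meta`` carries provenance (generator settings,
    clipping accounting, dropped-row counts).
    """

    df: pd.DataFrame
    instrument: InstrumentSpec
    joint: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValidationError(f"unknown joint {self.joint!r}")
        if len(self.df) == 0:
            raise EmptyCohortError("cohort has no records")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pre(self) -> np.ndarray:
        return self.df["pre_score"].to_numpy(dtype=float)

    @property
    def post(self) -> np.ndarray:
        return self.df["post_score"].to_numpy(dtype=float)

    @property
    def change(self) -> np.ndarray:
        """Change scores, derived (never stored) as post - pre."""
        return self.post - self.pre

    @property
    def transition(self) -> pd.Series:
        return self.df["transition"]

    def records(self) -> Iterator[PatientRecord]:
        for row in self.df.itertuples(index=False):
            yield PatientRecord(
                patient_id=str(row.patient_id),
                joint=row.joint,
                pre_score=float(row.pre_score),
                post_score=float(row.post_score),
                transition=row.transition,
                age=float(row.age),
                gender=row.gender,
                comorbidities={c: int(getattr(row, c)) for c in COMORBIDITIES},
                period=row.period,
            )

    def subset(self, mask: np.ndarray, **meta) -> "PairedCohort":
        return PairedCohort(
            self.df.loc[np.asarray(mask)].copy(),
            self.instrument,
            self.joint,
            {**self.meta, **meta},
        )


def _check_rows(df: pd.DataFrame, instrument: InstrumentSpec) -> list[RowDiagnostic]:
    """Vectorized row validation; returns one diagnostic per bad row."""
    bad: dict[int, str] = {}

    def flag(mask: pd.Series, reason: str) -> None:
        for idx in df.index[mask.to_numpy(dtype=bool)]:
            bad.setdefault(int(idx), reason)

    required = ["pre_score", "post_score", "transition", "age", "gender", "period"]
    flag(df[required].isna().any(axis=1), "missing required value")
    for col in ("pre_score", "post_score"):
        s = pd.to_numeric(df[col], errors="coerce")
        flag(s.isna() & df[col].notna(), f"{col} is not numeric")
        flag(~instrument.in_range(s.fillna(instrument.min_score)) & s.notna(),
             f"{col} outside [{instrument.min_score}, {instrument.max_score}]")
    flag(~df["transition"].isin(TRANSITION_LEVELS) & df["transition"].notna(),
         "unknown transition level")
    flag(~df["gender"].isin(GENDERS) & df["gender"].notna(), "unknown gender")
    flag(~df["period"].isin(PERIODS) & df["period"].notna(), "unknown period")
    age = pd.to_numeric(df["age"], errors="coerce")
    flag((age < 0) | (age > 120), "implausible age")
    for c in COMORBIDITIES:
        v = pd.to_numeric(df[c], errors="coerce")
        flag(v.isna() | ~v.isin([0, 1]), f"{c} flag must be 0/1")
    return [RowDiagnostic(i + 1, reason) for i, reason in sorted(bad.items())]


def validate_frame(
    df: pd.DataFrame, instrument: InstrumentSpec
) -> tuple[pd.DataFrame, list[RowDiagnostic]]:
    """Validate a raw frame; return (clean frame, diagnostics for dropped rows)."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")
    df = df.reset_index(drop=True)
    diagnostics = _check_rows(df, instrument)
    drop = [d.row - 1 for d in diagnostics]
    clean = df.drop(index=drop).reset_index(drop=True)
    if len(clean):
        clean = clean.astype(
            {"pre_score": float, "post_score": float, "age": float,
             **{c: int for c in COMORBIDITIES}}
        )
    return clean, diagnostics


def read_cohort(path, instrument: InstrumentSpec | None = None) -> PairedCohort:
    """Read and validate a cohort CSV.

    Rows failing range or invariant checks are dropped with row-numbered
    diagnostics (logged and stored under ``meta["diagnostics"]``). The
    instrument is taken from the file's ``instrument`` column unless given
    explicitly.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype={"patient_id": str})
    except pd.errors.EmptyDataError as exc:
        raise EmptyCohortError(f"{path}: file is empty") from exc
    if instrument is None:
        if "instrument" not in raw.columns:
            raise SchemaError(f"{path}: missing required columns: instrument")
        names = raw["instrument"].dropna().unique()
        if len(names) != 1:
            raise SchemaError(f"{path}: expected one instrument, found {list(names)}")
        try:
            instrument = INSTRUMENTS[str(names[0])]
        except KeyError as exc:
            raise SchemaError(f"{path}: unknown instrument {names[0]!r}") from exc
    clean, diagnostics = validate_frame(raw, instrument)
    if diagnostics:
        logger.warning("%s: dropped %d invalid row(s)", path, len(diagnostics))
        for d in diagnostics:
            logger.warning("%s: %s", path, d)
    if len(clean) == 0:
        raise EmptyCohortError(f"{path}: no valid records after validation")
    joints = clean["joint"].unique()
    if len(joints) != 1:
        raise SchemaError(f"{path}: expected one joint, found {list(joints)}")
    return PairedCohort(
        clean,
        instrument,
        str(joints[0]),
        meta={"source": str(path), "n_dropped": len(diagnostics),
              "diagnostics": [str(d) for d in diagnostics]},
    )


def write_cohort(cohort: PairedCohort, path) -> None:
    """Write a cohort CSV (UTF-8, comma-separated, header row).

    Scores are serialized at the instrument resolution (3 decimals for the
    EQ-5D-3L index, integers for Oxford scores) so that a write/read
    round-trip reproduces every field exactly.
    """
    df = cohort.df.copy()
    dec = cohort.instrument.decimals
    for col in ("pre_score", "post_score"):
        if dec == 0:
            df[col] = df[col].round().astype(int)
        else:
            df[col] = df[col].map(lambda v: f"{v:.{dec}f}")
    df["age"] = df["age"].map(lambda v: f"{v:g}")
    df[list(COLUMNS)].to_csv(path, index=False)


def stratify_by_transition(
    cohort: PairedCohort, drop_empty: bool = False
) -> dict[str, PairedCohort | None]:
    """Partition a cohort by transition level.

    Returns a mapping over all five levels in anchor order; empty strata
    map to ``None`` (or are omitted with ``drop_empty=True``). Strata are
    disjoint and exhaustive: their sizes sum to the cohort size.
    """
    out: dict[str, PairedCohort | None] = {}
    for level in TRANSITION_LEVELS:
        mask = (cohort.transition == level).to_numpy()
        if mask.any():
            out[level] = cohort.subset(mask, stratum=level)
        elif not drop_empty:
            out[level] = None
    return out
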