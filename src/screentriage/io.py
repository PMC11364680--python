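"""Visit-table data model and tabular I/O for screening cohorts.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per mammogram visit ("visit table"); :class:`VisitRecord` is the single-row
view of the same schema. Dates are held at month resolution
(``pandas.Period`` with monthly frequency) because every downstream quantity
— screening intervals, interval-cancer windows, lead times — is counted in
whole months.

Columns
-------
visit_id, woman_id : str
    Opaque identifiers.
visit_date : Period[M]
    Calendar month of the mammogram.
ai_score : float in [0, 100]
    Per-visit AI risk score (the maximum over both breasts, already
    collapsed upstream).
birads : int in {0..5}
    Radiologist BI-RADS assessment.
reader_detected : bool
    Final recall decision of the (double-) reading.
is_cancer_visit : bool
    Visit at / leading to histopathology-proven cancer.
detection_mode : {"screen_detected", "interval", "missed", "none"}
    How the cancer was found; ``none`` iff not a cancer visit.
diagnosis_date : Period[M] or NaT (optional)
    Month of histopathological diagnosis for cancer visits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

DETECTION_MODES = ("screen_detected", "interval", "missed", "none")

REQUIRED_COLUMNS = (
    "visit_id",
    "woman_id",
    "visit_date",
    "ai_score",
    "birads",
    "reader_detected",
    "is_cancer_visit",
    "detection_mode",
)

#: Full canonical column order; ``diagnosis_date`` is optional on input.
VISIT_COLUMNS = REQUIRED_COLUMNS + ("diagnosis_date",)


@dataclass(frozen=True)
class VisitRecord:
    """One mammogram event."""

    visit_id: str
    woman_id: str
    visit_date: pd.Period
    ai_score: float
    birads: int
    reader_detected: bool
    is_cancer_visit: bool
    detection_mode: str
    diagnosis_date: Optional[pd.Period] = None


def dichotomize_birads(birads):
    """Collapse BI-RADS categories to a reader-positive boolean.

    Categories 1 and 2 are negative; 0, 3, 4 and 5 are positive (0 means
    incomplete and triggers further workup, hence positive). Accepts a
    scalar or an array-like; returns a bool or a bool array.
    """
    arr = np.asarray(birads)
    if arr.dtype.kind not in "iu":
        try:
            arr = arr.astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"birads must be integers in 0..5: {exc}") from exc
    bad = ~np.isin(arr, np.arange(6))
    if bad.any():
        raise ValidationError(
            f"birads values outside 0..5: {np.unique(np.atleast_1d(arr)[np.atleast_1d(bad)])}"
        )
    positive = ~np.isin(arr, (1, 2))
    if np.isscalar(birads) or arr.ndim == 0:
        return bool(positive)
    return positive


def _to_period(values, column: str) -> pd.PeriodIndex:
    try:
        if isinstance(getattr(values, "dtype", None), pd.PeriodDtype):
            return pd.PeriodIndex(values, freq="M")
        if len(values) and isinstance(next(iter(np.asarray(values, dtype=object))), pd.Period):
            return pd.PeriodIndex(list(values), freq="M")
        return pd.PeriodIndex(pd.to_datetime(values, format="mixed"), freq="M")
    except (TypeError, ValueError, pd.errors.ParserError) as exc:
        raise ValidationError(f"column {column!r} is not parseable as year-month: {exc}") from exc


def _to_bool(series: pd.Series, column: str) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        idx = int(out.index[out.isna()][0])
        raise ValidationError(f"column {column!r} has a non-boolean value at row {idx}")
    return out.astype(bool)


def validate_visits(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a visit table.

    Returns a copy in canonical column order and dtypes. Unknown columns
    are dropped with a logged warning. Raises :class:`SchemaError` for
    missing columns and :class:`ValidationError` (naming the first
    offending row) for invariant violations.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in VISIT_COLUMNS]
    if extra:
        logger.warning("ignoring unknown column(s): %s", ", ".join(extra))

    out = pd.DataFrame(index=pd.RangeIndex(len(df)))
    src = df.reset_index(drop=True)
    out["visit_id"] = src["visit_id"].astype(str)
    out["woman_id"] = src["woman_id"].astype(str)
    out["visit_date"] = _to_period(src["visit_date"], "visit_date")

    score = pd.to_numeric(src["ai_score"], errors="coerce")
    bad = score.isna() | (score < 0) | (score > 100)
    if bad.any():
        idx = int(bad.idxmax())
        raise ValidationError(
            f"ai_score out of range [0, 100] at row {idx}: {src['ai_score'].iloc[idx]!r}"
        )
    out["ai_score"] = score.astype(float)

    birads = pd.to_numeric(src["birads"], errors="coerce")
    bad = birads.isna() | ~birads.isin(range(6))
    if bad.any():
        idx = int(bad.idxmax())
        raise ValidationError(f"birads outside 0..5 at row {idx}: {src['birads'].iloc[idx]!r}")
    out["birads"] = birads.astype(int)

    out["reader_detected"] = _to_bool(src["reader_detected"], "reader_detected")
    out["is_cancer_visit"] = _to_bool(src["is_cancer_visit"], "is_cancer_visit")

    mode = src["detection_mode"].astype(str).str.strip()
    bad = ~mode.isin(DETECTION_MODES)
    if bad.any():
        idx = int(bad.idxmax())
        raise ValidationError(f"unknown detection_mode at row {idx}: {mode.iloc[idx]!r}")
    out["detection_mode"] = mode

    if "diagnosis_date" in src.columns:
        raw = src["diagnosis_date"]
        has = raw.notna() & (raw.astype(str).str.strip() != "")
        diag = pd.Series(pd.NaT, index=out.index, dtype="period[M]")
        if has.any():
            diag[has] = _to_period(raw[has], "diagnosis_date")
        out["diagnosis_date"] = diag
    else:
        out["diagnosis_date"] = pd.Series(pd.NaT, index=out.index, dtype="period[M]")

    # cross-field invariants
    mode_none = out["detection_mode"] == "none"
    bad = mode_none != ~out["is_cancer_visit"]
    if bad.any():
        idx = int(bad.idxmax())
        raise ValidationError(
            f"detection_mode 'none' must coincide with is_cancer_visit=False (row {idx})"
        )
    bad = (out["detection_mode"] == "screen_detected") & ~out["reader_detected"]
    if bad.any():
        idx = int(bad.idxmax())
        raise ValidationError(f"screen-detected cancer with reader_detected=False (row {idx})")
    bad = out["detection_mode"].isin(("interval", "missed")) & out["reader_detected"]
    if bad.any():
        idx = int(bad.idxmax())
        raise ValidationError(f"interval/missed cancer with reader_detected=True (row {idx})")

    return out


def read_visits(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a delimited visit table from *path* and validate it.

    Row order is preserved. The header row names the columns; unknown
    columns are ignored with a warning.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    raw = raw.replace({"": None}) if "diagnosis_date" in raw.columns else raw
    return validate_visits(raw)


def write_visits(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a visit table to *path* (header row, one visit per row)."""
    out = df.copy()
    out["visit_date"] = out["visit_date"].astype(str)
    diag = out["diagnosis_date"]
    out["diagnosis_date"] = diag.astype(str).where(diag.notna(), "")
    out.to_csv(path, sep=delimiter, index=False)


def to_records(df: pd.DataFrame) -> list[VisitRecord]:
    """View a validated visit table as a list of :class:`VisitRecord`."""
    return [
        VisitRecord(
            visit_id=row.visit_id,
            woman_id=row.woman_id,
            visit_date=row.visit_date,
            ai_score=row.ai_score,
            birads=row.birads,
            reader_detected=row.reader_detected,
            is_cancer_visit=row.is_cancer_visit,
            detection_mode=row.detection_mode,
            diagnosis_date=None if pd.isna(row.diagnosis_date) else row.diagnosis_date,
        )
        for row in df.itertuples(index=False)
    ]


def from_records(records: Iterable[VisitRecord]) -> pd.DataFrame:
    """Build a validated visit table from :class:`VisitRecord` objects."""
    rows = [
        {
            "visit_id": r.visit_id,
            "woman_id": r.woman_id,
            "visit_date": r.visit_date,
            "ai_score": r.ai_score,
            "birads": r.birads,
            "reader_detected": r.reader_detected,
            "is_cancer_visit": r.is_cancer_visit,
            "detection_mode": r.detection_mode,
            "diagnosis_date": r.diagnosis_date,
        }
        for r in records
    ]
    return validate_visits(pd.DataFrame(rows, columns=VISIT_COLUMNS))
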