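"""Domain types and CSV I/O for the three record streams.

The audit links three tabular streams: the *reference* stream exported by
the meter-docking interface (one row per point-of-care glucose test, the
value the meter actually measured), and two hand-transcribed documentation
streams (a paper log kept by technicians and the EMR vital-signs flow
sheet kept by nurses). A patient-episode table supplies admission
boundaries and demographics; each admission episode is keyed by a visit
identification number (VIN), the only linkage key used.

All glucose values are integer mg/dL (meters report integers); mmol/L is
a display conversion only. Datetimes are timezone-naive local clock, as
they appear in single-site hospital logs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from datetime import datetime, time
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .errors import ConfigError, RowValidationError, SchemaError

MGDL_PER_MMOL = 18.016
#: Default meter reportable range, mg/dL (inclusive).
REPORTABLE_RANGE = (10, 600)

SEXES = ("male", "female", "unknown")
DIABETES = ("yes", "no", "unknown")
SOURCES = ("paper_log", "flow_sheet")

Source = Literal["paper_log", "flow_sheet"]


@dataclass
class PatientEpisode:
    """One admission episode, keyed by VIN."""

    vin: str
    age: int
    sex: str
    diabetes: str
    admit: datetime
    discharge: datetime

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.diabetes not in DIABETES:
            raise ValueError(f"diabetes must be one of {DIABETES}, got {self.diabetes!r}")
        if not self.admit < self.discharge:
            raise ValueError(f"admit {self.admit} not before discharge {self.discharge}")


@dataclass
class MeterRecord:
    """A reference glucose result as stored in the meter / docking database."""

    record_id: str
    vin: str
    test_time: datetime
    glucose_mgdl: int
    operator_id: str
    dock_time: Optional[datetime] = None

    def validate(self, reportable_range: tuple[int, int] = REPORTABLE_RANGE) -> None:
        lo, hi = reportable_range
        if not lo <= self.glucose_mgdl <= hi:
            raise ValueError(
                f"glucose {self.glucose_mgdl} outside reportable range [{lo}, {hi}]"
            )
        if self.dock_time is not None and self.dock_time < self.test_time:
            raise ValueError(
                f"dock_time {self.dock_time} precedes test_time {self.test_time}"
            )


@dataclass
class TranscribedEntry:
    """A hand-copied glucose value in one of the two documentation streams."""

    entry_id: str
    source: str
    vin: str
    entry_time: datetime
    value_mgdl: int

    def validate(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        if self.value_mgdl <= 0:
            raise ValueError(f"value_mgdl must be positive, got {self.value_mgdl}")


@dataclass(frozen=True)
class ShiftConfig:
    """Two clock times partitioning 24 h into a day and a night shift.

    Both intervals are half-open: the boundary instant belongs to the
    shift it opens. Defaults model standard 12-hour nursing shifts.
    """

    day_start: time = time(7, 0)
    night_start: time = time(19, 0)

    def __post_init__(self) -> None:
        if self.day_start == self.night_start:
            raise ConfigError("shift boundaries must be distinct")


def assign_shift(t: datetime, shift: ShiftConfig = ShiftConfig()) -> str:
    """Label a timestamp ``day`` or ``night`` under half-open shift intervals."""
    clock = t.time()
    a, b = shift.day_start, shift.night_start
    if a < b:
        return "day" if a <= clock < b else "night"
    # day shift wraps midnight
    return "day" if (clock >= a or clock < b) else "night"


def mgdl_to_mmol(v: float) -> float:
    """Convert mg/dL to mmol/L, rounded half-up to one decimal.

    The divisor 18.016 is the molar mass of glucose scaled to dL;
    half-up rounding reproduces the pairs printed in clinical reports.
    """
    if v < 0:
        raise ValueError(f"glucose cannot be negative, got {v}")
    return float(Decimal(v / MGDL_PER_MMOL).quantize(Decimal("0.1"), ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

SCHEMAS = {
    "meter": ["record_id", "vin", "test_time", "glucose_mgdl", "operator_id", "dock_time"],
    "entry": ["entry_id", "source", "vin", "entry_time", "value_mgdl"],
    "episode": ["vin", "age", "sex", "diabetes", "admit", "discharge"],
}

_TYPES = {"meter": MeterRecord, "entry": TranscribedEntry, "episode": PatientEpisode}
_DT_COLS = {
    "meter": ["test_time", "dock_time"],
    "entry": ["entry_time"],
    "episode": ["admit", "discharge"],
}
_INT_COLS = {"meter": ["glucose_mgdl"], "entry": ["value_mgdl"], "episode": ["age"]}


def _parse_dt(raw: str, optional: bool) -> Optional[datetime]:
    if raw is None or raw == "" or (isinstance(raw, float) and pd.isna(raw)):
        if optional:
            return None
        raise ValueError("missing datetime")
    return datetime.fromisoformat(str(raw))


def read_stream(path, schema: str) -> list:
    """Read and validate one CSV stream into its domain type.

    Parameters
    ----------
    path : path-like
        CSV file with a header matching the schema exactly.
    schema : {"meter", "entry", "episode"}

    Raises
    ------
    SchemaError
        Missing or extra columns (the offending columns are named).
    RowValidationError
        Any row with an unparseable datetime, non-numeric glucose, or a
        domain-invariant violation; all bad rows are collected and
        reported together rather than dropped.
    """
    if schema not in SCHEMAS:
        raise ConfigError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = SCHEMAS[schema]
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{schema} schema mismatch: missing columns {missing}, extra columns {extra}"
        )

    cls = _TYPES[schema]
    dt_cols = _DT_COLS[schema]
    int_cols = _INT_COLS[schema]
    out, problems = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        kw = dict(zip(df.columns, row))
        try:
            for c in dt_cols:
                kw[c] = _parse_dt(kw[c], optional=(c == "dock_time"))
            for c in int_cols:
                try:
                    kw[c] = int(kw[c])
                except (TypeError, ValueError):
                    raise ValueError(f"non-integer value {kw[c]!r} in column {c}")
            rec = cls(**kw)
            rec.validate()
            out.append(rec)
        except (ValueError, TypeError) as exc:
            problems.append((i, str(exc)))
    if problems:
        raise RowValidationError(problems)
    return out


def write_stream(records: Sequence, path, schema: str) -> None:
    """Write a record collection back to CSV; inverse of :func:`read_stream`."""
    if schema not in SCHEMAS:
        raise ConfigError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    cols = SCHEMAS[schema]
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(r)}
        for k, v in d.items():
            if isinstance(v, datetime):
                d[k] = v.isoformat(sep=" ")
            elif v is None:
                d[k] = ""
        rows.append(d)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def to_frame(records: Iterable) -> pd.DataFrame:
    """Record collection as a pandas DataFrame (datetimes kept native)."""
    recs = list(records)
    if not recs:
        return pd.DataFrame()
    cols = [f.name for f in fields(recs[0])]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in recs])
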