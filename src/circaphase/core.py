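"""Shared domain types, clock-phase arithmetic, and delimited-text I/O.

Everything downstream (preprocessing, cosinor fitting, DLMO, the activity
HMM, and the bathyphase regression) works on two primitives defined here:

* :class:`TimeSeries` — a strictly increasing, minute-resolution sequence of
  timestamped physiological measurements carrying a single unit tag.
* :class:`ClockPhase` — a time of day represented on the *unwrapped* interval
  [12, 36) anchored at the preceding noon, so that nocturnal phases (core
  temperature bathyphase near 03:30, center of rest near 03:05) form a
  contiguous cluster and regression over phases never straddles midnight.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VALID_UNITS",
    "TimeSeries",
    "ClockPhase",
    "SubjectRecord",
    "to_clock_phase",
    "canonical_hours",
    "circular_distance",
    "circular_signed_diff",
    "categorize_chronotype",
    "read_timeseries",
    "write_timeseries",
    "read_subjects",
    "write_subjects",
    "PHASE_TABLE_COLUMNS",
    "validate_phase_table",
    "FormatError",
    "ValidationError",
]

VALID_UNITS = frozenset({"degC", "counts_per_min", "lux", "pg_per_mL"})


class FormatError(ValueError):
    """A delimited-text file does not have the expected layout."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant."""


# ---------------------------------------------------------------------------
# Clock-phase arithmetic
# ---------------------------------------------------------------------------

def canonical_hours(hours: float) -> float:
    """Map any decimal-hour value onto the canonical window [12, 36).

    The window is anchored at the prior noon: 03:30 becomes 27.5 while
    17:40 stays 17.667.  All phases in the package live on this axis.
    """
    return float(np.mod(float(hours) - 12.0, 24.0) + 12.0)


def circular_signed_diff(a: "float | ClockPhase", b: "float | ClockPhase") -> float:
    """Signed circular difference a - b in hours, in (-12, 12]."""
    ah = a.hours if isinstance(a, ClockPhase) else float(a)
    bh = b.hours if isinstance(b, ClockPhase) else float(b)
    d = (ah - bh) % 24.0
    if d > 12.0:
        d -= 24.0
    return float(d)


def circular_distance(a: "float | ClockPhase", b: "float | ClockPhase") -> float:
    """Unsigned circular distance in hours; always in [0, 12]."""
    return abs(circular_signed_diff(a, b))


@dataclass(frozen=True, order=False)
class ClockPhase:
    """A time of day in decimal hours on the unwrapped window [12, 36)."""

    hours: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "hours", canonical_hours(self.hours))

    @classmethod
    def from_clock(cls, hour: int, minute: int = 0, second: float = 0.0) -> "ClockPhase":
        return cls(hour + minute / 60.0 + second / 3600.0)

    @classmethod
    def from_string(cls, text: str) -> "ClockPhase":
        parts = text.strip().split(":")
        if not 1 <= len(parts) <= 3:
            raise ValidationError(f"cannot parse clock time {text!r}")
        nums = [float(p) for p in parts] + [0.0, 0.0]
        return cls.from_clock(int(nums[0]), int(nums[1]), nums[2])

    @property
    def clock_hours(self) -> float:
        """Time of day in [0, 24)."""
        return self.hours % 24.0

    def as_clock_string(self) -> str:
        total_min = round(self.clock_hours * 60.0) % (24 * 60)
        return f"{total_min // 60:02d}:{total_min % 60:02d}"

    def signed_diff(self, other: "float | ClockPhase") -> float:
        return circular_signed_diff(self, other)

    def distance(self, other: "float | ClockPhase") -> float:
        return circular_distance(self, other)

    def shifted(self, delta_hours: float) -> "ClockPhase":
        return ClockPhase(self.hours + delta_hours)

    def __float__(self) -> float:
        return self.hours

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ClockPhase({self.hours:.4f} h = {self.as_clock_string()})"


def to_clock_phase(time_of_day) -> ClockPhase:
    """Convert a time of day (``"HH:MM"``, ``datetime.time``, datetime-like,
    or decimal hours) to a :class:`ClockPhase`."""
    if isinstance(time_of_day, ClockPhase):
        return time_of_day
    if isinstance(time_of_day, str):
        return ClockPhase.from_string(time_of_day)
    if isinstance(time_of_day, _dt.time):
        return ClockPhase.from_clock(time_of_day.hour, time_of_day.minute,
                                     time_of_day.second + time_of_day.microsecond / 1e6)
    if isinstance(time_of_day, (_dt.datetime, pd.Timestamp)):
        t = pd.Timestamp(time_of_day)
        return ClockPhase.from_clock(t.hour, t.minute, t.second + t.microsecond / 1e6)
    return ClockPhase(float(time_of_day))


# ---------------------------------------------------------------------------
# TimeSeries
# ---------------------------------------------------------------------------

@dataclass
class TimeSeries:
    """Timestamped, unit-tagged minute-level measurements with gaps allowed.

    Timestamps must be strictly increasing; gaps are represented by absent
    rows, never imputed at this layer.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    unit: str
    subject_id: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unknown unit tag {self.unit!r}; expected one of {sorted(VALID_UNITS)}")
        if len(self.timestamps) != len(self.values):
            raise ValidationError("timestamps and values differ in length")
        if len(self.timestamps) > 1:
            diffs = np.diff(self.timestamps.asi8)
            bad = np.nonzero(diffs <= 0)[0]
            if bad.size:
                i = int(bad[0]) + 1
                raise ValidationError(
                    f"timestamps not strictly increasing at row {i} "
                    f"({self.timestamps[i]!s} after {self.timestamps[i - 1]!s})"
                )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def span_hours(self) -> float:
        if len(self) < 2:
            return 0.0
        return float((self.timestamps[-1] - self.timestamps[0]) / pd.Timedelta(hours=1))

    def hours_since(self, anchor: pd.Timestamp) -> np.ndarray:
        """Elapsed decimal hours of each sample since ``anchor``."""
        return (self.timestamps.asi8 - pd.Timestamp(anchor).value) / 3.6e12

    def clock_hours(self) -> np.ndarray:
        """Clock time of day of each sample, decimal hours in [0, 24)."""
        t = self.timestamps
        return (t.hour + t.minute / 60.0 + t.second / 3600.0
                + t.microsecond / 3.6e9).to_numpy(dtype=float)

    def replace(self, **kwargs) -> "TimeSeries":
        return dataclasses.replace(self, **kwargs)

    def slice_time(self, start=None, stop=None) -> "TimeSeries":
        mask = np.ones(len(self), dtype=bool)
        if start is not None:
            mask &= self.timestamps >= pd.Timestamp(start)
        if stop is not None:
            mask &= self.timestamps < pd.Timestamp(stop)
        return self.replace(timestamps=self.timestamps[mask], values=self.values[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timestamp": self.timestamps,
            "value": self.values,
            "subject_id": self.subject_id,
        })

    def concat(self, other: "TimeSeries") -> "TimeSeries":
        if other.unit != self.unit:
            raise ValidationError(
                f"cannot concatenate series with units {self.unit!r} and {other.unit!r}")
        ts = self.timestamps.append(other.timestamps)
        return TimeSeries(ts, np.concatenate([self.values, other.values]),
                          self.unit, self.subject_id, self.channel)


def read_timeseries(path, channel: str = "", unit: str | None = None,
                    subject_id: str | None = None) -> TimeSeries:
    """Read a TimeSeries from delimited text (CSV with header).

    Required columns: ``timestamp``, ``value``, ``subject_id``.  Optional
    columns ``unit`` and ``channel`` override the keyword arguments.  Rows
    with unparseable timestamps are dropped (and counted); non-monotone
    timestamps raise :class:`ValidationError` naming the first offending row.
    """
    df = pd.read_csv(path)
    required = {"timestamp", "value", "subject_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    ok = ts.notna().to_numpy()
    df = df.loc[ok]
    ts = ts[ok]
    if unit is None:
        unit = str(df["unit"].iloc[0]) if "unit" in df.columns and len(df) else "degC"
    if not channel and "channel" in df.columns and len(df):
        channel = str(df["channel"].iloc[0])
    if subject_id is None:
        subject_id = str(df["subject_id"].iloc[0]) if len(df) else ""
    return TimeSeries(pd.DatetimeIndex(ts), df["value"].to_numpy(dtype=float),
                      unit, subject_id, channel)


def write_timeseries(series: TimeSeries, path) -> None:
    """Write a TimeSeries as CSV with ISO-8601 timestamps (read_timeseries inverse)."""
    df = series.to_frame()
    df["unit"] = series.unit
    df["channel"] = series.channel
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Subjects and chronotype
# ---------------------------------------------------------------------------

#: Horne–Östberg morningness–eveningness bands on the 16–86 score range.
CHRONOTYPE_BANDS = ((16, 41, "evening"), (42, 58, "intermediate"), (59, 86, "morning"))


def categorize_chronotype(score: int) -> str:
    """Map a morningness–eveningness questionnaire score to its category.

    Bands: 16–41 evening, 42–58 intermediate, 59–86 morning.
    """
    s = int(score)
    if s != score or not 16 <= s <= 86:
        raise ValidationError(f"chronotype score {score!r} outside the 16–86 questionnaire range")
    for lo, hi, cat in CHRONOTYPE_BANDS:
        if lo <= s <= hi:
            return cat
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass
class SubjectRecord:
    """Per-subject covariates: sex is coded 1 for male and 0 for female."""

    subject_id: str
    sex: int
    age: float
    bmi: float
    chronotype_score: int
    concurrent_treatment: bool = False
    chronotype_category: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValidationError(f"sex must be coded 0 (female) or 1 (male), got {self.sex!r}")
        expected = categorize_chronotype(self.chronotype_score)
        if not self.chronotype_category:
            self.chronotype_category = expected
        elif self.chronotype_category != expected:
            raise ValidationError(
                f"chronotype_category {self.chronotype_category!r} inconsistent with "
                f"score {self.chronotype_score} ({expected})")


SUBJECT_COLUMNS = ["subject_id", "sex", "age", "bmi", "chronotype_score",
                   "chronotype_category", "concurrent_treatment"]


def read_subjects(path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    missing = set(SUBJECT_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(SubjectRecord(
            subject_id=str(row["subject_id"]), sex=int(row["sex"]),
            age=float(row["age"]), bmi=float(row["bmi"]),
            chronotype_score=int(row["chronotype_score"]),
            concurrent_treatment=bool(row.get("concurrent_treatment", False)),
        ))
    return out


def write_subjects(subjects: Iterable[SubjectRecord], path) -> None:
    rows = [{c: getattr(s, c) for c in SUBJECT_COLUMNS} for s in subjects]
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PhaseTable
# ---------------------------------------------------------------------------

PHASE_TABLE_COLUMNS = [
    "subject_id", "dlmo",
    "core_acrophase", "core_acro_ci_lo", "core_acro_ci_hi",
    "core_bathyphase", "core_bathy_ci_lo", "core_bathy_ci_hi",
    "chest_acrophase", "chest_acro_ci_lo", "chest_acro_ci_hi",
    "chest_bathyphase", "chest_bathy_ci_lo", "chest_bathy_ci_hi",
    "center_of_rest", "dominant_period_class",
]

_CI_TRIPLES = [
    ("core_acrophase", "core_acro_ci_lo", "core_acro_ci_hi"),
    ("core_bathyphase", "core_bathy_ci_lo", "core_bathy_ci_hi"),
    ("chest_acrophase", "chest_acro_ci_lo", "chest_acro_ci_hi"),
    ("chest_bathyphase", "chest_bathy_ci_lo", "chest_bathy_ci_hi"),
]


def validate_phase_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check PhaseTable invariants; missing entries must be explicit NaN.

    Every confidence interval must contain its point estimate under circular
    distance; phases are stored in unwrapped decimal hours.
    """
    missing = set(PHASE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"phase table missing column(s) {sorted(missing)}")
    for point, lo, hi in _CI_TRIPLES:
        sub = df[[point, lo, hi]].dropna()
        for _, row in sub.iterrows():
            # interval given as an arc from lo to hi (possibly wrapping)
            arc = (row[hi] - row[lo]) % 24.0
            pos = (row[point] - row[lo]) % 24.0
            if pos > 24.0 - 1e-6:   # point == lo up to float wrap
                pos = 0.0
            if pos > arc + 1e-9:
                raise ValidationError(
                    f"CI [{row[lo]:.3f}, {row[hi]:.3f}] does not contain {point} "
                    f"{row[point]:.3f}")
    return df
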