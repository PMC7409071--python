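"""Core in-memory containers for minute-resolution sensor data and saliva panels.

All timestamps are timezone-naive local clock times: every quantity the
analyses report (acrophase, center-of-rest, DLMO, the 22:01-07:00 night
span) is defined on the wall clock, not on elapsed or UTC time.

Per-day quantities use a noon-to-noon "study day" axis so that a nocturnal
sleep episode is never split across two days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: Night span used for nocturnal rest windows and the physiologic
#: temperature-acrophase rule, inclusive at both ends (clock hours).
NIGHT_START_H = 22.0 + 1.0 / 60.0  # 22:01
NIGHT_END_H = 7.0  # 07:00


def _as_timestamp(t) -> pd.Timestamp:
    ts = pd.Timestamp(t)
    if ts.tzinfo is not None:
        raise ValueError("timestamps must be timezone-naive local clock times")
    return ts


@dataclass
class MinuteSeries:
    """A regular fixed-step time series with an explicit missingness mask.

    Parameters
    ----------
    start : timestamp-like
        Clock time of the first sample.
    values : array of float
        One value per step. Entries under the mask are ignored by every
        analysis; they may hold NaN or stale sensor values.
    missing : boolean array
        True where the sample is missing/unusable. Same length as ``values``.
    step_min : int
        Sampling step in minutes (1 for raw sensor data).
    """

    start: pd.Timestamp
    values: np.ndarray
    missing: np.ndarray
    step_min: int = 1

    def __post_init__(self) -> None:
        self.start = _as_timestamp(self.start)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.values.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.ndim != 1 or self.values.shape != self.missing.shape:
            raise ValueError("values and missing mask must be 1-D and equal length")
        if self.step_min < 1:
            raise ValueError("step_min must be >= 1 minute")

    # -- basic geometry ----------------------------------------------------
    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def end(self) -> pd.Timestamp:
        """Timestamp one step past the last sample (exclusive end)."""
        return self.start + pd.Timedelta(minutes=self.step_min * self.n)

    @property
    def duration_h(self) -> float:
        return self.step_min * self.n / 60.0

    def time_index(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n,
                             freq=pd.Timedelta(minutes=self.step_min))

    def hours_since_start(self) -> np.ndarray:
        return np.arange(self.n) * (self.step_min / 60.0)

    def clock_hours(self) -> np.ndarray:
        """Clock hour-of-day in [0, 24) of every sample."""
        h0 = self.start.hour + self.start.minute / 60.0 + self.start.second / 3600.0
        return (h0 + self.hours_since_start()) % 24.0

    def present(self) -> np.ndarray:
        return ~self.missing

    def index_of(self, t) -> int:
        """Index of the sample covering clock time ``t`` (may be out of range)."""
        dt = _as_timestamp(t) - self.start
        return int(dt.total_seconds() // (60 * self.step_min))

    def slice_window(self, start, end) -> "MinuteSeries":
        """Sub-series covering [start, end); clipped to the available range."""
        i0 = max(0, self.index_of(start))
        i1 = min(self.n, self.index_of(end))
        if i1 <= i0:
            raise ValueError("empty window")
        return replace(self, start=self.start + pd.Timedelta(minutes=i0 * self.step_min),
                       values=self.values[i0:i1].copy(),
                       missing=self.missing[i0:i1].copy())

    def study_day_index(self) -> np.ndarray:
        """Integer noon-to-noon study-day label for every sample.

        Day d covers [first noon at/before start + d days, + 1 day).
        """
        first_noon = self.start.normalize() + pd.Timedelta(hours=12)
        if self.start < first_noon:
            first_noon -= pd.Timedelta(days=1)
        mins = (self.start - first_noon).total_seconds() / 60.0 \
            + np.arange(self.n) * self.step_min
        return (mins // (24 * 60)).astype(int)


@dataclass
class ActivitySeries(MinuteSeries):
    """Minute-indexed activity counts (acc/min), the raw material for the
    dichotomy index, the rest-activity HMM and the spectral analysis."""

    def __post_init__(self) -> None:
        super().__post_init__()
        ok = ~self.missing
        if np.any(self.values[ok] < 0):
            raise ValueError("activity counts must be non-negative where present")


@dataclass
class TemperatureSeries(MinuteSeries):
    """Minute-indexed chest-surface temperature in degrees Celsius."""


@dataclass
class LightSeries(MinuteSeries):
    """Minute-indexed wrist light exposure in lux."""

    def __post_init__(self) -> None:
        super().__post_init__()
        ok = ~self.missing
        if np.any(self.values[ok] < 0):
            raise ValueError("lux must be non-negative where present")


# ---------------------------------------------------------------------------
# Diary and bed spans
# ---------------------------------------------------------------------------

@dataclass
class DiaryDay:
    """One diary entry: retiring in the evening of ``date``, rising the next
    morning, plus optional exercise spans and meal times during that day."""

    date: pd.Timestamp  # calendar date (normalized)
    retiring: pd.Timestamp
    rising: pd.Timestamp
    exercise: list = field(default_factory=list)  # list of (start, end)
    meals: list = field(default_factory=list)  # list of timestamps

    def __post_init__(self) -> None:
        self.date = _as_timestamp(self.date).normalize()
        self.retiring = _as_timestamp(self.retiring)
        self.rising = _as_timestamp(self.rising)
        if self.rising <= self.retiring:
            raise ValueError(
                f"diary day {self.date.date()}: rising must follow retiring "
                "on the noon-to-noon day axis")
        spans = sorted((pd.Timestamp(a), pd.Timestamp(b)) for a, b in self.exercise)
        for (a, b) in spans:
            if b <= a:
                raise ValueError("exercise span must have positive length")
        for (_, b), (a2, _) in zip(spans, spans[1:]):
            if a2 < b:
                raise ValueError("exercise spans overlap within a day")
        self.exercise = spans
        self.meals = [pd.Timestamp(m) for m in self.meals]


@dataclass
class DiaryLog:
    days: list  # list[DiaryDay]

    def __iter__(self) -> Iterator[DiaryDay]:
        return iter(self.days)

    def __len__(self) -> int:
        return len(self.days)

    def bed_spans(self) -> "BedSpans":
        return BedSpans(spans=[(d.retiring, d.rising) for d in self.days],
                        provenance="diary")


@dataclass
class BedSpans:
    """In-bed (retiring -> rising) intervals, one per study day."""

    spans: list  # list of (start, end) timestamps
    provenance: str = "diary"  # "diary" | "hmm"

    MAX_SPAN_H = 18.0

    def __post_init__(self) -> None:
        spans = sorted((_as_timestamp(a), _as_timestamp(b)) for a, b in self.spans)
        for a, b in spans:
            if b <= a:
                raise ValueError("bed span must have positive length")
            if (b - a).total_seconds() / 3600.0 > self.MAX_SPAN_H:
                raise ValueError("bed span exceeds 18 h")
        for (_, b), (a2, _) in zip(spans, spans[1:]):
            if a2 < b:
                raise ValueError("bed spans overlap")
        self.spans = spans

    def __len__(self) -> int:
        return len(self.spans)

    def in_bed_mask(self, series: MinuteSeries) -> np.ndarray:
        """Boolean mask over ``series`` samples lying inside any bed span."""
        idx = series.time_index()
        mask = np.zeros(series.n, dtype=bool)
        for a, b in self.spans:
            mask |= (idx >= a) & (idx < b)
        return mask


# ---------------------------------------------------------------------------
# Saliva panels
# ---------------------------------------------------------------------------

SALIVA_UNITS = {"cortisol": "nmol/L", "melatonin": "pg/mL"}


@dataclass
class SalivaPanel:
    """Timed saliva samples for one analyte (cortisol nmol/L, melatonin pg/mL)."""

    analyte: str
    times: Sequence
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        if self.analyte not in SALIVA_UNITS:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        self.times = pd.DatetimeIndex([_as_timestamp(t) for t in self.times])
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.times) != self.concentrations.size:
            raise ValueError("times and concentrations differ in length")
        if not self.times.is_monotonic_increasing or self.times.has_duplicates:
            raise ValueError("sample times must be strictly increasing")
        if not np.all(np.isfinite(self.concentrations)):
            raise ValueError("concentrations must be finite")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def units(self) -> str:
        return SALIVA_UNITS[self.analyte]

    def hours(self) -> np.ndarray:
        """Sample times as continuous hours since midnight of the first day."""
        t0 = self.times[0].normalize()
        return np.array([(t - t0).total_seconds() / 3600.0 for t in self.times])

    def clock_hours(self) -> np.ndarray:
        return self.hours() % 24.0


def clock_hour_in_night(h: float,
                        night_start: float = NIGHT_START_H,
                        night_end: float = NIGHT_END_H) -> bool:
    """True if clock hour ``h`` falls in the wrap-around night span
    [night_start, night_end], closed at both ends."""
    h = h % 24.0
    if night_start <= night_end:
        return night_start <= h <= night_end
    return h >= night_start or h <= night_end


def circular_mean_hour(hours: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular mean of clock hours, in [0, 24)."""
    hours = np.asarray(hours, dtype=float)
    if hours.size == 0:
        return float("nan")
    ang = hours * (2 * np.pi / 24.0)
    w = np.ones_like(ang) if weights is None else np.asarray(weights, dtype=float)
    s, c = np.sum(w * np.sin(ang)), np.sum(w * np.cos(ang))
    if s == 0 and c == 0:
        return float("nan")
    h = float((np.arctan2(s, c) * (24.0 / (2 * np.pi))) % 24.0)
    return 0.0 if h >= 24.0 else h
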