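"""File ingestion, off-body span detection, aggregation and interpolation.

Sensor files are plain CSV (``timestamp,value``) on a strict 1-min grid;
gaps in the grid become missing-masked entries. Off-body spans (sensor
removed, typically for a shower or bath) are recognized from the chest
temperature signal: a steady decay down to near room temperature followed
by a plateau there, and are masked out of both the temperature and the
activity series before any analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import IngestConfig
from .series import (ActivitySeries, DiaryDay, DiaryLog, LightSeries,
                     MinuteSeries, SalivaPanel, TemperatureSeries)

_SERIES_KINDS = {
    "activity": ActivitySeries,
    "temperature": TemperatureSeries,
    "light": LightSeries,
}


class IngestError(ValueError):
    pass


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def read_series(path, kind: str) -> MinuteSeries:
    """Read a ``timestamp,value`` CSV onto a complete 1-min grid.

    Rows absent from the grid are masked missing; duplicate or non-monotone
    timestamps are rejected with the offending row number (1-based, header
    excluded).
    """
    if kind not in _SERIES_KINDS:
        raise IngestError(f"unknown series kind {kind!r}; "
                          f"expected one of {sorted(_SERIES_KINDS)}")
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["timestamp", "value"]:
        raise IngestError(f"{path}: expected header 'timestamp,value'")
    ts = pd.to_datetime(df["timestamp"])
    for i in range(1, len(ts)):
        if ts.iloc[i] <= ts.iloc[i - 1]:
            raise IngestError(
                f"{path}: non-monotone or duplicate timestamp at row {i + 1} "
                f"({ts.iloc[i]})")
    if len(ts) == 0:
        raise IngestError(f"{path}: empty file")
    grid = pd.date_range(ts.iloc[0], ts.iloc[-1], freq="1min")
    values = np.full(len(grid), np.nan)
    pos = ((ts - ts.iloc[0]).dt.total_seconds() // 60).astype(int).to_numpy()
    if np.any((ts - ts.iloc[0]).dt.total_seconds().to_numpy() % 60 != 0):
        raise IngestError(f"{path}: timestamps not aligned to the 1-min grid")
    values[pos] = df["value"].to_numpy(dtype=float)
    missing = np.isnan(values)
    cls = _SERIES_KINDS[kind]
    series = cls(start=grid[0], values=np.nan_to_num(values),
                 missing=missing, step_min=1)
    if kind == "temperature":
        series = _mask_implausible_temps(series)
    return series


def _mask_implausible_temps(series: TemperatureSeries,
                            band=(15.0, 42.0)) -> TemperatureSeries:
    lo, hi = band
    bad = (~series.missing) & ((series.values < lo) | (series.values > hi))
    if bad.any():
        warnings.warn(f"masked {int(bad.sum())} temperature samples outside "
                      f"the plausibility band {band}")
    return replace(series, missing=series.missing | bad)


def write_series(series: MinuteSeries, path) -> None:
    """Write present samples as ``timestamp,value`` (missing rows omitted)."""
    idx = series.time_index()
    ok = series.present()
    pd.DataFrame({"timestamp": idx[ok].strftime("%Y-%m-%dT%H:%M:%S"),
                  "value": series.values[ok]}).to_csv(path, index=False)


def read_diary(path) -> DiaryLog:
    """Diary CSV: ``date,retiring,rising,exercise_spans,meals``.

    retiring/rising are full timestamps; exercise_spans is
    ``start1/end1;start2/end2`` (ISO timestamps), meals ``t1;t2``.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    days = []
    for _, row in df.iterrows():
        exercise = []
        if row.get("exercise_spans", ""):
            for span in row["exercise_spans"].split(";"):
                a, b = span.split("/")
                exercise.append((pd.Timestamp(a), pd.Timestamp(b)))
        meals = [pd.Timestamp(m) for m in row.get("meals", "").split(";") if m]
        days.append(DiaryDay(date=pd.Timestamp(row["date"]),
                             retiring=pd.Timestamp(row["retiring"]),
                             rising=pd.Timestamp(row["rising"]),
                             exercise=exercise, meals=meals))
    return DiaryLog(days=days)


def write_diary(diary: DiaryLog, path) -> None:
    rows = []
    for d in diary:
        rows.append({
            "date": d.date.strftime("%Y-%m-%d"),
            "retiring": d.retiring.isoformat(),
            "rising": d.rising.isoformat(),
            "exercise_spans": ";".join(f"{a.isoformat()}/{b.isoformat()}"
                                       for a, b in d.exercise),
            "meals": ";".join(m.isoformat() for m in d.meals),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_saliva(path, analyte: str) -> SalivaPanel:
    """Saliva CSV: ``timestamp,analyte,concentration``; one analyte extracted."""
    df = pd.read_csv(path)
    sub = df[df["analyte"] == analyte]
    if len(sub) == 0:
        raise IngestError(f"{path}: no {analyte} samples")
    return SalivaPanel(analyte=analyte,
                       times=pd.to_datetime(sub["timestamp"]).tolist(),
                       concentrations=sub["concentration"].to_numpy(dtype=float))


def write_saliva(panels, path) -> None:
    rows = []
    for p in panels:
        for t, c in zip(p.times, p.concentrations):
            rows.append({"timestamp": t.isoformat(), "analyte": p.analyte,
                         "concentration": c})
    pd.DataFrame(rows).sort_values("timestamp").to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Off-body (missing-span) detection
# ---------------------------------------------------------------------------

def detect_missing_spans(temp: TemperatureSeries,
                         activity: ActivitySeries | None = None,
                         config: IngestConfig | None = None) -> np.ndarray:
    """Flag off-body minutes from the temperature signal.

    A minute is flagged when it belongs to a run of at least
    ``offbody_plateau_min`` minutes lying within ``offbody_delta_c`` of room
    temperature; each flagged run is extended backwards through the
    monotone-decreasing decay that led into it (at most
    ``offbody_decay_window_min`` minutes). The returned combined mask is the
    union with the inputs' existing masks; masks only ever grow.
    """
    cfg = config or IngestConfig()
    if activity is not None:
        if activity.n != temp.n or activity.start != temp.start:
            raise IngestError("temperature and activity series are not aligned")
    if temp.missing.all():
        raise IngestError("no analyzable data: temperature fully missing")

    near_room = (~temp.missing) & (
        np.abs(temp.values - cfg.room_temp_c) <= cfg.offbody_delta_c)
    flagged = np.zeros(temp.n, dtype=bool)

    # plateau runs of sufficient length
    i = 0
    while i < temp.n:
        if near_room[i]:
            j = i
            while j < temp.n and near_room[j]:
                j += 1
            if j - i >= cfg.offbody_plateau_min:
                flagged[i:j] = True
                # backward extension through the monotone decay
                k = i - 1
                limit = max(-1, i - 1 - cfg.offbody_decay_window_min)
                while (k > limit and not temp.missing[k]
                       and temp.values[k] > temp.values[k + 1]):
                    flagged[k] = True
                    k -= 1
            i = j
        else:
            i += 1

    combined = temp.missing | flagged
    if activity is not None:
        combined = combined | activity.missing
    return combined


def apply_mask(series: MinuteSeries, mask: np.ndarray) -> MinuteSeries:
    """Return a copy with the mask unioned in (masks only grow)."""
    return replace(series, missing=series.missing | np.asarray(mask, bool))


# ---------------------------------------------------------------------------
# Aggregation and interpolation
# ---------------------------------------------------------------------------

def aggregate(series: MinuteSeries, bin_min: int, stat: str = "mean") -> MinuteSeries:
    """Aggregate onto ``bin_min``-minute bins; a bin with more than half of
    its minutes missing is itself missing."""
    if stat not in ("mean", "sum"):
        raise IngestError(f"unknown aggregation stat {stat!r}")
    if bin_min < series.step_min:
        raise IngestError("bin smaller than the series step")
    if (24 * 60) % bin_min != 0:
        raise IngestError("bin must divide evenly into 24 h")
    per = bin_min // series.step_min
    n_bins = series.n // per
    v = series.values[:n_bins * per].reshape(n_bins, per)
    m = series.missing[:n_bins * per].reshape(n_bins, per)
    n_present = (~m).sum(axis=1)
    out_missing = n_present <= per * 0.5  # strict: >50% missing -> missing
    vv = np.where(m, 0.0, v)
    with np.errstate(invalid="ignore"):
        if stat == "mean":
            out = vv.sum(axis=1) / np.where(n_present == 0, 1, n_present)
        else:
            out = vv.sum(axis=1)
    out[out_missing] = np.nan
    return replace(series, values=np.nan_to_num(out), missing=out_missing,
                   step_min=bin_min)


@dataclass
class InterpolationResult:
    series: MinuteSeries
    fraction_interpolated: float
    warning: str | None = None


def interpolate_missing(series: MinuteSeries,
                        config: IngestConfig | None = None) -> InterpolationResult:
    """Linearly interpolate interior gaps; ends are extended with the nearest
    present value. Returns the completed series plus the interpolated fraction."""
    cfg = config or IngestConfig()
    ok = series.present()
    if not ok.any():
        raise IngestError("no analyzable data: series fully missing")
    frac = float(series.missing.mean())
    warning = None
    if frac > cfg.interp_warn_frac:
        warning = (f"{frac:.0%} of bins interpolated; downstream rhythm "
                   "estimates are unreliable")
        if cfg.interp_hard_fail:
            raise IngestError(warning)
    idx = np.arange(series.n)
    filled = np.interp(idx, idx[ok], series.values[ok])
    out = replace(series, values=filled,
                  missing=np.zeros(series.n, dtype=bool))
    return InterpolationResult(series=out, fraction_interpolated=frac,
                               warning=warning)


# ---------------------------------------------------------------------------
# Subject directory ingestion
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """Everything readable from one subject directory; absent files are None."""

    subject_id: str
    activity: ActivitySeries | None = None
    temperature: TemperatureSeries | None = None
    light: LightSeries | None = None
    diary: DiaryLog | None = None
    cortisol: SalivaPanel | None = None
    melatonin: SalivaPanel | None = None
    covariates: dict | None = None
    completeness: dict | None = None


def read_subject_dir(path, config: IngestConfig | None = None) -> SubjectData:
    """Read a subject directory (activity.csv, temperature.csv, light.csv,
    diary.csv, saliva.csv, covariates.csv), mask detected off-body spans, and
    report per-signal completeness."""
    cfg = config or IngestConfig()
    path = Path(path)
    data = SubjectData(subject_id=path.name)

    def maybe(fname, fn):
        f = path / fname
        return fn(f) if f.exists() else None

    data.activity = maybe("activity.csv", lambda f: read_series(f, "activity"))
    data.temperature = maybe("temperature.csv",
                             lambda f: read_series(f, "temperature"))
    data.light = maybe("light.csv", lambda f: read_series(f, "light"))
    data.diary = maybe("diary.csv", read_diary)
    saliva = path / "saliva.csv"
    if saliva.exists():
        for analyte in ("cortisol", "melatonin"):
            try:
                panel = read_saliva(saliva, analyte)
            except IngestError:
                panel = None
            setattr(data, analyte, panel)
    cov = path / "covariates.csv"
    if cov.exists():
        row = pd.read_csv(cov).iloc[0]
        data.covariates = row.to_dict()

    if data.temperature is not None and data.activity is not None:
        mask = detect_missing_spans(data.temperature, data.activity, cfg)
        data.temperature = apply_mask(data.temperature, mask)
        data.activity = apply_mask(data.activity, mask)

    data.completeness = {
        name: round(100.0 * float(s.present().mean()), 2)
        for name, s in (("activity", data.activity),
                        ("temperature", data.temperature),
                        ("light", data.light)) if s is not None
    }
    return data
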