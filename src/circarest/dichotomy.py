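"""Dichotomy index I<O: the percentage of in-bed activity counts per minute
strictly below the median out-of-bed activity count, and the 97.5% low/high
classification applied after the first 72 h of recording.

Conventions (documented because they move the index by whole percents):

* ties at the median count as NOT below (strict inequality, read literally
  from the index's definition);
* one pooled out-of-bed median per analysis window, not per-day medians;
* missing minutes are excluded from both pools;
* a window with an all-zero out-of-bed pool (bed-bound subject) gets
  io_percent = 0.0 with a degenerate flag rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DichotomyConfig
from .series import ActivitySeries, BedSpans

THRESHOLD_PERCENT = 97.5


class DichotomyError(ValueError):
    pass


@dataclass
class IOResult:
    io_percent: float
    window: tuple                    # (start, end) timestamps
    n_in_minutes: int
    n_out_minutes: int
    out_median: float
    category: str | None = None      # "low" | "high"; set only for >=72-h windows
    flags: list = field(default_factory=list)


def compute_io(activity: ActivitySeries, beds: BedSpans,
               window: tuple | None = None,
               config: DichotomyConfig | None = None) -> IOResult:
    """Dichotomy index over ``window`` (default: the full recording).

    Requires at least one complete in-bed interval inside the window and at
    least ``min_out_of_bed_h`` hours of non-missing out-of-bed minutes.
    """
    cfg = config or DichotomyConfig()
    if window is None:
        window = (activity.start, activity.end)
    w0, w1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    sub = activity.slice_window(w0, w1)

    complete = [s for s in beds.spans if s[0] >= w0 and s[1] <= w1]
    if not complete:
        raise DichotomyError("no rest interval: no complete in-bed span "
                             "inside the window")
    in_bed = BedSpans(spans=complete, provenance=beds.provenance).in_bed_mask(sub)
    ok = sub.present()
    in_vals = sub.values[in_bed & ok]
    out_vals = sub.values[~in_bed & ok]
    if in_vals.size == 0:
        raise DichotomyError("no rest interval: all in-bed minutes missing")
    if out_vals.size == 0:
        raise DichotomyError("all out-of-bed minutes missing")
    if out_vals.size < cfg.min_out_of_bed_h * 60:
        raise DichotomyError(
            f"only {out_vals.size} out-of-bed minutes in window; "
            f">= {cfg.min_out_of_bed_h:.0f} h required")

    out_median = float(np.median(out_vals))
    flags = []
    if out_median == 0.0:
        io = 0.0
        flags.append("degenerate: out-of-bed median is zero")
    else:
        io = 100.0 * float(np.mean(in_vals < out_median))
    window_h = (w1 - w0).total_seconds() / 3600.0
    category = classify_io(io, cfg) if window_h >= cfg.classification_window_h \
        else None
    return IOResult(io_percent=io, window=(w0, w1),
                    n_in_minutes=int(in_vals.size),
                    n_out_minutes=int(out_vals.size),
                    out_median=out_median, category=category, flags=flags)


def compute_io_72h(activity: ActivitySeries, beds: BedSpans,
                   config: DichotomyConfig | None = None) -> IOResult:
    """The (I<O)_72h triage value: compute_io on the first 72 h of recording."""
    cfg = config or DichotomyConfig()
    end = activity.start + pd.Timedelta(hours=cfg.classification_window_h)
    return compute_io(activity, beds, (activity.start, end), cfg)


def classify_io(io_percent: float,
                config: DichotomyConfig | None = None) -> str:
    """"low" when I<O is at or below the threshold (default 97.5%), else "high"."""
    cfg = config or DichotomyConfig()
    if not (0.0 <= io_percent <= 100.0):
        raise DichotomyError(f"I<O out of range: {io_percent}")
    return "low" if io_percent <= cfg.threshold_percent else "high"
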