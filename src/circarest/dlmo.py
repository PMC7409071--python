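"""Dim light melatonin onset (DLMO).

DLMO is the clock time at which evening salivary melatonin first exceeds a
baseline-derived threshold and stays above it. The threshold is the mean of
3 consecutive pre-rise baseline samples plus twice their sample SD; when no
individual baseline qualifies, a group-pooled threshold (pooled baseline
mean + 2 pooled SD, computed separately for patients and controls) is used
instead. Crossing times are linearly interpolated between the flanking
samples. Dim-light compliance over the 30 min before each sample is checked
against a configurable lux cutoff and flagged, never fatal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import DlmoConfig
from .series import LightSeries, SalivaPanel


class DlmoError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Dim-light validity
# ---------------------------------------------------------------------------

def check_dim_light(light: LightSeries | None, sample_times,
                    config: DlmoConfig | None = None) -> list:
    """Per-sample validity flag: "valid", "invalid" or "indeterminate".

    Valid means the mean lux over the 30 min before collection is below the
    cutoff and no single minute exceeds 4x the cutoff.
    """
    cfg = config or DlmoConfig()
    flags = []
    for t in sample_times:
        t = pd.Timestamp(t)
        if light is None:
            flags.append("indeterminate")
            continue
        i1 = light.index_of(t)
        i0 = i1 - 30
        if i0 < 0 or i1 > light.n:
            flags.append("indeterminate")
            continue
        window = light.values[i0:i1]
        wmask = light.missing[i0:i1]
        if wmask.any():
            flags.append("indeterminate")
            continue
        if (window.mean() < cfg.dim_light_cutoff_lux
                and window.max() <= cfg.dim_light_peak_factor
                * cfg.dim_light_cutoff_lux):
            flags.append("valid")
        else:
            flags.append("invalid")
    return flags


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

@dataclass
class BaselineRun:
    values: np.ndarray           # the 3 consecutive baseline concentrations
    indices: tuple
    threshold: float             # run mean + 2 x run sample SD


def _first_rise_index(conc: np.ndarray, frac: float) -> int | None:
    """Index of the first sample belonging to the sustained rise.

    The rise starts at the first step whose increase exceeds ``frac`` of the
    mean of all preceding samples and which is followed by a further
    increase (or is the final step). Samples before that index are the
    pre-rise baseline pool; slow baseline drift below the fraction does not
    truncate the pool."""
    n = conc.size
    for k in range(1, n):
        if conc[k] - conc[k - 1] > frac * conc[:k].mean():
            if k == n - 1 or conc[k + 1] > conc[k]:
                return k
    return None


def individual_threshold(panel: SalivaPanel,
                         config: DlmoConfig | None = None) -> BaselineRun | None:
    """Earliest qualifying 3-sample baseline run: entirely at or before the
    first sustained rise, with coefficient of variation < 0.33. Returns None
    when no run qualifies (pooled fallback)."""
    cfg = config or DlmoConfig()
    if panel.analyte != "melatonin":
        raise DlmoError(f"expected a melatonin panel, got {panel.analyte}")
    conc = panel.concentrations
    if conc.size < 3:
        return None
    rise = _first_rise_index(conc, cfg.rise_fraction)
    last_start = (rise - 3 if rise is not None else conc.size - 3)
    for s in range(0, last_start + 1):
        run = conc[s:s + 3]
        mean = run.mean()
        sd = run.std(ddof=1)
        if mean > 0 and sd / mean < cfg.baseline_cv_max:
            return BaselineRun(values=run.copy(), indices=(s, s + 1, s + 2),
                               threshold=float(mean + 2 * sd))
    return None


@dataclass
class PooledThreshold:
    threshold: float
    group: str
    n_subjects: int
    n_values: int


def pooled_threshold(panels: list, group: str,
                     config: DlmoConfig | None = None) -> PooledThreshold:
    """Group threshold = mean + 2 x SD of the pooled baseline values of all
    subjects in the group with a qualifying individual baseline."""
    cfg = config or DlmoConfig()
    pools = [r.values for r in
             (individual_threshold(p, cfg) for p in panels) if r is not None]
    if len(pools) < 2:
        raise DlmoError("pooled threshold needs >= 2 subjects with "
                        "individual baselines")
    allv = np.concatenate(pools)
    return PooledThreshold(
        threshold=float(allv.mean() + 2 * allv.std(ddof=1)),
        group=group, n_subjects=len(pools), n_values=int(allv.size))


def pooled_validation(panels: list, group: str,
                      config: DlmoConfig | None = None) -> dict:
    """Pearson correlation between individual-threshold and pooled-threshold
    DLMO times over the subjects having both (the pooled threshold's
    validation check)."""
    cfg = config or DlmoConfig()
    pooled = pooled_threshold(panels, group, cfg)
    ind_times, pool_times = [], []
    for p in panels:
        run = individual_threshold(p, cfg)
        if run is None:
            continue
        r_i = compute_dlmo(p, run.threshold)
        r_p = compute_dlmo(p, pooled.threshold)
        if r_i.dlmo_time is None or r_p.dlmo_time is None:
            continue
        ind_times.append(_hours(r_i.dlmo_time))
        pool_times.append(_hours(r_p.dlmo_time))
    if len(ind_times) < 3:
        return {"pearson_r": float("nan"), "n": len(ind_times),
                "pooled_threshold": pooled.threshold}
    r, p = stats.pearsonr(ind_times, pool_times)
    return {"pearson_r": float(r), "p_value": float(p), "n": len(ind_times),
            "pooled_threshold": pooled.threshold}


def _hours(t: pd.Timestamp) -> float:
    return (t - t.normalize()).total_seconds() / 3600.0


# ---------------------------------------------------------------------------
# Onset
# ---------------------------------------------------------------------------

@dataclass
class DLMOResult:
    threshold: float
    dlmo_time: pd.Timestamp | None
    baseline_source: str                  # "individual" | "pooled"
    baseline_samples: np.ndarray | None
    dim_light_flags: list = field(default_factory=list)
    group: str | None = None
    flags: list = field(default_factory=list)

    @property
    def dlmo_clock_h(self) -> float:
        return _hours(self.dlmo_time) if self.dlmo_time is not None \
            else float("nan")


def compute_dlmo(panel: SalivaPanel, threshold: float,
                 validity: list | None = None,
                 baseline_source: str = "individual",
                 baseline_samples: np.ndarray | None = None,
                 group: str | None = None) -> DLMOResult:
    """First sustained crossing of the threshold, linearly interpolated.

    The crossing sample must stay above the threshold for all subsequent
    samples. A first sample already above the threshold means the onset
    precedes the sampling window (undetermined, flagged).
    """
    if len(panel) < 2:
        raise DlmoError("need >= 2 melatonin samples")
    if threshold <= 0:
        raise DlmoError("threshold must be positive")
    conc = panel.concentrations
    flags = []
    result = DLMOResult(threshold=float(threshold), dlmo_time=None,
                        baseline_source=baseline_source,
                        baseline_samples=baseline_samples,
                        dim_light_flags=validity or [], group=group,
                        flags=flags)
    if conc[0] > threshold:
        flags.append("undetermined: onset precedes the sampling window")
        return result
    above = conc > threshold
    cross = None
    for i in range(len(conc) - 1):
        if not above[i] and above[i + 1] and above[i + 1:].all():
            cross = i
            break
    if cross is None:
        flags.append("undetermined: melatonin never sustainably exceeds "
                     "the threshold")
        return result
    t0, t1 = panel.times[cross], panel.times[cross + 1]
    c0, c1 = conc[cross], conc[cross + 1]
    frac = (threshold - c0) / (c1 - c0)
    result.dlmo_time = t0 + frac * (t1 - t0)
    if validity:
        v0, v1 = validity[cross], validity[cross + 1]
        if "invalid" in (v0, v1):
            flags.append("crossing flanked by dim-light-invalid samples")
        elif "indeterminate" in (v0, v1):
            flags.append("dim-light status indeterminate at the crossing")
    return result


def dlmo_for_subject(melatonin: SalivaPanel, light: LightSeries | None,
                     group: str | None = None,
                     pooled: PooledThreshold | None = None,
                     config: DlmoConfig | None = None) -> DLMOResult:
    """Individual-baseline DLMO with pooled fallback, dim-light checked."""
    cfg = config or DlmoConfig()
    validity = check_dim_light(light, melatonin.times, cfg)
    run = individual_threshold(melatonin, cfg)
    if run is not None:
        return compute_dlmo(melatonin, run.threshold, validity,
                            baseline_source="individual",
                            baseline_samples=run.values, group=group)
    if pooled is None:
        raise DlmoError("no individual baseline and no pooled threshold "
                        "available")
    return compute_dlmo(melatonin, pooled.threshold, validity,
                        baseline_source="pooled", group=group)
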