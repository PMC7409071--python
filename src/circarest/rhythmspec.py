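"""Least-squares periodogram rhythm estimation and 24-h autocorrelation.

The periodogram fits, for every trial period on a continuous grid, a single
sinusoid (plus mean) by least squares; the spectrum value is the fraction
of variance explained. The dominant period is the spectrum argmax; its 90%
confidence intervals come from residual resampling (re-estimating period,
amplitude and acrophase per resample), and rhythm significance from a
permutation null: surrogates that keep the marginal distribution of the
series but destroy its time order, so any reproducible periodic structure
pushes the observed peak past the null's 95th percentile.

r24, the lag-24-h Pearson autocorrelation of the (hourly) series, indexes
day-to-day recurrence of the activity pattern on a -1..1 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RhythmConfig
from .series import MinuteSeries


class RhythmError(ValueError):
    pass


@dataclass
class Spectrum:
    periods_h: np.ndarray
    power: np.ndarray          # variance explained (R^2) per period
    amplitude: np.ndarray      # fitted sinusoid amplitude per period
    acrophase_h: np.ndarray    # clock time of fitted maximum per period
    series: MinuteSeries       # the (complete) series the spectrum came from


@dataclass
class RhythmEstimate:
    dominant_period_h: float
    amplitude: float
    acrophase_h: float
    ci90_period: tuple
    ci90_amplitude: tuple
    ci90_acrophase: tuple
    significant: bool
    peak_power: float
    null_power_95: float
    fraction_interpolated: float = 0.0
    flags: list = field(default_factory=list)


@dataclass
class AutocorrResult:
    r24: float
    n_pairs: int
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Spectrum machinery (vectorized over periods and replicate series)
# ---------------------------------------------------------------------------

def _design(t_h: np.ndarray, periods: np.ndarray):
    """Orthonormal bases Q_p of span{1, sin, cos} for every period.

    Returns Q of shape (P, n, 3) with orthonormal columns."""
    n = t_h.size
    P = periods.size
    w = 2 * np.pi * t_h[None, :] / periods[:, None]
    X = np.empty((P, n, 3))
    X[:, :, 0] = 1.0
    X[:, :, 1] = np.sin(w)
    X[:, :, 2] = np.cos(w)
    Q = np.empty_like(X)
    for p in range(P):
        Q[p], _ = np.linalg.qr(X[p])
    return X, Q


def _spectrum_matrix(Y: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """R^2 of the sinusoid fit, for every (period, series) pair.

    Y is (m, n) replicate series; Q the orthonormal designs (P, n, 3).
    The intercept-only column is excluded from the explained sum of squares.
    """
    Yc = Y - Y.mean(axis=1, keepdims=True)
    tot = np.sum(Yc ** 2, axis=1)                       # (m,)
    proj = np.einsum("pnk,mn->pmk", Q[:, :, 1:], Yc)    # (P, m, 2)
    expl = np.sum(proj ** 2, axis=2)                    # (P, m)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = expl / tot[None, :]
    return np.where(tot[None, :] > 0, r2, 0.0)  # constant series: no rhythm


def periodogram(series: MinuteSeries, config: RhythmConfig | None = None,
                periods_h: np.ndarray | None = None) -> Spectrum:
    """Least-squares periodogram of a complete (interpolated) series.

    The series must span at least twice the maximum trial period.
    """
    cfg = config or RhythmConfig()
    if series.missing.any():
        raise RhythmError("periodogram requires a complete series; "
                          "interpolate missing bins first")
    if periods_h is None:
        periods_h = np.round(np.arange(cfg.period_min_h,
                                       cfg.period_max_h + 1e-9,
                                       cfg.period_step_h), 10)
    periods_h = np.asarray(periods_h, float)
    if series.duration_h < 2 * periods_h.max():
        raise RhythmError(
            f"series spans {series.duration_h:.0f} h; need >= twice the "
            f"maximum trial period ({2 * periods_h.max():.0f} h)")
    t_h = series.hours_since_start()
    X, Q = _design(t_h, periods_h)
    y = series.values[None, :]
    power = _spectrum_matrix(y, Q)[:, 0]

    # per-period amplitude and acrophase from the raw (non-orthonormal) fit
    amp = np.empty_like(power)
    acro = np.empty_like(power)
    h0 = series.clock_hours()[0]
    for p in range(periods_h.size):
        coef, *_ = np.linalg.lstsq(X[p], series.values, rcond=None)
        a, b = coef[1], coef[2]
        amp[p] = np.hypot(a, b)
        # a sin wt + b cos wt peaks at wt = atan2(a, b)
        tmax = (np.arctan2(a, b) / (2 * np.pi)) * periods_h[p]
        acro[p] = (h0 + tmax % periods_h[p]) % 24.0
    return Spectrum(periods_h=periods_h, power=power, amplitude=amp,
                    acrophase_h=acro, series=series)


def _permutation_null(y: np.ndarray, m: int, rng) -> np.ndarray:
    """m surrogate series with the marginal distribution of y but the time
    order destroyed — the null of no temporal (hence no periodic) structure."""
    return rng.permuted(np.broadcast_to(y, (m, y.size)).copy(), axis=1)


def dominant_rhythm(spectrum: Spectrum, n_resamples: int | None = None,
                    seed: int = 0,
                    config: RhythmConfig | None = None,
                    fraction_interpolated: float = 0.0) -> RhythmEstimate:
    """Dominant-period estimate with resampling CIs and a permutation
    significance test. A tie at the spectrum maximum resolves to the smaller
    period (logged)."""
    cfg = config or RhythmConfig()
    B = cfg.n_resamples if n_resamples is None else n_resamples
    flags = []
    pk = np.flatnonzero(spectrum.power == spectrum.power.max())
    if pk.size > 1:
        flags.append(f"{pk.size}-way tie at the spectrum maximum; "
                     "smaller period reported")
    i0 = int(pk[0])
    period = float(spectrum.periods_h[i0])
    amplitude = float(spectrum.amplitude[i0])
    acrophase = float(spectrum.acrophase_h[i0])

    series = spectrum.series
    y = series.values
    t_h = series.hours_since_start()
    X, Q = _design(t_h, spectrum.periods_h)
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, 0x57EC]))

    # residual-resampling CIs around the dominant-period fit
    coef, *_ = np.linalg.lstsq(X[i0], y, rcond=None)
    fitted = X[i0] @ coef
    resid = y - fitted
    idx = rng.integers(0, resid.size, size=(B, resid.size))
    Yb = fitted[None, :] + resid[idx]
    Rb = _spectrum_matrix(Yb, Q)                   # (P, B)
    ib = np.argmax(Rb, axis=0)
    per_b = spectrum.periods_h[ib]
    amp_b = np.empty(B)
    acr_b = np.empty(B)
    h0 = series.clock_hours()[0]
    for b in range(B):
        cb, *_ = np.linalg.lstsq(X[ib[b]], Yb[b], rcond=None)
        amp_b[b] = np.hypot(cb[1], cb[2])
        tmax = (np.arctan2(cb[1], cb[2]) / (2 * np.pi)) * per_b[b]
        acr_b[b] = (h0 + tmax % per_b[b]) % 24.0
    ci_period = tuple(np.percentile(per_b, [5, 95]))
    ci_amp = tuple(np.percentile(amp_b, [5, 95]))
    # circular percentiles for acrophase, centered on the point estimate
    d = (acr_b - acrophase + 12.0) % 24.0 - 12.0
    lo, hi = np.percentile(d, [5, 95])
    ci_acro = ((acrophase + lo) % 24.0, (acrophase + hi) % 24.0)

    # permutation null for the peak power
    S = _permutation_null(y, cfg.n_scrambles, rng)
    null_max = _spectrum_matrix(S, Q).max(axis=0)
    cutoff = float(np.percentile(null_max, 100 * (1 - cfg.significance_level)))
    significant = bool(spectrum.power[i0] > cutoff)
    if not significant:
        flags.append("no significant rhythm at the dominant period")
    return RhythmEstimate(dominant_period_h=period, amplitude=amplitude,
                          acrophase_h=acrophase, ci90_period=ci_period,
                          ci90_amplitude=ci_amp, ci90_acrophase=ci_acro,
                          significant=significant,
                          peak_power=float(spectrum.power[i0]),
                          null_power_95=cutoff,
                          fraction_interpolated=fraction_interpolated,
                          flags=flags)


# ---------------------------------------------------------------------------
# 24-h autocorrelation
# ---------------------------------------------------------------------------

def autocorr24(series: MinuteSeries) -> AutocorrResult:
    """Pearson correlation of the series with itself shifted by 24 h; pairs
    with either member missing are dropped."""
    lag = int(round(24 * 60 / series.step_min))
    if series.n <= lag:
        raise RhythmError("need more than 24 h of data for r24")
    if series.duration_h < 48:
        raise RhythmError("need >= 48 h of data for r24")
    a = series.values[:-lag]
    b = series.values[lag:]
    ok = ~(series.missing[:-lag] | series.missing[lag:])
    n_pairs = int(ok.sum())
    if n_pairs < 3:
        return AutocorrResult(r24=float("nan"), n_pairs=n_pairs,
                              flags=["too few overlapping pairs"])
    x, z = a[ok], b[ok]
    if np.std(x) == 0 or np.std(z) == 0:
        return AutocorrResult(r24=float("nan"), n_pairs=n_pairs,
                              flags=["undefined: zero variance at lag 24 h"])
    r = float(np.corrcoef(x, z)[0, 1])
    return AutocorrResult(r24=r, n_pairs=n_pairs)
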