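"""Cosinor modelling of chest temperature and salivary cortisol.

Temperature uses a two-harmonic model (24 h + 12 h components) fitted to an
averaged 24-h profile of the 1-h-smoothed minute series:

    y(t) = M + a1 sin(2*pi*t/24) + b1 cos(2*pi*t/24)
             + a2 sin(2*pi*t/12) + b2 cos(2*pi*t/12) + e(t)

Cortisol uses the single 24-h harmonic fitted on the raw sample times.
Amplitude per harmonic is sqrt(a^2 + b^2); the reported acrophase is the
clock time at which the full fitted curve attains its maximum (evaluated on
a 1-min grid), which for the two-harmonic model is not in general the phase
of the 24-h component alone. 90% confidence intervals are bootstrap-based
(residual bootstrap for the averaged temperature profile, case bootstrap
over samples for cortisol); cortisol rhythm significance is the
zero-amplitude F-test.

Temperature rhythms are classified physiologic (significant ~24-h period
with a nocturnal acrophase between 22:01 and 07:00, both ends inclusive),
abnormal (significant but not nocturnal-24-h), or arrhythmic (no
significant dominant rhythm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import CosinorConfig
from .series import SalivaPanel, TemperatureSeries, clock_hour_in_night
from .rhythmspec import RhythmEstimate


class CosinorError(ValueError):
    pass


@dataclass
class CosinorFit:
    mesor: float
    coefficients: dict           # {"a1","b1"[,"a2","b2"]}
    amplitudes: dict             # per-harmonic sqrt(a^2+b^2)
    acrophase_h: float           # clock time of the fitted-curve maximum
    ci90_mesor: tuple
    ci90_amplitude: tuple        # CI of the fundamental (24-h) amplitude
    ci90_acrophase: tuple
    residual_sd: float
    n_obs: int
    periods_h: tuple
    significant: bool | None = None   # zero-amplitude F-test (cortisol)
    f_pvalue: float | None = None
    flags: list = field(default_factory=list)

    @property
    def amplitude(self) -> float:
        """Fundamental (24-h) amplitude."""
        return self.amplitudes["24"]

    def predict(self, clock_h: np.ndarray) -> np.ndarray:
        y = np.full_like(np.asarray(clock_h, float), self.mesor)
        for T in self.periods_h:
            a = self.coefficients[_ab_key(T, "a")]
            b = self.coefficients[_ab_key(T, "b")]
            w = 2 * np.pi * np.asarray(clock_h, float) / T
            y = y + a * np.sin(w) + b * np.cos(w)
        return y


def _ab_key(T: float, which: str) -> str:
    return f"{which}1" if int(T) == 24 else f"{which}2"


def _design(t_h: np.ndarray, periods=(24.0, 12.0)) -> np.ndarray:
    cols = [np.ones_like(t_h)]
    for T in periods:
        w = 2 * np.pi * t_h / T
        cols += [np.sin(w), np.cos(w)]
    return np.column_stack(cols)


def _curve_max_clock(coef: np.ndarray, periods) -> float:
    grid = np.arange(0, 24, 1.0 / 60.0)
    y = _design(grid, periods) @ coef
    return float(grid[int(np.argmax(y))])


def _pack_fit(coef, resid, n, periods, ci_m, ci_a, ci_p, flags,
              significant=None, f_pvalue=None) -> CosinorFit:
    coefficients, amplitudes = {}, {}
    for i, T in enumerate(periods):
        a, b = coef[1 + 2 * i], coef[2 + 2 * i]
        coefficients[_ab_key(T, "a")] = float(a)
        coefficients[_ab_key(T, "b")] = float(b)
        amplitudes[str(int(T))] = float(np.hypot(a, b))
    return CosinorFit(
        mesor=float(coef[0]), coefficients=coefficients,
        amplitudes=amplitudes,
        acrophase_h=_curve_max_clock(coef, periods),
        ci90_mesor=ci_m, ci90_amplitude=ci_a, ci90_acrophase=ci_p,
        residual_sd=float(np.std(resid, ddof=len(coef))) if n > len(coef)
        else 0.0,
        n_obs=int(n), periods_h=tuple(periods), significant=significant,
        f_pvalue=f_pvalue, flags=flags)


def _amp_and_se(coef, XtXinv, s2):
    """24-h amplitude and its delta-method standard error."""
    a, b = coef[1], coef[2]
    amp = float(np.hypot(a, b))
    C = s2 * XtXinv[1:3, 1:3]
    if amp < 1e-12:
        return amp, float(np.sqrt(max(C[0, 0], 0.0)))
    g = np.array([a / amp, b / amp])
    return amp, float(np.sqrt(max(g @ C @ g, 0.0)))


def _bootstrap_cis(t_h, coef, fitted, resid, periods, n_boot, alpha, rng,
                   case_y=None):
    """Bootstrap CIs for mesor, 24-h amplitude and acrophase.

    Mesor and amplitude use studentized (bootstrap-t) intervals, which
    calibrate far better than raw percentiles at cosinor sample sizes;
    acrophase uses circular percentiles centered on the point estimate.
    Residual bootstrap when case_y is None, otherwise case resampling of
    (t, y) pairs.
    """
    X = _design(t_h, periods)
    n, p = X.shape
    dof = max(n - p, 1)
    XtXinv = np.linalg.pinv(X.T @ X)
    s2 = float(resid @ resid) / dof
    mes_hat = float(coef[0])
    se_mes = np.sqrt(max(s2 * XtXinv[0, 0], 0.0))
    amp_hat, se_amp = _amp_and_se(coef, XtXinv, s2)
    point = _curve_max_clock(coef, periods)
    if s2 < 1e-24:  # noiseless fit: degenerate point intervals
        return ((mes_hat, mes_hat), (amp_hat, amp_hat), (point, point))

    t_mes = np.empty(n_boot)
    t_amp = np.empty(n_boot)
    acro = np.empty(n_boot)
    for b in range(n_boot):
        if case_y is None:
            Xb, XtXinv_b = X, XtXinv
            yb = fitted + resid[rng.integers(0, n, n)]
        else:
            idx = rng.integers(0, n, n)
            Xb = X[idx]
            XtXinv_b = np.linalg.pinv(Xb.T @ Xb)
            yb = case_y[idx]
        cb, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        rb = yb - Xb @ cb
        s2b = max(float(rb @ rb) / dof, 1e-24)
        ampb, se_ampb = _amp_and_se(cb, XtXinv_b, s2b)
        se_mesb = np.sqrt(max(s2b * XtXinv_b[0, 0], 1e-24))
        t_mes[b] = (cb[0] - mes_hat) / se_mesb
        t_amp[b] = (ampb - amp_hat) / max(se_ampb, 1e-12)
        acro[b] = _curve_max_clock(cb, periods)
    q = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    qm = np.percentile(t_mes, q)
    qa = np.percentile(t_amp, q)
    ci_mes = (mes_hat - qm[1] * se_mes, mes_hat - qm[0] * se_mes)
    ci_amp = (max(0.0, amp_hat - qa[1] * se_amp),
              amp_hat - qa[0] * se_amp)
    d = (acro - point + 12.0) % 24.0 - 12.0
    lo, hi = np.percentile(d, q)
    return (ci_mes, ci_amp, ((point + lo) % 24.0, (point + hi) % 24.0))


# ---------------------------------------------------------------------------
# Temperature (two-harmonic on the averaged 24-h profile)
# ---------------------------------------------------------------------------

def smoothed_profile(temp: TemperatureSeries,
                     config: CosinorConfig | None = None):
    """1-h centered moving average over non-missing minutes, then the mean
    across days for every clock minute. Returns (clock_h, profile, coverage)."""
    cfg = config or CosinorConfig()
    n = temp.n
    ok = temp.present().astype(float)
    v = np.where(temp.missing, 0.0, temp.values)
    kernel = np.ones(61)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(ok, kernel, mode="same")
    smooth = np.where(den >= 31, num / np.maximum(den, 1), np.nan)
    smooth[:30] = np.nan   # incomplete edge windows
    smooth[-30:] = np.nan

    clock_min = ((temp.start.hour * 60 + temp.start.minute)
                 + np.arange(n)) % 1440
    sums = np.zeros(1440)
    counts = np.zeros(1440)
    good = np.isfinite(smooth)
    np.add.at(sums, clock_min[good], smooth[good])
    np.add.at(counts, clock_min[good], 1)
    covered = counts > 0
    coverage = float(covered.mean())
    profile = np.where(covered, sums / np.maximum(counts, 1), np.nan)
    return np.arange(1440) / 60.0, profile, coverage


def fit_temperature_cosinor(temp: TemperatureSeries, seed: int = 0,
                            config: CosinorConfig | None = None) -> CosinorFit:
    """Two-harmonic cosinor of the averaged 24-h temperature profile."""
    cfg = config or CosinorConfig()
    if (temp.present().sum() * temp.step_min) < 72 * 60:
        raise CosinorError("need >= 72 h of non-missing temperature data")
    clock_h, profile, coverage = smoothed_profile(temp, cfg)
    if coverage < cfg.min_profile_coverage:
        raise CosinorError(
            f"averaged profile covers {coverage:.0%} of clock minutes; "
            f">= {cfg.min_profile_coverage:.0%} required")
    ok = np.isfinite(profile)
    t, y = clock_h[ok], profile[ok]
    periods = (24.0, 12.0)
    X = _design(t, periods)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    # deconvolve the known 61-min boxcar gain so pure harmonics are
    # recovered without the smoothing stage's amplitude attenuation
    coef = _deconvolve_boxcar(coef, periods)
    fitted = X @ coef
    resid = y - fitted
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, 0xC051]))
    ci_m, ci_a, ci_p = _bootstrap_cis(t, coef, fitted, resid, periods,
                                      cfg.n_bootstrap, cfg.alpha, rng)
    return _pack_fit(coef, resid, y.size, periods, ci_m, ci_a, ci_p, [])


def _boxcar_gain(period_h: float, window_min: int = 61) -> float:
    """Amplitude gain of a centered boxcar average on a pure sinusoid."""
    x = np.pi * window_min / (period_h * 60.0)
    return float(np.sin(x) / (window_min * np.sin(x / window_min)))


def _deconvolve_boxcar(coef: np.ndarray, periods) -> np.ndarray:
    out = coef.copy()
    for i, T in enumerate(periods):
        out[1 + 2 * i:3 + 2 * i] /= _boxcar_gain(T)
    return out


# ---------------------------------------------------------------------------
# Cortisol (single 24-h harmonic on raw sample times)
# ---------------------------------------------------------------------------

def fit_cortisol_cosinor(panel: SalivaPanel, seed: int = 0,
                         config: CosinorConfig | None = None) -> CosinorFit:
    """24-h cosinor on raw cortisol sample times (no binning); adequacy
    requires at least 9 samples over the collection days."""
    cfg = config or CosinorConfig()
    if panel.analyte != "cortisol":
        raise CosinorError(f"expected a cortisol panel, got {panel.analyte}")
    if len(panel) < cfg.cortisol_min_samples:
        raise CosinorError(
            f"inadequate panel: {len(panel)} samples, "
            f">= {cfg.cortisol_min_samples} required")
    t = panel.hours()          # continuous hours; 24-h harmonic only
    y = panel.concentrations
    periods = (24.0,)
    X = _design(t, periods)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted

    # zero-amplitude F-test against the mesor-only model
    rss1 = float(np.sum(resid ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df1 = y.size - 3
    if df1 <= 0 or rss1 <= 0:
        fp = float("nan")
        significant = None
    else:
        F = ((rss0 - rss1) / 2) / (rss1 / df1)
        fp = float(stats.f.sf(F, 2, df1))
        significant = bool(fp < cfg.f_test_alpha)
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, 0xC052]))
    ci_m, ci_a, ci_p = _bootstrap_cis(t, coef, fitted, resid, periods,
                                      cfg.n_bootstrap, cfg.alpha, rng,
                                      case_y=y)
    return _pack_fit(coef, resid, y.size, periods, ci_m, ci_a, ci_p, [],
                     significant=significant, f_pvalue=fp)


# ---------------------------------------------------------------------------
# Temperature rhythm classification
# ---------------------------------------------------------------------------

@dataclass
class TempRhythmClass:
    label: str                   # "physiologic" | "abnormal" | "arrhythmic"
    dominant_period_h: float
    acrophase_h: float


def classify_temperature_rhythm(rhythm: RhythmEstimate,
                                fit: CosinorFit) -> TempRhythmClass:
    """Physiologic: significant dominant period within 24 +/- 2 h and a
    nocturnal acrophase in [22:01, 07:00] (closed, wrap-around clock).
    Abnormal: significant but failing either condition. Arrhythmic: no
    significant rhythm."""
    if not rhythm.significant:
        label = "arrhythmic"
    elif (abs(rhythm.dominant_period_h - 24.0) <= 2.0
          and clock_hour_in_night(fit.acrophase_h)):
        label = "physiologic"
    else:
        label = "abnormal"
    return TempRhythmClass(label=label,
                           dominant_period_h=rhythm.dominant_period_h,
                           acrophase_h=fit.acrophase_h)
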