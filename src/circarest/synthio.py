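"""Synthetic subjects and cohorts with the statistical structure the
analyses assume.

Each subject is generated from an explicit ground truth:

* activity — a 3-state Markov chain (inactive/rest IA, moderately active MA,
  highly active HA) on 5-min bins, with state-conditional lognormal counts
  disaggregated to minutes and rounded to integers. The chain's transition
  matrix switches smoothly between a day regime and a night regime gated by
  the subject's (realized) diary retiring/rising times, which is what gives
  the activity pattern its circadian structure;
* chest temperature — a two-harmonic (24 h + 12 h) cosinor plus AR(1) noise;
* light — an indoor daytime level, dim evening light and darkness in bed;
* cortisol — a 24-h cosine sampled on a 3-h daytime grid over two days;
* melatonin — a flat noisy baseline plus a logistic evening rise whose
  threshold-crossing time is the subject's true dim-light melatonin onset;
* diary — retiring/rising clock times drawn around phenotype-specific means.

The "robust" and "disrupted" phenotypes differ in night-rest stability,
daytime activity level, circadian amplitude of activity and temperature,
and diary regularity; their default parameter sets are calibrated so that
robust subjects land above and disrupted subjects at or below the 97.5%
dichotomy-index threshold in the large majority of draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import ingest
from .series import (ActivitySeries, DiaryDay, DiaryLog, LightSeries,
                     SalivaPanel, TemperatureSeries)

START = pd.Timestamp("2024-03-04 12:00:00")  # recordings start at noon
BIN_MIN = 5


# ---------------------------------------------------------------------------
# Truth parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class HmmTruth:
    """3-state emission/transition ground truth on 5-min bins.

    Emissions are lognormal on the count scale: log(count + 1) for a bin in
    state s is N(mean[s], sigma[s]). ``transition_night`` of None gives a
    time-homogeneous chain (no circadian modulation).
    """

    means: np.ndarray            # log(count+1) locations, ascending IA<MA<HA
    sigmas: np.ndarray
    transition_day: np.ndarray   # 3x3 row-stochastic
    transition_night: np.ndarray | None = None
    gate_width_h: float = 0.10   # softness of the day/night regime switch
    gate_lead_h: float = 0.20    # night regime leads retiring (settling down)
    minute_cv: float = 0.3       # within-bin minute-to-minute lognormal sd

    def __post_init__(self):
        self.means = np.asarray(self.means, float)
        self.sigmas = np.asarray(self.sigmas, float)
        for P in (self.transition_day, self.transition_night):
            if P is None:
                continue
            P = np.asarray(P, float)
            if P.shape != (3, 3) or np.any(P < 0) or np.any(P > 1):
                raise ValueError("transition matrix must be 3x3 with entries in [0,1]")
            if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-12:
                raise ValueError("transition matrix rows must sum to 1")
        if not np.all(np.diff(self.means) > 0):
            raise ValueError("emission locations must be ascending IA < MA < HA")
        if np.all(self.sigmas == 0):
            raise ValueError("degenerate truth: zero-variance emissions in all states")


@dataclass
class TempTruth:
    mesor_c: float = 35.6
    amp24_c: float = 0.5
    phase24_h: float = 2.5       # clock hour of the 24-h component maximum
    amp12_c: float = 0.15
    phase12_h: float = 3.0
    ar_phi: float = 0.9
    ar_sigma: float = 0.05

    def __post_init__(self):
        if self.amp24_c < 0 or self.amp12_c < 0:
            raise ValueError("temperature amplitudes must be >= 0")
        if not (0 <= self.phase24_h < 24):
            raise ValueError("acrophase must lie in [0, 24)")


@dataclass
class CortisolTruth:
    mesor: float = 10.0          # nmol/L
    amplitude: float = 6.0
    acrophase_h: float = 8.0
    noise_sd: float = 1.2

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("cortisol amplitude must be >= 0")
        if not (0 <= self.acrophase_h < 24):
            raise ValueError("acrophase must lie in [0, 24)")


@dataclass
class MelatoninTruth:
    baseline: float = 2.5        # pg/mL
    onset_h: float = 21.0        # true DLMO clock hour
    plateau: float = 25.0        # asymptotic rise above baseline
    tau_h: float = 0.15          # logistic time scale (brisk evening rise)
    midpoint_offset_h: float = 0.8  # logistic midpoint lag past the onset
    noise_cv: float = 0.10

    def __post_init__(self):
        if self.baseline <= 0 or self.plateau < 0:
            raise ValueError("melatonin levels must be positive")


@dataclass
class DiaryTruth:
    retiring_mean_h: float = 23.0  # clock hour (evening)
    rising_mean_h: float = 7.0
    retiring_sd_h: float = 0.35
    rising_sd_h: float = 0.35


@dataclass
class SubjectProfile:
    subject_id: str
    group: str                   # "patient" | "control"
    phenotype: str               # "robust" | "disrupted"
    age: float
    sex: str                     # "M" | "F"
    hmm_truth: HmmTruth
    temp_truth: TempTruth
    cortisol_truth: CortisolTruth
    melatonin_truth: MelatoninTruth
    diary_truth: DiaryTruth
    exercise_propensity: float
    seed: int
    covariate_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.phenotype not in ("robust", "disrupted"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")

    def activity_circadian_amplitude(self) -> float:
        """Half the day-night contrast of the expected activity level implied
        by the truth chain (acc/min); used only for profile-level checks."""
        level = np.exp(self.hmm_truth.means + self.hmm_truth.sigmas ** 2 / 2) - 1
        day = _stationary(self.hmm_truth.transition_day) @ level
        Pn = self.hmm_truth.transition_night
        night = day if Pn is None else _stationary(Pn) @ level
        return float((day - night) / 2.0)


def _stationary(P: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Default phenotype parameter sets (calibrated once; see docs/methods.md)
# ---------------------------------------------------------------------------

_DAY_P = {
    "robust": np.array([[0.30, 0.60, 0.10],
                        [0.05, 0.85, 0.10],
                        [0.02, 0.28, 0.70]]),
    "disrupted": np.array([[0.60, 0.37, 0.03],
                           [0.15, 0.80, 0.05],
                           [0.05, 0.35, 0.60]]),
}
_NIGHT_P = {
    "robust": np.array([[0.994, 0.006, 0.000],
                        [0.85, 0.15, 0.00],
                        [0.70, 0.30, 0.00]]),
    "disrupted": np.array([[0.935, 0.060, 0.005],
                           [0.45, 0.50, 0.05],
                           [0.30, 0.60, 0.10]]),
}
_MEANS = {"robust": np.array([1.5, 3.2, 5.0]),
          "disrupted": np.array([1.5, 2.9, 4.4])}
_SIGMAS = np.array([0.45, 0.50, 0.45])


def default_profile(subject_id: str, group: str, phenotype: str,
                    seed: int) -> SubjectProfile:
    """Phenotype-specific truth with per-subject variation drawn from ``seed``."""
    rng = np.random.default_rng(seed)
    robust = phenotype == "robust"

    Pn = _NIGHT_P[phenotype].copy()
    # jitter the night rest-interruption rate on the log-odds scale
    esc = Pn[0, 1] * float(np.exp(rng.normal(0.0, 0.25)))
    esc = min(esc, 0.5)
    Pn[0] = [1.0 - esc - Pn[0, 2], esc, Pn[0, 2]]
    hmm = HmmTruth(means=_MEANS[phenotype] + rng.normal(0, 0.08, 3),
                   sigmas=_SIGMAS.copy(),
                   transition_day=_DAY_P[phenotype].copy(),
                   transition_night=Pn)

    temp = TempTruth(
        mesor_c=35.6 + rng.normal(0, 0.2),
        amp24_c=max(0.05, (0.50 if robust else 0.22) + rng.normal(0, 0.05)),
        phase24_h=(2.5 + rng.normal(0, 0.7)) % 24 if robust
        else (13.0 + rng.normal(0, 2.0)) % 24,
        amp12_c=max(0.0, 0.15 + rng.normal(0, 0.03)),
        phase12_h=float(rng.uniform(0, 12)),
    )
    cort = CortisolTruth(
        mesor=10.0 + rng.normal(0, 1.0),
        amplitude=max(0.5, (6.0 if robust else 3.0) + rng.normal(0, 0.8)),
        acrophase_h=(8.0 + rng.normal(0, 0.8)) % 24,
        noise_sd=1.2 if robust else 2.0,
    )
    mel = MelatoninTruth(
        baseline=float(2.5 * np.exp(rng.normal(0, 0.04))
                       * (1.4 if group == "patient" else 1.0)),
        onset_h=float(np.clip((21.3 if robust else 20.8) + rng.normal(0, 0.8),
                              20.3, 22.6)),
        plateau=float(max(6.0, (25.0 if robust else 10.0)
                          * np.exp(rng.normal(0, 0.2)))),
    )
    diary = DiaryTruth(
        retiring_mean_h=23.0 + rng.normal(0, 0.4) + (0.5 if not robust else 0),
        rising_mean_h=7.0 + rng.normal(0, 0.4) + (0.5 if not robust else 0),
        retiring_sd_h=0.35 if robust else 1.10,
        rising_sd_h=0.35 if robust else 1.10,
    )
    if group == "patient":
        age = float(rng.integers(40, 83))
        sex = "M" if rng.random() < 0.84 else "F"
    else:
        age = float(rng.integers(21, 79))
        sex = "M" if rng.random() < 0.45 else "F"
    cov = {
        "meq_score": float(np.clip(rng.normal(58, 8), 16, 86)),
        "psqi_global": float(np.clip(rng.normal(5 if robust else 8, 2), 0, 21)),
        "hads_total": float(np.clip(rng.normal(7, 3), 0, 42)),
        "mdasi_sleep": float(np.clip(rng.normal(2 if robust else 4, 1.5), 0, 10)),
    }
    return SubjectProfile(
        subject_id=subject_id, group=group, phenotype=phenotype,
        age=age, sex=sex, hmm_truth=hmm, temp_truth=temp,
        cortisol_truth=cort, melatonin_truth=mel, diary_truth=diary,
        exercise_propensity=0.8 if robust else 0.2,
        seed=int(seed), covariate_truth=cov)


# ---------------------------------------------------------------------------
# Record
# ---------------------------------------------------------------------------

@dataclass
class SyntheticRecord:
    activity: ActivitySeries
    temperature: TemperatureSeries
    light: LightSeries
    diary: DiaryLog
    cortisol: SalivaPanel
    melatonin: SalivaPanel
    covariates: dict
    truth: SubjectProfile
    state_path_truth: np.ndarray | None = None   # per 5-min bin, 0=IA,1=MA,2=HA
    offbody_truth: np.ndarray | None = None      # per-minute injected-span mask


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------

def generate_subject(profile: SubjectProfile, days: int) -> SyntheticRecord:
    """Generate one subject's full record; deterministic given profile.seed."""
    if days < 3:
        raise ValueError("days must be >= 3 (72-h classification impossible)")
    rng = np.random.default_rng(profile.seed)
    n_min = days * 1440
    n_bins = days * (1440 // BIN_MIN)

    diary = _generate_diary(profile, days, rng)
    path = _simulate_states(profile.hmm_truth, diary, n_bins, rng)
    activity = _emit_activity(profile.hmm_truth, path, n_min, rng)
    temperature = _generate_temperature(profile.temp_truth, n_min, rng)
    light = _generate_light(diary, n_min, rng)
    cortisol = _generate_cortisol(profile.cortisol_truth, diary, rng)
    melatonin = _generate_melatonin(profile.melatonin_truth, rng)

    exercise_days = sum(1 for d in diary if d.exercise)
    covariates = {
        "subject_id": profile.subject_id, "group": profile.group,
        "age": profile.age, "sex": profile.sex,
        "exercise_days": exercise_days,
        **profile.covariate_truth,
    }
    return SyntheticRecord(activity=activity, temperature=temperature,
                           light=light, diary=diary, cortisol=cortisol,
                           melatonin=melatonin, covariates=covariates,
                           truth=profile, state_path_truth=path)


def _generate_diary(profile: SubjectProfile, days: int,
                    rng: np.random.Generator) -> DiaryLog:
    dt = profile.diary_truth
    entries = []
    for d in range(days):
        date = (START + pd.Timedelta(days=d)).normalize()
        ret_h = dt.retiring_mean_h + rng.normal(0, dt.retiring_sd_h)
        ris_h = dt.rising_mean_h + rng.normal(0, dt.rising_sd_h)
        ret_h = float(np.clip(ret_h, 20.0, 27.5))   # same evening..past midnight
        ris_h = float(np.clip(ris_h, 4.5, 11.5))
        retiring = date + pd.Timedelta(hours=ret_h)
        rising = date + pd.Timedelta(days=1, hours=ris_h)
        exercise = []
        if rng.random() < profile.exercise_propensity:
            ex_start = date + pd.Timedelta(hours=float(rng.uniform(14, 18)))
            exercise.append((ex_start,
                             ex_start + pd.Timedelta(minutes=int(rng.integers(30, 61)))))
        meals = [date + pd.Timedelta(hours=h + float(rng.normal(0, 0.3)))
                 for h in (8.0, 12.5, 19.0)]
        entries.append(DiaryDay(date=date, retiring=retiring, rising=rising,
                                exercise=exercise, meals=meals))
    return DiaryLog(days=entries)


def _transition_stack(truth: HmmTruth, diary: DiaryLog,
                      n_bins: int) -> np.ndarray:
    """Per-bin 3x3 transition matrices, blending day and night regimes."""
    Pd, Pn = truth.transition_day, truth.transition_night
    if Pn is None:
        return np.broadcast_to(Pd, (n_bins, 3, 3))
    w = np.zeros(n_bins)
    for day in diary:
        ret = (day.retiring - START).total_seconds() / 60.0 \
            - truth.gate_lead_h * 60.0
        ris = (day.rising - START).total_seconds() / 60.0
        mins = np.arange(n_bins) * BIN_MIN
        rel = (mins - ret) / 60.0
        span = (ris - ret) / 60.0
        wd = (expit(rel / truth.gate_width_h)
              * expit((span - rel) / truth.gate_width_h))
        w = np.maximum(w, wd)
    return w[:, None, None] * Pn + (1 - w)[:, None, None] * Pd


def _simulate_states(truth: HmmTruth, diary: DiaryLog, n_bins: int,
                     rng: np.random.Generator) -> np.ndarray:
    P = _transition_stack(truth, diary, n_bins)
    path = np.empty(n_bins, dtype=int)
    pi0 = _stationary(truth.transition_day)  # recording starts at noon
    path[0] = rng.choice(3, p=pi0)
    u = rng.random(n_bins)
    for t in range(1, n_bins):
        cdf = np.cumsum(P[t, path[t - 1]])
        path[t] = int(np.searchsorted(cdf, u[t]))
    return path


def _emit_activity(truth: HmmTruth, path: np.ndarray, n_min: int,
                   rng: np.random.Generator) -> ActivitySeries:
    n_bins = path.size
    # bin-level aggregate drawn on the log(count+1) scale, then spread over
    # minutes with lognormal weights and rounded to integer counts
    z = rng.normal(truth.means[path], truth.sigmas[path])
    bin_level = np.maximum(np.exp(z) - 1.0, 0.0)
    g = np.exp(rng.normal(0.0, truth.minute_cv, size=(n_bins, BIN_MIN)))
    g /= g.mean(axis=1, keepdims=True)
    minutes = np.rint(bin_level[:, None] * g).reshape(-1)[:n_min]
    return ActivitySeries(start=START, values=np.maximum(minutes, 0.0),
                          missing=np.zeros(n_min, bool))


def _generate_temperature(truth: TempTruth, n_min: int,
                          rng: np.random.Generator) -> TemperatureSeries:
    h = (START.hour + np.arange(n_min) / 60.0) % 24.0
    base = (truth.mesor_c
            + truth.amp24_c * np.cos(2 * np.pi * (h - truth.phase24_h) / 24.0)
            + truth.amp12_c * np.cos(2 * np.pi * (h - truth.phase12_h) / 12.0))
    noise = np.empty(n_min)
    e = rng.normal(0, truth.ar_sigma, n_min)
    noise[0] = e[0] / np.sqrt(1 - truth.ar_phi ** 2)
    for i in range(1, n_min):
        noise[i] = truth.ar_phi * noise[i - 1] + e[i]
    return TemperatureSeries(start=START, values=base + noise,
                             missing=np.zeros(n_min, bool))


def _generate_light(diary: DiaryLog, n_min: int,
                    rng: np.random.Generator) -> LightSeries:
    idx = START + pd.to_timedelta(np.arange(n_min), unit="m")
    h = (START.hour + np.arange(n_min) / 60.0) % 24.0
    lux = np.where((h >= 8) & (h < 19), 250.0,
                   np.where((h >= 19) | (h < 1), 8.0, 0.0))
    lux = lux * np.exp(rng.normal(0, 0.25, n_min))
    in_bed = np.zeros(n_min, bool)
    for d in diary:
        in_bed |= (idx >= d.retiring) & (idx < d.rising)
    lux[in_bed] = 0.0
    return LightSeries(start=START, values=lux, missing=np.zeros(n_min, bool))


_CORTISOL_GRID_H = (7.0, 10.0, 13.0, 16.0, 19.0, 22.0)


def _generate_cortisol(truth: CortisolTruth, diary: DiaryLog,
                       rng: np.random.Generator) -> SalivaPanel:
    """12 samples on a 3-h daytime grid over the first 2 full days, anchored
    at the diary rising time (first sample within an hour of getting up)."""
    times, conc = [], []
    for day in (1, 2):
        date = (START + pd.Timedelta(days=day)).normalize()
        rise_h = ((diary.days[day - 1].rising - date).total_seconds() / 3600.0
                  if day - 1 < len(diary.days) else 7.0)
        for gh in _CORTISOL_GRID_H:
            hh = max(gh, min(rise_h + 0.5, gh + 1.0)) + rng.normal(0, 0.1)
            t = date + pd.Timedelta(hours=hh)
            clock = hh % 24.0
            y = (truth.mesor
                 + truth.amplitude * np.cos(2 * np.pi * (clock - truth.acrophase_h) / 24.0)
                 + rng.normal(0, truth.noise_sd))
            times.append(t)
            conc.append(max(0.3, y))
    order = np.argsort(pd.DatetimeIndex(times))
    return SalivaPanel(analyte="cortisol",
                       times=[times[i] for i in order],
                       concentrations=np.asarray(conc)[order])


def _generate_melatonin(truth: MelatoninTruth,
                        rng: np.random.Generator) -> SalivaPanel:
    """6 hourly evening samples from 19:00; logistic rise whose midpoint lags
    the labeled onset so that, at default noise, the noiseless curve crosses
    the expected individual threshold (baseline + 2 SD) at the onset itself."""
    date = (START + pd.Timedelta(days=3)).normalize()
    mid = truth.onset_h + truth.midpoint_offset_h
    times, conc = [], []
    for k in range(6):
        hh = 19.0 + k + rng.normal(0, 0.03)
        rise = truth.plateau / (1.0 + np.exp(-(hh - mid) / truth.tau_h))
        y = truth.baseline * np.exp(rng.normal(0, truth.noise_cv)) + rise
        times.append(date + pd.Timedelta(hours=hh))
        conc.append(max(0.1, y))
    return SalivaPanel(analyte="melatonin", times=times,
                       concentrations=np.asarray(conc))


# ---------------------------------------------------------------------------
# Missingness injection (off-body "shower" spans)
# ---------------------------------------------------------------------------

def inject_missingness(record: SyntheticRecord, events_per_day: float,
                       room_temp_c: float = 21.0,
                       decay_tau_min: float = 2.0) -> SyntheticRecord:
    """Insert sensor-off spans: temperature decays exponentially toward room
    temperature and plateaus there; activity over the span is masked missing.
    The injected-minute truth mask is retained for ingest-stage validation."""
    if events_per_day < 0:
        raise ValueError("rate must be >= 0")
    n = record.activity.n
    days = n / 1440.0
    n_spans = int(round(events_per_day * days))
    if n_spans == 0:
        return record
    rng = np.random.default_rng(np.random.SeedSequence(
        [record.truth.seed & 0x7FFFFFFF, 0x0FFB0D7]))
    spans, mask = [], np.zeros(n, bool)
    tries = 0
    while len(spans) < n_spans and tries < 1000 * n_spans:
        tries += 1
        dur = int(rng.integers(10, 41))
        t0 = int(rng.integers(0, n - dur))
        if mask[max(0, t0 - 5):t0 + dur + 5].any():
            continue
        spans.append((t0, dur))
        mask[t0:t0 + dur] = True
    if mask.mean() > 0.5:
        raise ValueError("rate too high: more than 50% of data would be removed")

    temp = record.temperature.values.copy()
    act_missing = record.activity.missing.copy()
    for t0, dur in spans:
        t_on = temp[t0 - 1] if t0 > 0 else room_temp_c + 0.5
        k = np.arange(dur)
        temp[t0:t0 + dur] = (room_temp_c + (t_on - room_temp_c)
                             * np.exp(-k / decay_tau_min)
                             + rng.normal(0, 0.05, dur))
        act_missing[t0:t0 + dur] = True
    return replace(record,
                   temperature=replace(record.temperature, values=temp),
                   activity=replace(record.activity, missing=act_missing),
                   offbody_truth=mask)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Subject counts per (group, phenotype), plus the recording length."""

    counts: dict = field(default_factory=lambda: {
        ("patient", "disrupted"): 13, ("patient", "robust"): 12,
        ("control", "disrupted"): 4, ("control", "robust"): 29,
    })
    days: int = 7

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        counts = {}
        for group, sub in d.get("counts", d).items():
            if group == "days":
                continue
            for phenotype, n in sub.items():
                counts[(group, phenotype)] = int(n)
        return cls(counts=counts, days=int(d.get("days", 7)))


@dataclass
class Cohort:
    records: list
    covariates: pd.DataFrame


def subject_seed(master_seed: int, index: int) -> int:
    """Stable per-subject seed below 2**31, derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cohort(spec: CohortSpec, seed: int) -> Cohort:
    total = sum(spec.counts.values())
    if total == 0:
        warnings.warn("zero subjects requested; returning an empty cohort")
        return Cohort(records=[], covariates=pd.DataFrame())
    records, rows = [], []
    idx = 0
    for (group, phenotype), count in sorted(spec.counts.items()):
        for _ in range(count):
            sid = f"{group[:3]}{idx:03d}"
            prof = default_profile(sid, group, phenotype,
                                   subject_seed(seed, idx))
            rec = generate_subject(prof, spec.days)
            records.append(rec)
            rows.append({**rec.covariates, "phenotype": phenotype,
                         "seed": prof.seed})
            idx += 1
    return Cohort(records=records, covariates=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# File output (same CSV dialects ingest reads)
# ---------------------------------------------------------------------------

def write_subject_dir(record: SyntheticRecord, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ingest.write_series(record.activity, path / "activity.csv")
    ingest.write_series(record.temperature, path / "temperature.csv")
    ingest.write_series(record.light, path / "light.csv")
    ingest.write_diary(record.diary, path / "diary.csv")
    ingest.write_saliva([record.cortisol, record.melatonin],
                        path / "saliva.csv")
    pd.DataFrame([record.covariates]).to_csv(path / "covariates.csv",
                                             index=False)


def write_cohort_dir(cohort: Cohort, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for rec in cohort.records:
        write_subject_dir(rec, path / rec.truth.subject_id)
    cohort.covariates.to_csv(path / "cohort_covariates.csv", index=False)
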