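"""3-state hidden Markov modelling of 5-min rest-activity data.

States are inactive/rest (IA), moderately active (MA) and highly active
(HA), with Gaussian emissions on the log(count + 1) scale and states
relabeled by ascending emission location after fitting. The homogeneous
model is fitted by EM (hmmlearn) with multiple restarts; an optional
harmonic variant modulates the transition-matrix rows over the 24-h clock
through multinomial logits on the first two harmonics (24 h and 12 h),
which produces periodic state-probability profiles.

Derived circadian quantifiers:

* P1-1 — probability of remaining in the rest state over one 5-min step
  (1 - P1-1 estimates rest interruption); under the harmonic model both
  the clock-time average and the full profile are available;
* mid MA / mid HA — back-transformed state locations in acc/min;
* rhythm index RI in [0, 1] — day-to-day regularity and quality of the rest
  state (see ``derive_metrics``; definition tag "jaccard-posterior-v1");
* center-of-rest — posterior-weighted circular mean clock time of rest;
* per-day sleep onset / wake / duration from nocturnal rest runs, and the
  across-day sample SD of durations ("sleep duration variability").
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy.optimize import minimize

from .config import HmmConfig
from .series import (ActivitySeries, MinuteSeries, NIGHT_END_H, NIGHT_START_H,
                     circular_mean_hour)

STATE_LABELS = ("IA", "MA", "HA")
RI_DEFINITION = "jaccard-posterior-v1"


class HmmError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class HmmModel:
    n_states: int
    means: np.ndarray                 # log(count+1) locations, ascending
    sigmas: np.ndarray
    transition: np.ndarray            # homogeneous matrix / harmonic base point
    startprob: np.ndarray
    loglik: float
    converged: bool
    bin_min: int = 5
    harmonic_base: np.ndarray | None = None   # (n, n) logits
    harmonic_coef: np.ndarray | None = None   # (n, n, 4) sin/cos 24h+12h
    degenerate: bool = False
    flags: list = field(default_factory=list)

    @property
    def is_harmonic(self) -> bool:
        return self.harmonic_coef is not None

    def transition_at(self, clock_h: np.ndarray) -> np.ndarray:
        """Per-time row-stochastic transition matrices, shape (T, n, n)."""
        clock_h = np.atleast_1d(np.asarray(clock_h, float))
        if not self.is_harmonic:
            return np.broadcast_to(self.transition,
                                   (clock_h.size, self.n_states, self.n_states))
        f = _harmonic_features(clock_h)                    # (T, 4)
        logits = self.harmonic_base[None] + np.einsum(
            "ijk,tk->tij", self.harmonic_coef, f)
        logits -= logits.max(axis=2, keepdims=True)
        P = np.exp(logits)
        return P / P.sum(axis=2, keepdims=True)

    @property
    def p11(self) -> float:
        """P(IA -> IA): the raw matrix entry (homogeneous model)."""
        return float(self.transition[0, 0])

    def p11_time_average(self, step_h: float = 0.25) -> float:
        """Clock-time average of P(IA -> IA) over 24 h (harmonic model); for
        the homogeneous model this equals the raw entry."""
        grid = np.arange(0.0, 24.0, step_h)
        return float(self.transition_at(grid)[:, 0, 0].mean())

    def mid_levels(self) -> np.ndarray:
        """Back-transformed state locations in acc/min."""
        return np.exp(self.means) - 1.0


def _harmonic_features(clock_h: np.ndarray) -> np.ndarray:
    w = 2 * np.pi * clock_h / 24.0
    return np.stack([np.sin(w), np.cos(w), np.sin(2 * w), np.cos(2 * w)],
                    axis=-1)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _prepare(activity_5min: MinuteSeries) -> tuple[np.ndarray, np.ndarray]:
    y = np.log1p(np.maximum(activity_5min.values, 0.0))
    return y, activity_5min.missing.copy()


def fit_hmm(activity_5min: MinuteSeries, harmonic: bool = False,
            seed: int = 0, config: HmmConfig | None = None) -> HmmModel:
    """Fit the rest-activity HMM by EM with ``n_restarts`` restarts, keeping
    the best log-likelihood; states relabeled IA < MA < HA by location.

    A fit in which any state holds under ``degenerate_mass`` of the posterior
    mass is refit with 2 states and flagged.
    """
    cfg = config or HmmConfig()
    y, missing = _prepare(activity_5min)
    n_ok = int((~missing).sum())
    if n_ok < 288:
        raise HmmError(f"need >= 288 non-missing 5-min bins, got {n_ok}")

    model = _fit_homogeneous(y, missing, cfg.n_states, seed, cfg)
    if model.degenerate and cfg.n_states == 3:
        model2 = _fit_homogeneous(y, missing, 2, seed, cfg)
        model2.flags.append("degenerate 3-state fit; refit with 2 states")
        model2.degenerate = True
        model = model2
    model.bin_min = activity_5min.step_min
    if harmonic and not model.degenerate:
        model = _fit_harmonic(model, y, missing, activity_5min.clock_hours(),
                              cfg)
    return model


def _fit_homogeneous(y: np.ndarray, missing: np.ndarray, n_states: int,
                     seed: int, cfg: HmmConfig) -> HmmModel:
    obs = y[~missing]
    if np.ptp(obs) < 1e-12:
        # constant series: no state structure at all
        m = float(obs[0])
        k = min(2, n_states)
        model = HmmModel(n_states=k,
                         means=np.array([m] * k) + np.arange(k) * 1e-6,
                         sigmas=np.full(k, 1e-3),
                         transition=np.full((k, k), 1.0 / k),
                         startprob=np.full(k, 1.0 / k),
                         loglik=float("nan"), converged=False,
                         degenerate=True,
                         flags=["constant series: no 3-state structure"])
        return model

    segments = _contiguous_segments(~missing)
    X = np.concatenate([y[a:b] for a, b in segments])[:, None]
    lengths = [b - a for a, b in segments]
    qs = np.quantile(obs, np.linspace(0.15, 0.85, n_states))

    best = None
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x4E57])
    for child in ss.spawn(cfg.n_restarts):
        rng = np.random.default_rng(child)
        hm = GaussianHMM(n_components=n_states, covariance_type="diag",
                         n_iter=cfg.max_iter, tol=cfg.tol * abs(len(X)),
                         init_params="", params="stmc",
                         random_state=np.random.RandomState(
                             int(child.generate_state(1)[0] % (2 ** 31))))
        hm.startprob_ = np.full(n_states, 1.0 / n_states)
        tm = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
        np.fill_diagonal(tm, 0.9)
        hm.transmat_ = tm
        hm.means_ = (qs * np.exp(rng.normal(0, 0.05, n_states)))[:, None]
        hm.covars_ = np.full((n_states, 1), np.var(obs) / n_states)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                hm.fit(X, lengths)
                ll = float(hm.score(X, lengths))
            except (ValueError, np.linalg.LinAlgError):
                continue
        if best is None or ll > best[0]:
            best = (ll, hm)
    if best is None:
        raise HmmError("EM failed in all restarts")
    ll, hm = best

    order = np.argsort(hm.means_.ravel())
    means = hm.means_.ravel()[order]
    sigmas = np.sqrt(hm.covars_.reshape(n_states, -1).ravel()[order])
    trans = hm.transmat_[np.ix_(order, order)]
    start = hm.startprob_[order]
    model = HmmModel(n_states=n_states, means=means, sigmas=sigmas,
                     transition=trans, startprob=start, loglik=ll,
                     converged=bool(hm.monitor_.converged))
    # posterior occupancy check for degenerate states
    logB = _emission_logprob(y, missing, means, sigmas)
    _, gamma, _ = _forward_backward(logB, trans, start)
    occupancy = gamma.mean(axis=0)
    if np.any(occupancy < cfg.degenerate_mass):
        model.degenerate = True
        model.flags.append(
            f"state occupancy {np.round(occupancy, 4).tolist()} below "
            f"{cfg.degenerate_mass:.0%} for some state")
    return model


def _contiguous_segments(ok: np.ndarray) -> list:
    segs, i, n = [], 0, ok.size
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            segs.append((i, j))
            i = j
        else:
            i += 1
    return segs


# ---------------------------------------------------------------------------
# Forward-backward / Viterbi with missing bins and time-varying transitions
# ---------------------------------------------------------------------------

def _emission_logprob(y, missing, means, sigmas) -> np.ndarray:
    sig = np.maximum(sigmas, 1e-6)
    logB = (-0.5 * ((y[:, None] - means[None]) / sig[None]) ** 2
            - np.log(sig[None]) - 0.5 * np.log(2 * np.pi))
    logB[missing] = 0.0  # no emission term: posteriors propagate via the chain
    return logB


def _trans_stack(model_or_P, T, clock_h=None):
    if isinstance(model_or_P, HmmModel):
        if model_or_P.is_harmonic:
            return model_or_P.transition_at(clock_h)
        P = model_or_P.transition
    else:
        P = model_or_P
    return np.broadcast_to(P, (T,) + P.shape)


def _forward_backward(logB, trans, startprob, clock_h=None):
    """Scaled forward-backward. ``trans`` is a matrix, a (T,n,n) stack or an
    HmmModel. Returns (loglik, gamma (T,n), xi (T-1,n,n))."""
    T, n = logB.shape
    P = _trans_stack(trans, T, clock_h)
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    alpha = np.empty((T, n))
    c = np.empty(T)
    a = startprob * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ P[t]) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, n))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (P[t + 1] @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = (alpha[:-1, :, None] * P[1:]
          * (B[1:] * beta[1:])[:, None, :] / c[1:, None, None])
    xi /= xi.sum(axis=(1, 2), keepdims=True)
    loglik = float(np.sum(np.log(c)) + np.sum(logB.max(axis=1)))
    return loglik, gamma, xi


def _viterbi(logB, trans, startprob, clock_h=None) -> np.ndarray:
    T, n = logB.shape
    P = _trans_stack(trans, T, clock_h)
    with np.errstate(divide="ignore"):
        logP = np.log(np.maximum(P, 1e-300))
        logpi = np.log(np.maximum(startprob, 1e-300))
    delta = logpi + logB[0]
    psi = np.zeros((T, n), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logP[t]
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(n)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# Harmonic EM
# ---------------------------------------------------------------------------

def _fit_harmonic(base: HmmModel, y, missing, clock_h, cfg: HmmConfig) -> HmmModel:
    """EM for transition-logit harmonic modulation, warm-started from the
    homogeneous fit. Emissions and start probabilities are re-estimated too."""
    n = base.n_states
    feats = np.hstack([np.ones((y.size, 1)), _harmonic_features(clock_h)])  # (T,5)
    B_logit = np.log(np.maximum(base.transition, 1e-8))
    C = np.zeros((n, n, 4))
    means, sigmas, start = base.means.copy(), base.sigmas.copy(), \
        base.startprob.copy()
    model = HmmModel(n_states=n, means=means, sigmas=sigmas,
                     transition=base.transition.copy(), startprob=start,
                     loglik=-np.inf, converged=False, bin_min=base.bin_min,
                     harmonic_base=B_logit, harmonic_coef=C,
                     flags=list(base.flags))
    prev_ll = -np.inf
    for _ in range(cfg.harmonic_em_iter):
        logB = _emission_logprob(y, missing, model.means, model.sigmas)
        ll, gamma, xi = _forward_backward(logB, model, model.startprob,
                                          clock_h=clock_h)
        model.loglik = ll
        if ll - prev_ll < cfg.tol * abs(ll) * y.size and np.isfinite(prev_ll):
            model.converged = True
            break
        prev_ll = ll
        # M-step: emissions (non-missing bins only)
        g = gamma.copy()
        g[missing] = 0.0
        w = g.sum(axis=0)
        model.means = (g * y[:, None]).sum(axis=0) / np.maximum(w, 1e-12)
        var = (g * (y[:, None] - model.means[None]) ** 2).sum(axis=0) \
            / np.maximum(w, 1e-12)
        model.sigmas = np.sqrt(np.maximum(var, 1e-6))
        model.startprob = gamma[0]
        # M-step: per-row weighted multinomial logit on [1, harmonics]
        for i in range(n):
            theta0 = np.hstack([model.harmonic_base[i, 1:, None],
                                model.harmonic_coef[i, 1:, :]]).ravel() \
                if n > 1 else np.zeros(0)
            theta = _fit_row_logit(theta0, xi[:, i, :], feats[1:], n)
            mat = theta.reshape(n - 1, 5)
            model.harmonic_base[i] = np.concatenate([[0.0], mat[:, 0]])
            model.harmonic_coef[i] = np.vstack([np.zeros(4), mat[:, 1:]])
        model.transition = model.transition_at(np.arange(0, 24, 0.25)).mean(axis=0)
    return model


def _fit_row_logit(theta0, xi_row, feats, n):
    """Maximize sum_t sum_j xi[t,j] log softmax_j(theta_j . feats[t]); the
    first destination state is the zero-logit reference."""
    T = feats.shape[0]

    def negll_grad(theta):
        mat = theta.reshape(n - 1, 5)
        logits = np.hstack([np.zeros((T, 1)), feats @ mat.T])
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        r = xi_row.sum(axis=1)
        nll = -float(np.sum(xi_row * np.log(np.maximum(p, 1e-300))))
        grad = -((xi_row[:, 1:] - r[:, None] * p[:, 1:]).T @ feats)
        return nll, grad.ravel()

    res = minimize(negll_grad, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 200})
    return res.x


# ---------------------------------------------------------------------------
# Decoding and derived quantifiers
# ---------------------------------------------------------------------------

@dataclass
class StatePath:
    series: MinuteSeries
    states: np.ndarray        # most-likely (Viterbi) state per bin
    posteriors: np.ndarray    # (T, n) forward-backward posteriors
    loglik: float


def decode_states(model: HmmModel, activity_5min: MinuteSeries) -> StatePath:
    """Global (Viterbi) decoding plus per-bin forward-backward posteriors;
    missing bins carry chain-propagated posteriors (no emission term)."""
    if activity_5min.step_min != model.bin_min:
        raise HmmError(f"series binned at {activity_5min.step_min} min but "
                       f"model fitted on {model.bin_min}-min bins")
    y, missing = _prepare(activity_5min)
    clock = activity_5min.clock_hours()
    logB = _emission_logprob(y, missing, model.means, model.sigmas)
    ll, gamma, _ = _forward_backward(logB, model, model.startprob, clock_h=clock)
    states = _viterbi(logB, model, model.startprob, clock_h=clock)
    return StatePath(series=activity_5min, states=states, posteriors=gamma,
                     loglik=ll)


@dataclass
class SleepWindows:
    onsets: list              # per retained day, clock timestamps
    wakes: list
    durations_h: list
    sleep_duration_sd_h: float
    n_days_omitted: int


@dataclass
class HmmDerived:
    mid_MA: float
    mid_HA: float
    p11: float
    p11_time_average: float
    ri: float
    ri_definition: str
    center_of_rest_h: float
    sleep: SleepWindows | None
    flags: list = field(default_factory=list)


def derive_metrics(model: HmmModel, path: StatePath) -> HmmDerived:
    """All HMM-derived circadian quantifiers for one decoded subject."""
    flags = list(model.flags)
    mids = model.mid_levels()
    mid_MA = float(mids[1]) if model.n_states >= 2 else float("nan")
    mid_HA = float(mids[-1]) if model.n_states >= 2 else float("nan")

    ia = path.states == 0
    post_ia = path.posteriors[:, 0]
    if not ia.any():
        flags.append("no IA-decoded bins: RI and center-of-rest undefined")
        ri = float("nan")
        center = float("nan")
    else:
        ri = rhythm_index(path)
        center = circular_mean_hour(path.series.clock_hours()[ia],
                                    weights=post_ia[ia])
    try:
        sleep = estimate_sleep_windows(path)
    except HmmError as exc:
        sleep = None
        flags.append(str(exc))
    return HmmDerived(mid_MA=mid_MA, mid_HA=mid_HA, p11=model.p11,
                      p11_time_average=model.p11_time_average(),
                      ri=ri, ri_definition=RI_DEFINITION,
                      center_of_rest_h=center, sleep=sleep, flags=flags)


def rhythm_index(path: StatePath) -> float:
    """RI = mean weighted-Jaccard overlap, over all day pairs, of the
    IA-decoded bin sets on the 24-h clock grid.

    Each clock bin of each complete study day carries the mean IA posterior
    of the IA run it belongs to (0 if not decoded IA). RI is 1 for identical
    daily rest blocks decoded with posterior 1 and tends to 0 when no
    consistent rest state recurs from day to day.
    """
    series = path.series
    per_day = 24 * 60 // series.step_min
    day_idx = series.study_day_index()
    run_weight = _run_mean_ia_posterior(path)
    days = []
    for d in np.unique(day_idx):
        sel = day_idx == d
        if sel.sum() != per_day:
            continue  # incomplete study day
        days.append(run_weight[sel])
    if len(days) < 2:
        return float("nan")
    overlaps = []
    for wa, wb in itertools.combinations(days, 2):
        union = np.maximum(wa, wb).sum()
        if union == 0:
            continue
        overlaps.append(np.minimum(wa, wb).sum() / union)
    return float(np.mean(overlaps)) if overlaps else float("nan")


def _run_mean_ia_posterior(path: StatePath) -> np.ndarray:
    """Per-bin weight: mean IA posterior within the IA run containing the
    bin, zero outside IA runs."""
    ia = path.states == 0
    w = np.zeros(path.states.size)
    for a, b in _contiguous_segments(ia):
        w[a:b] = path.posteriors[a:b, 0].mean()
    return w


def estimate_sleep_windows(path: StatePath) -> SleepWindows:
    """Per study day, the longest maximal IA run intersecting the 22:01-07:00
    night span gives sleep onset (run start), wake (run end) and duration."""
    series = path.series
    idx = series.time_index()
    day_idx = series.study_day_index()
    n_days = int(day_idx.max()) + 1
    if n_days < 3:
        raise HmmError("need >= 3 study days for sleep-window estimation")
    runs = _contiguous_segments(path.states == 0)
    first_noon = idx[0].normalize() + (
        np.timedelta64(12, "h") if idx[0].hour >= 12
        else np.timedelta64(-12, "h"))

    onsets, wakes, durations = [], [], []
    omitted = 0
    for d in range(n_days):
        night_a = first_noon + np.timedelta64(d, "D") \
            + np.timedelta64(int((NIGHT_START_H - 12) * 60), "m")
        night_b = first_noon + np.timedelta64(d + 1, "D") \
            + np.timedelta64(int(NIGHT_END_H * 60) - 12 * 60, "m")
        best = None
        for a, b in runs:
            run_a, run_b = idx[a], idx[b - 1] + np.timedelta64(
                series.step_min, "m")
            if run_b <= night_a or run_a >= night_b:
                continue
            length = b - a
            if best is None or length > best[0]:
                best = (length, run_a, run_b)
        if best is None:
            omitted += 1
            continue
        length, run_a, run_b = best
        onsets.append(run_a)
        wakes.append(run_b)
        durations.append(length * series.step_min / 60.0)
    if len(durations) < 2:
        raise HmmError("fewer than 2 days with a nocturnal rest run")
    sd = float(np.std(durations, ddof=1))
    return SleepWindows(onsets=onsets, wakes=wakes, durations_h=durations,
                        sleep_duration_sd_h=sd, n_days_omitted=omitted)
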