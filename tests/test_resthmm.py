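import numpy as np
import pandas as pd
import pytest

from circarest import dichotomy, ingest, resthmm, synthio
from circarest.series import MinuteSeries

START = pd.Timestamp("2024-03-04 12:00:00")

# balanced-occupancy homogeneous truth used for recovery checks
P_TRUTH = np.array([[0.90, 0.07, 0.03],
                    [0.06, 0.88, 0.06],
                    [0.03, 0.09, 0.88]])
MEANS_TRUTH = np.array([1.5, 3.2, 5.0])


def _homogeneous_record(seed, days=7):
    prof = synthio.default_profile("h", "patient", "robust", seed)
    prof.hmm_truth = synthio.HmmTruth(
        means=MEANS_TRUTH.copy(), sigmas=np.array([0.45, 0.5, 0.45]),
        transition_day=P_TRUTH.copy(), transition_night=None)
    return synthio.generate_subject(prof, days)


def _bins(record):
    return ingest.aggregate(record.activity, 5, "mean")


class TestFit:
    def test_recovers_known_truth(self):
        hits = 0
        for i in range(5):
            rec = _homogeneous_record(600 + i)
            m = resthmm.fit_hmm(_bins(rec), seed=i)
            hits += (np.max(np.abs(m.transition - P_TRUTH)) <= 0.05
                     and np.max(np.abs(m.means - MEANS_TRUTH)
                                / MEANS_TRUTH) <= 0.10)
        assert hits >= 4

    def test_deterministic_given_seed(self):
        rec = _homogeneous_record(601)
        m1 = resthmm.fit_hmm(_bins(rec), seed=9)
        m2 = resthmm.fit_hmm(_bins(rec), seed=9)
        assert np.array_equal(m1.means, m2.means)
        assert np.array_equal(m1.transition, m2.transition)

    def test_emission_locations_ascending(self):
        rec = _homogeneous_record(602)
        m = resthmm.fit_hmm(_bins(rec), seed=0)
        assert np.all(np.diff(m.means) > 0)

    def test_all_zero_series_degenerate_two_state_flag(self):
        s = MinuteSeries(start=START, values=np.zeros(2016),
                         missing=np.zeros(2016, bool), step_min=5)
        m = resthmm.fit_hmm(s, seed=0)
        assert m.degenerate
        assert m.n_states == 2

    def test_too_short_series_rejected(self):
        s = MinuteSeries(start=START, values=np.random.default_rng(0).
                         gamma(1, 10, 100), missing=np.zeros(100, bool),
                         step_min=5)
        with pytest.raises(resthmm.HmmError, match="288"):
            resthmm.fit_hmm(s, seed=0)


class TestDecode:
    def test_separated_emissions_match_threshold_oracle(self):
        rng = np.random.default_rng(3)
        truth_path = rng.integers(0, 3, 2016)
        levels = np.array([0.0, 50.0, 500.0])
        v = levels[truth_path] * np.exp(rng.normal(0, 0.05, 2016))
        s = MinuteSeries(start=START, values=v, missing=np.zeros(2016, bool),
                         step_min=5)
        m = resthmm.fit_hmm(s, seed=1)
        path = resthmm.decode_states(m, s)
        # oracle: nearest emission location on the log scale
        y = np.log1p(v)
        oracle = np.argmin(np.abs(y[:, None] - m.means[None]), axis=1)
        assert np.mean(path.states == oracle) >= 0.99

    def test_posteriors_normalized_everywhere(self):
        rec = _homogeneous_record(603)
        bins = _bins(rec)
        miss = bins.missing.copy()
        miss[100:120] = True  # posteriors must propagate over missing bins
        gappy = MinuteSeries(start=bins.start, values=bins.values,
                             missing=miss, step_min=5)
        m = resthmm.fit_hmm(gappy, seed=2)
        path = resthmm.decode_states(m, gappy)
        assert np.allclose(path.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_bin_mismatch_rejected(self):
        rec = _homogeneous_record(604)
        m = resthmm.fit_hmm(_bins(rec), seed=0)
        hourly = ingest.aggregate(rec.activity, 60, "mean")
        with pytest.raises(resthmm.HmmError, match="binned"):
            resthmm.decode_states(m, hourly)


def _synthetic_path(states, posteriors=None, days=4):
    n = days * 288
    s = MinuteSeries(start=START, values=np.zeros(n),
                     missing=np.zeros(n, bool), step_min=5)
    post = np.zeros((n, 3))
    if posteriors is None:
        post[np.arange(n), states] = 1.0
    else:
        post[:] = posteriors
    return resthmm.StatePath(series=s, states=states, posteriors=post,
                             loglik=0.0)


class TestDerived:
    def test_perfectly_periodic_rest_block_gives_ri_one(self):
        states = np.ones(4 * 288, dtype=int)
        for d in range(4):
            a = d * 288 + int(10.5 * 12)   # 22:30 -> 06:30 each night
            states[a:a + 96] = 0
        path = _synthetic_path(states)
        assert resthmm.rhythm_index(path) == pytest.approx(1.0)
        m = resthmm.HmmModel(n_states=3, means=np.array([1.0, 3.0, 5.0]),
                             sigmas=np.ones(3), transition=np.eye(3),
                             startprob=np.ones(3) / 3, loglik=0.0,
                             converged=True, bin_min=5)
        derived = resthmm.derive_metrics(m, path)
        # block 22:30-06:30 -> circular midpoint 02:30
        assert derived.center_of_rest_h == pytest.approx(2.5, abs=0.1)

    def test_shuffled_path_ri_indistinguishable_from_null(self):
        rng = np.random.default_rng(8)
        states = np.ones(4 * 288, dtype=int)
        for d in range(4):
            a = d * 288 + 126
            states[a:a + 96] = 0
        shuffled = rng.permutation(states)
        ri_shuffled = resthmm.rhythm_index(_synthetic_path(shuffled))
        null = [resthmm.rhythm_index(_synthetic_path(rng.permutation(states)))
                for _ in range(200)]
        assert ri_shuffled <= np.percentile(null, 95)
        # and far below the structured path's RI
        assert ri_shuffled < 0.5

    def test_p11_matches_empirical_transition_fraction(self):
        rng = np.random.default_rng(12)
        n = 100_000
        path = np.empty(n, dtype=int)
        path[0] = 0
        u = rng.random(n)
        for t in range(1, n):
            path[t] = np.searchsorted(np.cumsum(P_TRUTH[path[t - 1]]), u[t])
        ia = path[:-1] == 0
        empirical = np.mean(path[1:][ia] == 0)
        assert abs(empirical - P_TRUTH[0, 0]) <= 0.02

    def test_relabeling_invariance(self):
        """Permuting state labels before relabeling yields identical
        derived metrics, because fitting relabels by emission location."""
        rec = _homogeneous_record(605)
        bins = _bins(rec)
        m = resthmm.fit_hmm(bins, seed=4)
        perm = [2, 0, 1]
        m_perm = resthmm.HmmModel(
            n_states=3, means=m.means[perm], sigmas=m.sigmas[perm],
            transition=m.transition[np.ix_(perm, perm)],
            startprob=m.startprob[perm], loglik=m.loglik, converged=True,
            bin_min=5)
        order = np.argsort(m_perm.means)
        m_back = resthmm.HmmModel(
            n_states=3, means=m_perm.means[order],
            sigmas=m_perm.sigmas[order],
            transition=m_perm.transition[np.ix_(order, order)],
            startprob=m_perm.startprob[order], loglik=m.loglik,
            converged=True, bin_min=5)
        d1 = resthmm.derive_metrics(m, resthmm.decode_states(m, bins))
        d2 = resthmm.derive_metrics(m_back,
                                    resthmm.decode_states(m_back, bins))
        assert d1.p11 == pytest.approx(d2.p11)
        assert d1.ri == pytest.approx(d2.ri)
        assert d1.mid_MA == pytest.approx(d2.mid_MA)


class TestSleepWindows:
    def test_identical_nightly_runs_give_zero_sd(self):
        states = np.ones(4 * 288, dtype=int)
        for d in range(4):
            a = d * 288 + int(11 * 12)   # 23:00-07:00
            states[a:a + 96] = 0
        sw = resthmm.estimate_sleep_windows(_synthetic_path(states))
        assert sw.sleep_duration_sd_h == pytest.approx(0.0)
        assert all(d == pytest.approx(8.0) for d in sw.durations_h)

    def test_known_durations_sample_sd(self):
        states = np.ones(4 * 288, dtype=int)
        for d, hours in zip(range(3), (7, 8, 9)):
            a = d * 288 + int(11 * 12)
            states[a:a + hours * 12] = 0
        sw = resthmm.estimate_sleep_windows(_synthetic_path(states))
        assert sw.durations_h == [7.0, 8.0, 9.0]
        assert sw.sleep_duration_sd_h == pytest.approx(1.0)
        assert sw.n_days_omitted == 1

    def test_onsets_near_diary_truth(self):
        within = total = 0
        for i in range(5):
            prof = synthio.default_profile(f"s{i}", "control", "robust",
                                           3000 + i)
            rec = synthio.generate_subject(prof, 7)
            bins = ingest.aggregate(rec.activity, 5, "mean")
            m = resthmm.fit_hmm(bins, seed=i)
            sw = resthmm.estimate_sleep_windows(resthmm.decode_states(m, bins))
            for t in sw.onsets:
                err = min(abs((t - d.retiring).total_seconds()) / 60
                          for d in rec.diary)
                total += 1
                within += err <= 30
        assert within / total >= 0.8


class TestHarmonic:
    def test_rows_stochastic_at_all_clock_times(self):
        rec = synthio.generate_subject(
            synthio.default_profile("h", "patient", "robust", 777), 7)
        bins = _bins(rec)
        m = resthmm.fit_hmm(bins, harmonic=True, seed=3)
        P = m.transition_at(np.arange(0, 24, 0.1))
        assert np.allclose(P.sum(axis=2), 1.0, atol=1e-9)
        assert np.all(P >= 0)

    def test_harmonic_captures_nocturnal_rest_persistence(self):
        rec = synthio.generate_subject(
            synthio.default_profile("h", "patient", "robust", 778), 7)
        bins = _bins(rec)
        m0 = resthmm.fit_hmm(bins, harmonic=False, seed=3)
        mh = resthmm.fit_hmm(bins, harmonic=True, seed=3)
        assert mh.loglik > m0.loglik
        P = mh.transition_at(np.array([3.0, 15.0]))
        assert P[0, 0, 0] > P[1, 0, 0]  # IA more persistent at 03:00 than 15:00
        # both conventions of P1-1 are available
        assert 0 <= mh.p11_time_average() <= 1


def test_p11_couples_with_dichotomy_index_across_phenotypes():
    """P1-1 and I<O rank subjects consistently across a mixed cohort."""
    from scipy.stats import spearmanr
    p11s, ios = [], []
    for i in range(14):
        ph = "robust" if i % 2 == 0 else "disrupted"
        prof = synthio.default_profile(f"c{i}", "patient", ph, 9100 + i)
        rec = synthio.generate_subject(prof, 7)
        m = resthmm.fit_hmm(ingest.aggregate(rec.activity, 5, "mean"), seed=i)
        p11s.append(m.p11)
        ios.append(dichotomy.compute_io(
            rec.activity, rec.diary.bed_spans()).io_percent)
    r, _ = spearmanr(p11s, ios)
    assert r > 0.4
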