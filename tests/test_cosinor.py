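import numpy as np
import pandas as pd
import pytest

from circarest import cosinor
from circarest.rhythmspec import RhythmEstimate
from circarest.series import SalivaPanel, TemperatureSeries

START = pd.Timestamp("2024-03-04 12:00:00")


def two_harmonic_temp(M=36.0, a1=0.3, b1=-0.4, a2=0.1, b2=0.05, days=7,
                      noise=0.0, rng=None):
    n = days * 1440
    h = START.hour + np.arange(n) / 60.0
    w1, w2 = 2 * np.pi * h / 24, 2 * np.pi * h / 12
    y = (M + a1 * np.sin(w1) + b1 * np.cos(w1)
         + a2 * np.sin(w2) + b2 * np.cos(w2))
    if noise:
        y = y + rng.normal(0, noise, n)
    return TemperatureSeries(start=START, values=y,
                             missing=np.zeros(n, bool))


def cortisol_panel(mesor=10.0, amp=5.0, acro=8.0, noise=0.0, rng=None,
                   n_days=2, hours=(7, 10, 13, 16, 19, 22)):
    times, conc = [], []
    for day in range(n_days):
        for h in hours:
            times.append(pd.Timestamp("2024-03-05") +
                         pd.Timedelta(days=day, hours=h))
            y = mesor + amp * np.cos(2 * np.pi * (h - acro) / 24)
            if rng is not None:
                y += rng.normal(0, noise)
            conc.append(max(0.1, y))
    return SalivaPanel(analyte="cortisol", times=times,
                       concentrations=np.array(conc))


class TestTemperature:
    def test_noiseless_two_harmonic_recovered_exactly(self):
        fit = cosinor.fit_temperature_cosinor(two_harmonic_temp(), seed=0)
        assert fit.mesor == pytest.approx(36.0, abs=1e-6)
        assert fit.coefficients["a1"] == pytest.approx(0.3, abs=1e-6)
        assert fit.coefficients["b1"] == pytest.approx(-0.4, abs=1e-6)
        assert fit.coefficients["a2"] == pytest.approx(0.1, abs=1e-6)
        assert fit.coefficients["b2"] == pytest.approx(0.05, abs=1e-6)

    def test_constant_temperature(self):
        fit = cosinor.fit_temperature_cosinor(
            two_harmonic_temp(M=36.0, a1=0, b1=0, a2=0, b2=0), seed=0)
        assert fit.mesor == pytest.approx(36.0, abs=1e-9)
        assert fit.amplitudes["24"] == pytest.approx(0.0, abs=1e-9)
        assert fit.amplitudes["12"] == pytest.approx(0.0, abs=1e-9)

    def test_acrophase_is_curve_maximum(self):
        fit = cosinor.fit_temperature_cosinor(two_harmonic_temp(), seed=0)
        grid = np.arange(0, 24, 1 / 60)
        curve = fit.predict(grid)
        assert curve.max() == pytest.approx(
            fit.predict(np.array([fit.acrophase_h]))[0], abs=1e-9)

    def test_coefficients_match_normal_equations(self, rng):
        temp = two_harmonic_temp(noise=0.2, rng=rng)
        fit = cosinor.fit_temperature_cosinor(temp, seed=0)
        clock_h, profile, _ = cosinor.smoothed_profile(temp)
        ok = np.isfinite(profile)
        t, y = clock_h[ok], profile[ok]
        w1, w2 = 2 * np.pi * t / 24, 2 * np.pi * t / 12
        X = np.column_stack([np.ones_like(t), np.sin(w1), np.cos(w1),
                             np.sin(w2), np.cos(w2)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        beta = cosinor._deconvolve_boxcar(beta, (24.0, 12.0))
        assert fit.mesor == pytest.approx(beta[0], abs=1e-9)
        assert fit.coefficients["a1"] == pytest.approx(beta[1], abs=1e-9)
        assert fit.coefficients["b2"] == pytest.approx(beta[4], abs=1e-9)

    def test_insufficient_data_rejected(self):
        short = two_harmonic_temp(days=2)
        with pytest.raises(cosinor.CosinorError, match="72"):
            cosinor.fit_temperature_cosinor(short, seed=0)


class TestCortisol:
    def test_eight_samples_rejected(self):
        panel = cortisol_panel(hours=(7, 10, 13, 16))  # 2 days x 4 = 8
        with pytest.raises(cosinor.CosinorError, match="inadequate"):
            cosinor.fit_cortisol_cosinor(panel, seed=0)

    def test_noiseless_exact_recovery(self):
        fit = cosinor.fit_cortisol_cosinor(cortisol_panel(), seed=0)
        assert fit.mesor == pytest.approx(10.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(5.0, abs=1e-9)
        assert fit.acrophase_h == pytest.approx(8.0, abs=1 / 60)
        assert fit.significant

    def test_flat_panel_not_significant(self, rng):
        fit = cosinor.fit_cortisol_cosinor(
            cortisol_panel(amp=0.0, noise=1.0, rng=rng), seed=0)
        assert not fit.significant

    def test_nesting_identity_with_zero_second_harmonic(self):
        """A single-harmonic signal fitted by the 24-h cortisol model equals
        the two-harmonic fit with a2=b2=0 on the same profile."""
        temp = two_harmonic_temp(M=36.0, a1=0.25, b1=0.1, a2=0.0, b2=0.0)
        fit2 = cosinor.fit_temperature_cosinor(temp, seed=0)
        assert fit2.coefficients["a2"] == pytest.approx(0.0, abs=1e-9)
        assert fit2.coefficients["b2"] == pytest.approx(0.0, abs=1e-9)
        assert fit2.amplitudes["24"] == pytest.approx(np.hypot(0.25, 0.1),
                                                      abs=1e-9)

    def test_time_origin_invariance(self):
        """Shifting all sample timestamps by whole days leaves the fitted
        clock-time acrophase unchanged."""
        p1 = cortisol_panel()
        p2 = SalivaPanel(analyte="cortisol",
                         times=[t + pd.Timedelta(days=3) for t in p1.times],
                         concentrations=p1.concentrations)
        f1 = cosinor.fit_cortisol_cosinor(p1, seed=0)
        f2 = cosinor.fit_cortisol_cosinor(p2, seed=0)
        assert f2.acrophase_h == pytest.approx(f1.acrophase_h, abs=1e-6)
        assert f2.amplitude == pytest.approx(f1.amplitude, abs=1e-9)

    def test_bootstrap_ci_brackets_truth_under_noise(self, rng):
        hits = 0
        for i in range(25):
            panel = cortisol_panel(noise=5.0 / 4, rng=rng)
            fit = cosinor.fit_cortisol_cosinor(panel, seed=i)
            lo, hi = fit.ci90_amplitude
            hits += lo <= 5.0 <= hi
        assert hits >= 18  # ~90% nominal with wide binomial slack


class TestClassification:
    def _rhythm(self, period=24.0, significant=True):
        return RhythmEstimate(dominant_period_h=period, amplitude=0.4,
                              acrophase_h=0.0, ci90_period=(23, 25),
                              ci90_amplitude=(0.2, 0.6),
                              ci90_acrophase=(1, 3), significant=significant,
                              peak_power=0.5, null_power_95=0.1)

    def _fit(self, acro):
        return cosinor.CosinorFit(
            mesor=36.0, coefficients={"a1": 0.1, "b1": 0.1},
            amplitudes={"24": 0.3}, acrophase_h=acro,
            ci90_mesor=(35, 37), ci90_amplitude=(0.1, 0.5),
            ci90_acrophase=(acro - 1, acro + 1), residual_sd=0.1,
            n_obs=1440, periods_h=(24.0,))

    @pytest.mark.parametrize("acro,period,sig,label", [
        (2.0, 24.0, True, "physiologic"),
        (14.0, 24.0, True, "abnormal"),      # rhythmic but diurnal acrophase
        (2.0, 24.0, False, "arrhythmic"),
        (2.0, 18.0, True, "abnormal"),       # non-circadian dominant period
        (22 + 1 / 60, 24.0, True, "physiologic"),  # 22:01 boundary included
        (7.0, 24.0, True, "physiologic"),          # 07:00 boundary included
        (7.1, 24.0, True, "abnormal"),
    ])
    def test_rules(self, acro, period, sig, label):
        out = cosinor.classify_temperature_rhythm(
            self._rhythm(period, sig), self._fit(acro))
        assert out.label == label
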