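# Methods

This note records the modelling assumptions, defaults and numerical
choices behind `circarest`, in the order the pipeline runs them. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Time conventions

All timestamps are timezone-naive local clock times: every reported
quantity (acrophase, center-of-rest, DLMO, the 22:01–07:00 night span) is
a wall-clock quantity. Per-day statistics use a noon-to-noon "study day"
so a nocturnal sleep episode is never split across days. The night span
[22:01, 07:00] is closed at both ends and interpreted on the wrap-around
clock.

## Ingest

Sensor CSVs (`timestamp,value`, 1-min grid) are completed onto the full
grid with gaps masked missing; duplicate or non-monotone timestamps are
hard errors naming the offending row. Temperature values outside a
plausibility band (default 15–42 °C) are masked with a warning.

**Off-body detection.** Sensor-off spans (shower, bath) appear in the
chest temperature signal as a steady decay to near room temperature
followed by a plateau. A minute is flagged when it belongs to a run of at
least `offbody_plateau_min` (default 10) minutes within `offbody_delta_c`
(default 2 °C) of `room_temp_c` (default 21 °C, a typical indoor value);
each run is extended backwards through the monotone decay that led into
it, up to 15 min. The plateau rule alone suffices at the series start,
where no preceding steady state exists. Flags are applied to both the
temperature and activity masks; masks only ever grow through ingest.

**Aggregation.** Bins (5-min for the HMM, hourly for spectral work) use
the mean of present minutes; a bin with at most half its minutes present
is missing. Interpolation of hourly gaps is linear, stays inside the
convex hull of the neighboring values, extends ends with the nearest
value, and reports the interpolated fraction; above 30% a warning is
attached to downstream rhythm estimates (configurable hard-fail).

## Dichotomy index

`I<O` = percentage of non-missing in-bed minutes whose count is *strictly*
below the median non-missing out-of-bed count, with one pooled out-of-bed
median per analysis window. Ties count as not-below; this is documented
because a tie-heavy subject can differ by whole percents between the two
readings. In-bed intervals come from the diary when available, otherwise
from the HMM's nocturnal rest windows. Daytime naps remain in the
out-of-bed pool. Classification after 72 h: low if I<O ≤ 97.5%, else
high; a window needs at least one complete in-bed interval and 4 h of
out-of-bed minutes. A bed-bound subject (out-of-bed median 0) is reported
as I<O = 0 with a degeneracy flag rather than an error.

## Rest-activity HMM

Emissions are Gaussian on log(count + 1) — the standard variance-
stabilizing choice for heavy-tailed accelerometry counts. Three states
(IA < MA < HA by location) are fitted by EM on the contiguous non-missing
segments of the 5-min series: 5 restarts with quantile-initialized
locations and mild multiplicative jitter, up to 500 iterations, relative
log-likelihood tolerance 1e-6, best likelihood kept, states relabeled by
ascending location. A fit in which any state holds under 1% of the
posterior mass is refit with 2 states and flagged; a constant series
short-circuits to a flagged degenerate model. At least 288 non-missing
bins (one day) are required.

Decoding is global (Viterbi) for the reported path, with forward–backward
posteriors for weighting; missing bins carry no emission term, so their
posteriors propagate through the chain.

**Harmonic variant.** Transition rows are modulated on the logit scale by
the first two harmonics of clock time (sin/cos at 24 h and 12 h),
`P_ij(t) ∝ exp(b_ij + c_ij·f(t))`, fitted by EM whose M-step solves a
weighted multinomial logit per row (L-BFGS with analytic gradients,
homogeneous fit as warm start). Rows are stochastic at every clock time
by construction. P1-1 under this model is reported both as the clock-time
average of `P_11(t)` and via the time-averaged matrix.

**Derived quantifiers.**

* mid MA / mid HA: back-transformed emission locations, `exp(μ) − 1`
  acc/min.
* Rhythm index (tagged `jaccard-posterior-v1` in output): the mean, over
  all pairs of complete study days, of the weighted Jaccard overlap of
  IA-decoded bin sets on the 24-h clock grid, each bin weighted by the
  mean IA posterior of its run. Identical daily rest blocks decoded with
  posterior 1 give RI = 1; a path with no recurring rest structure tends
  to 0. This operationalization was chosen because both printed endpoints
  are directly testable.
* Center-of-rest: posterior-weighted circular mean clock hour of IA bins.
* Sleep windows: per study day, the longest maximal IA run intersecting
  the night span gives onset, wake and duration; days without a
  nocturnal run are omitted and counted. The across-day sample SD of
  durations is the "sleep duration variability" covariate used in the
  determinant analysis.

## Spectral estimation and r24

The periodogram is a least-squares sinusoid fit per trial period
(default grid 6–30 h, step 0.1 h) on the complete hourly series; the
spectrum value is the fraction of variance explained. A least-squares
periodogram rather than an FFT because the series is short (~168 points),
interpolated, and the period grid is continuous. The dominant period is
the argmax (ties resolve to the smaller period and are logged). 90% CIs
re-estimate period, amplitude and acrophase on 500 residual-bootstrap
resamples; acrophase intervals are circular percentiles centered on the
point estimate. Significance compares the observed peak against the 95th
percentile of the maximum spectrum value over 200 permutation surrogates
(time order destroyed, marginal distribution kept). A phase-randomizing
surrogate was rejected: it preserves the amplitude spectrum, so a pure
sinusoid would never test significant against its own surrogates.

r24 is the Pearson correlation of the hourly series with itself lagged
24 h, pairs with either member missing dropped, undefined (flagged) for
constant input. Hourly resolution matches the spectral input and is
recorded in output metadata.

## Cosinor models

Temperature: a centered 61-min moving average over non-missing minutes
(incomplete edge windows dropped), averaged per clock minute across days
(error if under half the clock minutes are covered), then ordinary least
squares with 24-h and 12-h harmonics. The fitted coefficients are divided
by the known boxcar gain per harmonic (≈0.997 at 24 h, ≈0.988 at 12 h),
so the estimator is unbiased for pure harmonics despite the smoothing.
The reported acrophase is the argmax of the full fitted curve on a 1-min
grid — for a two-harmonic curve this is not the phase of the 24-h
component alone.

Cortisol: the 24-h harmonic on raw sample times, no binning; adequacy
requires at least 9 samples. Rhythm significance is the zero-amplitude
F-test (α = 0.05).

**Bootstrap CIs.** 90% intervals use 500 seeded resamples — residual
bootstrap for the averaged temperature profile, case resampling for
cortisol samples. Mesor and amplitude intervals are studentized
(bootstrap-t with delta-method standard errors): raw percentile intervals
cover the true amplitude only ~77–84% at the 12-sample cortisol design,
while bootstrap-t covers ~90%. A noiseless fit returns degenerate point
intervals. The temperature profile's residuals are autocorrelated across
clock minutes, so its intervals are approximate.

**Classification.** Physiologic: significant dominant period within
24 ± 2 h *and* cosinor acrophase inside the night span. Abnormal:
significant but failing either condition. Arrhythmic: no significant
rhythm. The spectral significance flag is the gate; the cortisol-style
F-test for temperature is available alongside but not used by the
classifier.

## DLMO

Individual threshold: the earliest run of 3 consecutive samples lying
entirely before the sustained evening rise, with coefficient of variation
below 0.33; threshold = run mean + 2 × run sample SD (n−1). The rise is
operationalized as the first step increase exceeding 25% of the mean of
all preceding samples and followed by a further increase (or final step);
slow baseline drift below that fraction does not truncate the baseline
pool, while a steep monotone rise from the first sample leaves no
baseline (pooled fallback). The pooled threshold is the mean + 2 SD of
all qualifying baseline values within a group (patients and controls
separately, at least 2 contributors) and is validated by the Pearson
correlation between individual- and pooled-threshold onsets over subjects
having both.

Onset: the first crossing from ≤ threshold to > threshold that stays
above for all subsequent samples, linearly interpolated between the
flanking samples. A first sample already above the threshold means the
onset precedes the window (undetermined, flagged). Dim light requires
mean lux < 50 over the 30 min before collection with no minute above
4 × 50 lux; failures flag, never abort.

## Determinant analysis

Spearman correlations (average-rank ties, pairwise-complete deletion,
≥ 5 pairs) screen predictors against I<O. Group contrasts: two-tailed
Welch t-tests and Fisher's exact test. Both two-sided Fisher conventions
are exposed because both occur in widely used software: mass-summation
(sum of hypergeometric probabilities ≤ observed; the R/scipy definition;
the default) and tail doubling (twice the smaller one-sided tail).

Model selection enumerates all predictor subsets up to 4 (a limit imposed
by cohort sizes in the tens), fits each by OLS (listwise deletion, with
the dropped-row count reported; condition numbers above 1e10 skip the
subset), and ranks by AICc with k counting all parameters including the
error variance. Fits include an intercept by default; a no-intercept mode
mirrors intercept-free reported regression equations, and the
discrepancy is surfaced rather than resolved. Note that AIC-family
selection retains a spurious predictor with probability ≈ P(χ²₁ > 2.3)
per decoy; "recovery" of a generating model therefore means the selected
subset *contains* the generating predictors, not that it equals them.

## Synthetic-data generator

Each subject is generated from explicit truth:

* **Activity**: a 3-state Markov chain on 5-min bins whose transition
  matrix blends a day regime and a night regime through a sigmoid gate
  (width 0.1 h) around the realized diary retiring/rising times; the gate
  leads retiring by 0.2 h (settling into bed). Bin levels are lognormal
  on log(count+1) (IA/MA/HA locations 1.5/3.2/5.0 for robust subjects,
  MA/HA reduced for disrupted), spread over minutes with lognormal
  weights and rounded to integer acc/min. Robust subjects keep
  P(IA→IA) ≈ 0.994 at night; disrupted ≈ 0.935 with MA/HA excursions —
  this single contrast drives most of the I<O separation.
* **Temperature**: two-harmonic cosinor (robust: amplitude ~0.5 °C,
  nocturnal acrophase ~02:30; disrupted: ~0.22 °C, afternoon acrophase)
  plus AR(1) noise (φ = 0.9, σ = 0.05 °C) for physiological smoothness.
* **Cortisol**: 24-h cosine (mesor ~10 nmol/L, morning acrophase ~08:00)
  sampled on a 3-h daytime grid over two days, anchored at the diary
  rising time, Gaussian noise.
* **Melatonin**: flat lognormal baseline (~2.5 pg/mL; ×1.4 in patients)
  plus a logistic evening rise (τ = 0.15 h, plateau 25/10 pg/mL for
  robust/disrupted). The logistic midpoint lags the labeled onset by
  0.8 h so that, at default noise, the noiseless curve crosses the
  expected individual threshold (baseline + 2 SD) essentially at the
  labeled onset under hourly sampling with linear interpolation; this
  makes the onset an unambiguous recovery target. Onsets are spread with
  SD 0.8 h (clipped to 20:18–22:36 so the 19:00–24:00 sampling window
  retains a pre-rise baseline).
* **Diary**: retiring/rising around 23:00/07:00 with day-to-day SD 0.35 h
  (robust) or 1.1 h (disrupted) — disrupted subjects are strictly more
  irregular by construction.
* **Light**: ~250 lux indoor daytime, ~8 lux dim evening, darkness in
  bed — evening saliva sampling is dim-light valid by design.
* **Off-body spans**: `inject_missingness` inserts 10–40-min spans where
  temperature decays exponentially (τ = 2 min) to 21 °C and activity is
  masked; the injected-minute truth mask is retained for validating the
  detector.

Per-subject seeds derive from the master seed via `SeedSequence`; all
generators are pure functions of (profile, seed).

**Calibration, done once and frozen.** The phenotype defaults were tuned
so that robust subjects land above and disrupted subjects at or below the
97.5% I<O threshold in ≈100% of draws (simulated low/high medians ~91/99%
at 72 h), then frozen. The DLMO defaults were chosen by a one-time grid
search over (τ, midpoint lag) for onset recoverability at hourly
sampling.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: device noise and calibration drift, naps and
irregular shift-work schedules, postural and ambient temperature
artifacts beyond off-body spans, non-sinusoidal hormone shapes (e.g. the
cortisol awakening response), assay noise floors, questionnaire item
structure (scores are drawn directly as numbers), and any covariance
between signals beyond what the shared diary induces.

## Problem sizes

The test suite exercises the statistical claims at the following sizes,
chosen to give stable pass/fail behaviour at modest runtime: 100
subjects for the dichotomy-index oracle and HMM recovery checks, 200
simulations for bootstrap coverage, 100 replicates for spectral and
selection recovery, 100 subjects for DLMO recovery (50 for pooled
validation), and one 58-subject cohort (17 disrupted) for end-to-end
classification. `scripts/acceptance.py` uses the same designs with some
replicate counts halved.

## Known limitations

* The pooled-vs-individual DLMO Pearson validation fluctuates (≈0.88–0.98
  across master seeds at n≈25 pairs): with hourly sampling, a subject
  whose baseline noise band straddles the pooled threshold can cross an
  interval early, and single discordant pairs move a small-sample Pearson
  r substantially. This is a property of the mean+2SD/hourly-sampling
  method, not of the implementation.
* The harmonic HMM uses a fixed two-harmonic logit parameterization; no
  model selection over harmonic order is attempted.
* The RI definition is one defensible operationalization of a previously described
  [0, 1] regularity score whose exact formula lives in unpublished
  software; outputs carry the `ri_definition` tag so downstream users can
  detect a change.
* Cohort contrasts report raw p-values; no multiplicity correction is
  applied, matching common practice in small exploratory cohorts.
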