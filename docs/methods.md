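# Methods

This note documents the models, the defaults, and the design choices behind
`circaphase`, and states what the synthetic-data experiments do and do not
demonstrate.

## Phase coordinates

Clock phases are circular. To keep ordinary (linear) regression valid, each
phase variable is unwrapped onto an interval chosen so that its cohort
cluster never straddles the interval boundary:

- nocturnal phases — core temperature bathyphase (~03:30), center of rest
  (~03:05), chest temperature acrophase (~03:00) — and the evening DLMO use a
  noon-anchored window **[12, 36)** (03:30 → 27.5);
- the daytime chest temperature bathyphase (~11:00) sits next to the noon
  anchor, so it uses plain clock hours **[0, 24)** instead.

The per-variable coding is fixed and used consistently by the generator, the
phase table, and the regression. Circular distance (≤ 12 h) and signed
circular differences are used for all error summaries, so accuracy numbers
are wrap-safe regardless of coding.

## Preprocessing

Core temperature arrives as two pill segments ingested 24 h apart. Within
the first **3 h** of each segment, samples outside **[35, 40] °C** are
deleted (ingestion transients from food and drink); both bounds and the
window are configurable. The segments are stitched by taking the first pill
until its last sample and the second pill strictly afterwards. The series is
then aggregated to clock-aligned left-closed 5-minute mean bins, smoothed
with a centred moving average over [t−30 min, t+30 min) (12 bins at 5-min
spacing; centred because nothing in the problem favours a trailing window),
and collapsed into an averaged 24-hour profile (mean across days per clock
bin; empty bins stay missing, never zero). Chest surface temperature goes
through the identical aggregate → smooth → profile chain. Smoothing precedes
profile averaging; with unequal day coverage the two orders differ slightly,
and this order treats the recording as one continuous series.

Cosinor fits on 5-minute profiles evaluate the harmonic basis at **bin
centers** (left edge + 2.5 min); using left edges would bias every phase
2.5 min early.

## Two-harmonic cosinor

The temperature model is a fixed-period two-harmonic cosinor (12 h + 24 h)
estimated by OLS; 8 distinct time points spanning ≥ 12 h are required, and a
rank-deficient design raises. Phases are extracted by brute argmax/argmin of
the fitted curve on a 1-minute grid (the native device resolution), ties
broken toward the earliest clock time; a fitted peak-to-trough range below
1e-10 marks the phases undefined rather than returning grid noise.

Confidence intervals use a **residual-resampling bootstrap**: refit on
ŷ(t) + e*(t) with e* drawn i.i.d. from the fitted residuals, collect the
replicate phases, and take the shortest arc spanned by the central 90% of
the signed circular deviations re-centred on the point estimate. Residual
(rather than case) resampling was chosen because the design points are a
fixed clock grid, not a random sample; re-centred circular quantiles avoid
wrap artifacts near midnight. With 5-minute profiles the i.i.d. assumption
is mild; on smoothed series residuals are autocorrelated and the intervals
would be anticonservative (see Limitations).

## Dominant-period classification

Spectral power at 24 h and 12 h is measured as the squared harmonic
amplitude from the joint two-harmonic OLS fit. The null distribution is
built by giving each recorded day an independent random circular time shift,
which preserves within-day structure while destroying day-to-day phase
coherence. A period is significant when its observed power exceeds the
97.5th percentile of its permutation null (two periods are tested, so the
per-period level is halved); the dominant period is the significant one with
the larger power, otherwise "none". Default 200 permutations, seeded.

## DLMO

A sample is invalid if the wrist lux record exceeds 50 lux in the half-open
window (t − 30 min, t]; a gap of more than 5 consecutive minutes of lux
coverage in that window marks the sample indeterminate (treated as unusable
but distinguished from a positive light exposure). The individual threshold
is mean + 2 × sample SD of the baseline; the baseline is the **earliest**
triple of consecutive valid samples, accepted only if flat (each value at
most 1.5× the running mean of its predecessors in the triple). Scanning
further into the evening is deliberately not done: later flat triples are
usually the post-rise plateau, and admitting them corrupts the pooled
baseline. Subjects without an adequate baseline fall back to the pooled
threshold (mean + 2 SD of all adequate baselines in the cohort); the
pipeline uses the pooled threshold for everyone by default, keeping the
individual threshold as a cross-check. The onset is the first strict upward
crossing, linearly interpolated between the neighbouring valid samples;
a profile already above threshold at its first valid sample, or never
exceeding it, yields an explicit undefined result with a reason.

## Activity HMM and center of rest

Minute-level counts x are transformed to log(1 + x) and modelled with
Gaussian emissions in K = 3 latent regimes ordered by ascending mean
(state 0 = inactive/rest). The chain is time-inhomogeneous: for minute of
day m, the transition logit from state i to j is

    η_ij(m) = c_ij + Σ_h [ α_hij cos(2πhm/1440) + β_hij sin(2πhm/1440) ]

with the diagonal fixed at 0 as the reference (staying put); one harmonic
(h = 1, the 24-h period) by default. Placing the harmonics on the
transitions (rather than emissions or the initial law) makes the *timing* of
regime switches clock-dependent, which is the phenomenon of interest, while
emission levels stay subject-specific constants.

Fitting is EM: exact forward–backward smoothing (scaled, with per-step
transition matrices indexed by minute of day; a compiled kernel with a pure
NumPy fallback, both verified against exact path enumeration), closed-form
emission updates, and a weighted multinomial-logit M-step for the transition
parameters (L-BFGS with analytic gradients, warm-started, so each iteration
improves the expected complete-data likelihood — generalized EM, likelihood
monotone). Missing minutes are marginalised (unit emission likelihood), so
posteriors exist on the full clock grid. Initialisation is deterministic
(emission means at the 15/55/90% quantiles, sticky transitions); additional
restarts perturb it, and the best likelihood wins. Emission likelihood rows
are rescaled by their maximum (posterior-invariant; the log offset is added
back to the likelihood) so that widely separated states do not underflow.

The center-of-rest time is the **circular** center of mass of the 24-hour
posterior rest-probability profile: the angle of Σ_m p_rest(m)·e^{iθ_m} with
θ_m at bin centers. A linear centroid would be wrong for the majority of
subjects, whose rest spans midnight.

## INTime regression

Candidate covariates: sex, age, BMI, chronotype score, DLMO, center of
rest, chest acrophase, chest bathyphase; outcome: core bathyphase (all
phases in the codings above). The screen reports pairwise Spearman
correlations and two-sample t-tests against binary covariates, flagging
p < 0.1. Selection is bidirectional stepwise from the full model, minimising
AICc with k counting all coefficients plus the error variance.

Missing data: selection runs on rows complete for *all* candidates so that
AICc values are comparable (AICc scales with n; letting each candidate model
choose its own complete cases would reward covariates with missing values
simply for shrinking n). The selected model is then refit on every row
complete for the selected variables, so subjects lacking only DLMO — the
most frequently missing covariate — re-enter the final fit whenever DLMO is
not selected.

The fitted model includes an intercept by default (suppressable); the
published fixed-coefficient equation is intercept-free and immutable, and
returns point predictions only since it carries no residual variance.
Prediction bands for fitted models are the standard OLS observation
intervals at the 90% level.

The sample-size analysis resamples covariate rows of the fitted design with
replacement at each candidate n, adds residuals resampled i.i.d. onto the
fitted values, refits, and collects the adjusted R²; it reports the central
90%/95% interval width relative to the reference adjusted R² and the
smallest n below the 10% criterion, over a default grid
{100, 200, 400, 600, 800, 1000, 1500} with 1000 trials.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, with
defaults representing the cohort conditions the package targets:

- **Cohort structure.** Sexes alternate (balanced within one). Chronotype
  score ~ N(57, 10²) clipped to [16, 86]. Center of rest ~ 03:05 ± 1.3 h
  with correlation −0.70 to the score; chest acrophase ~ 03:00 ± 2.2 h with
  correlation 0.67 to the center of rest; DLMO ~ 20:50 ± 1.1 h, correlation
  0.40, clipped into the sampled evening. The true core bathyphase is the
  published four-coefficient equation evaluated at (sex, score, center of
  rest, chest bathyphase) plus an intercept of 18.95 h — chosen so the
  cohort median lands near 03:30 under the phase codings above — plus
  Gaussian noise of SD **0.9 h**. That residual SD is derived from the
  cohort study this design emulates: an adjusted R² of ≈ 0.64 at an outcome
  SD of ≈ 1.5 h, and a prediction-error IQR of ≈ 71 min, both imply ≈ 0.9 h.
- **Core temperature.** Mesor 37.0 °C; 24-h amplitude 0.35 ± 0.07 °C, 12-h
  amplitude 0.12 ± 0.04 °C, both harmonics phased to share their minimum at
  the true bathyphase (making the truth exact and reproducing the
  empirically observed sharp-trough / flat-crest asymmetry); white noise
  SD 0.15 °C. Two pill segments start 24 h apart at 08:00; durations are
  log-normal (median 1.6 d, log-SD 0.58) clipped to [0.2, 13.4] d, so a
  realistic minority of subjects has ≥ 24 h overlap. The first 2 h of each
  segment receive spikes outside [35, 40] °C at rate 0.08/min.
- **Chest.** Dominant-class mixture 24h/12h/none with probabilities
  0.636/0.273/0.091; amplitudes (24 h, 12 h) of (0.8, 0.4) °C for
  24h-dominant, (0.3, 0.8) for 12h-dominant, and (0.01, 0.01) for
  arrhythmic subjects — deliberately below the permutation-test detection
  floor (~0.015 °C at 7 days of 5-minute data with 0.25 °C noise), so
  "arrhythmic" is actually arrhythmic to the classifier. The 12-h harmonic
  peak is offset +0.1..0.6 h from the 24-h peak so the global minimum
  (daytime bathyphase) follows the nightly acrophase, as observed in chest
  recordings.
- **Activity.** A sticky (persistence 0.9) three-regime chain whose rest
  probability is a raised-cosine bump (1-h edges) over the subject's rest
  span (duration 8.5 ± 0.75 h centred on the center of rest); counts are
  negative-binomial per state (means 2/35/180 counts/min × a log-normal
  subject factor, dispersion 3), giving subject-level median activities
  spanning roughly 6–135 counts/min with maxima in the hundreds.
  Device-removal gaps (log-normal ~25 min episodes) remove a configurable
  2% of minutes from both chest channels.
- **Melatonin.** Flat baseline (1–4 pg/mL) with a logistic rise anchored so
  that, noise-free, the individual threshold is crossed exactly at the true
  onset; multiplicative log-normal noise (12%); evening lux is dim with a
  configurable fraction of samples given a >50 lux burst in the preceding
  half hour.

Everything is deterministic given (seed, subject index); regenerating a
subject never perturbs the others, and ground truth is always emitted
alongside the raw series.

**What the generator does not emulate:** thermoregulatory dynamics (meals,
exercise, sleep-stage effects on temperature), masking of the endogenous
rhythm by behaviour, non-24-h free-running periods, sensor drift, melatonin
assay nonlinearity, and day-to-day phase instability. Passing tests
demonstrate that the estimation chain recovers the parameters of *this*
statistical structure at realistic noise levels — not that it is robust to
physiological confounders absent from the model.

## Numerical choices and degenerate inputs

- Extrema on a 1-minute grid; ties toward the earliest clock time.
- Constant series: cosinor returns zero amplitudes with undefined phases;
  the HMM refuses to fit (degenerate emissions).
- EM tolerance 1e-6 relative log-likelihood, max 50 iterations (40 in the
  pipeline), 5 restarts for standalone fits and 3 in the pipeline; emission
  SD floored at 1e-3 on the log scale.
- Bootstrap and permutation counts: 1000 / 200 by default; the test suite
  uses 200 bootstrap replicates and reduced restarts where the check is
  about calibration rather than precision.
- Problem sizes used by the tests: cosinor calibration at 288-bin profiles
  (200–500 replicates), HMM recovery at 100 subjects × 3 days, stepwise
  recovery at 100 cohorts of n = 200, end-to-end runs at the full default
  n = 33 with 7-day chest recordings.

## Known limitations

- Bootstrap CIs assume exchangeable residuals; on heavily smoothed series
  they are anticonservative. Profile-level fits (the default pipeline path)
  largely avoid this.
- The stepwise exact-covariate-set recovery rate is bounded away from 1 at
  large n: the AICc penalty tends to 2 per parameter, so each irrelevant
  candidate is retained with probability ≈ P(χ²₁ > 2) ≈ 0.16 regardless of
  noise level. At n = 200 with four irrelevant candidates the exact-set
  rate is ≈ 0.55–0.60, although the true covariates are essentially always
  included and their coefficients are recovered within 2 SE. Strong
  parsimony holds only at small n, where the AICc correction bites.
- The harmonic HMM formulation (harmonics on transition logits, Gaussian
  emissions on log counts, circular center of gravity) is one defensible
  member of a family; alternatives (harmonics on emissions, a linear 24-h
  centroid anchored at a fixed hour) would give slightly different
  center-of-rest values.
- DLMO baseline selection ("before rise") has no canonical operational
  definition; the earliest-flat-triple rule is a documented choice, and its
  1.5× rise factor is configurable.
- The INTime model is a within-sample predictive association on synthetic
  cohorts; no causal reading, and no external validation cohort is modelled.
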