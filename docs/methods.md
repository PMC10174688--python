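# Methods

This note documents the models, parameter choices, and numerical
decisions behind `fcbrainage`, and states what the synthetic-data tests
do and do not establish about real data.

## Preprocessing model

The package consumes ROI time series that are assumed to be already
denoised (slice-timing/motion correction, nuisance regression and
temporal filtering happen upstream); the reader warns, but does not
fail, when input series have a conspicuously nonzero mean. Three
quality-control parameters matter:

* **FD threshold** (`0.5 mm`, default): the censoring cutoff on
  framewise displacement. The FD formula is the Power-style sum of
  absolute backward differences of the six rigid-body parameters, with
  rotations converted to arc length on a 50 mm sphere. Rotations are
  assumed to be in radians; a `rotation_unit="degrees"` switch is
  provided because motion files in the wild use both conventions.
* **Censoring window** (1 before / 2 after): every frame within
  `[s−1, s+2]` of an exceedance frame `s` is dropped, clamped at run
  boundaries.
* **Retention gate** (`0.7`): a session is excluded when the retained
  fraction across all of its runs falls *strictly below* 70% — the gate
  is inclusive at exactly 70% because the exclusion criterion is worded
  as "less than" the threshold. Retention is evaluated across the
  concatenated session, not per run; with two 7-minute runs the
  criterion corresponds to 588 s of clean data.

Correlations of exactly ±1 are clipped to `1 − 1e−7` before the Fisher
transform so every edge stays finite (|z| ≈ 8.4 at the clip). The
diagonal is stored as 0 and never enters the feature vector. Edge order
is fixed (strict lower triangle, row-major) and recorded in trained
models so prediction can refuse a mismatched feature space.

## Age model

A linear ε-insensitive SVR with the standard default hyperparameters
C = 1.0 and ε = 0.1, and no feature standardization (a `standardize`
flag exists, default off). The solver convergence tolerance is tightened
to `1e−6` — a numerical choice, not a statistical one; at the problem
sizes used here the default looser tolerance leaves the weights
noticeably short of the convex-program optimum (the test suite checks
fitted predictions against an independent SLSQP solution of the primal
QP to 1e−4). Cross-validation uses a seeded shuffled k-fold partition
(k = 5 by default, no stratification); the permutation test reshuffles
the age labels and refits the *entire* cross-validation each time, which
preserves exchangeability, and uses the add-one convention
`p = (1 + hits)/(1 + n_perm)` so p is never zero. Degenerate training
sets with a single distinct age yield a constant model rather than an
error, since the convex problem's optimum is exactly that.

## Attenuation

The expected follow-up brain age advances each subject's *own* baseline
prediction along the cohort trajectory: `expected = predicted_T0 +
slope·Δt_years`. The alternative reading — projecting chronological age
through the full regression, `intercept + slope·(age_T0 + Δt)` — is
available via `method="regress"` for sensitivity analysis; the default
was chosen because it uses exactly the stated inputs (the T0 prediction
and the elapsed time) and makes the corrected-gap comparison below an
identity. Intervals are measured in fractional months from scan dates
(days / 30.4375).

Bias correction regresses the gap (predicted − chronological) on
chronological age and keeps the residual; the output is exactly
orthogonal to age. At T18 the T0-fitted bias regression is reused by
default (cohort consistency; refitting at each timepoint is available
with `reuse_t0_bias=False`). With the default reuse and T18 ages equal
to T0 ages plus the exact interval, the corrected-gap difference
`gap_T0 − gap_T18` equals the primary attenuation *identically* — the
two measures only diverge when the bias regression is refit per
timepoint or the intervals are approximated, which is why they are
reported as near- rather than exactly identical on real data.

Sign conventions, fixed everywhere: positive attenuation = slowed aging;
weight change is signed with negative = loss; the attenuation-vs-weight
regression uses −(weight change) so that loss sits on the positive
x-axis and the slope reads directly as months of attenuation per 1% of
body weight lost, with a standard OLS t-interval.

## Association plan

Deltas are T0 − T18 (a decrease over the trial is positive), so weight
loss produces a positive delta and a negative percent change
simultaneously. Pearson tests are used for continuous deltas, Kendall
tau-b (tie-corrected; exact enumeration for untied n ≤ 8) for ordinal
items, and a pooled-variance t-test for two-level items (Welch via
`equal_var=False`). Missing values are handled pairwise-complete per
variable with the n used reported per test. BH-FDR is applied separately
within each of the five biomarker categories; food-frequency items are
reported uncorrected by default (an `include_ffq_in_fdr` flag adds them
as their own family). When covariates (age, sex) are supplied, both the
attenuation and each continuous variable are residualized on them before
the Pearson test; sex enters as a 0/1 indicator.

## Power chain

The Fisher-z approximation without the small-sample bias term is the
default: it reproduces the three reference numbers (β = 3% at
n = 102/r = 0.369; minimal n = 90 for 95% power; minimal detectable
d ≈ 0.664 at n = 102/90% power) to rounding, and a Monte-Carlo check
(5000 simulated correlation tests) agrees with it to ±0.01. The
bias-corrected variant `atanh(r) + r/(2(n−1))` and the negligible
wrong-tail term are available by flag. `corr_sample_size` returns the
exact integer inverse of `corr_power` (closed-form seed, then verified
by direct evaluation); `required_effect_d` solves for r by monotone
bisection to 1e−10 and converts to d via `d = 2r/√(1−r²)`. The minimal
detectable d computed here is 0.663, within the ±0.005 band across
approximation variants. The stated sample-size requirement pairs
"alpha 0.05, beta > 0.05" with n > 90; this is read as power ≥ 0.95.

## Synthetic-data generator

The generator emulates the *statistical* structure of a longitudinal
RSFC intervention study:

* **Aging connectome.** Two endpoint correlation matrices share a
  low-rank factor loading; each adds an independent perturbation scaled
  by `1 − similarity`, plus a shared unique-variance diagonal, and is
  renormalized to unit diagonal. The connectome at latent brain age *a*
  is the convex combination of the endpoints with weight
  `clip((a − age_min)/(age_max − age_min), 0, 1)` — always a valid
  correlation matrix. The default age range (25–90) deliberately extends
  past the sampled chronological range (35–75) so follow-up latent ages
  do not hit the clipped, saturated ends of the interpolation.
* **Latent ages.** Chronological ages are uniform; latent brain age
  adds N(0, `brain_age_noise_sd`) years. At follow-up the latent age
  advances by the inter-scan interval (N(21.36, 1.68) months, negative
  draws redrawn rather than clamped to keep the distribution normal; the
  redraw count is recorded in the generator parameters) and is slowed by
  `gamma/12` years per percent of weight lost
  (weight change ~ N(−4.35, 5.86)%), plus N(0, `residual_sd`) years.
  `residual_sd` — the within-subject reliability of the latent
  trajectory — has no data-anchored value and must be supplied
  explicitly; the reference study uses 3.0 years, on the order of the
  test-retest error of connectivity-based age predictions.
* **Motion.** A slow random-walk drift (FD ≪ 0.5 mm) plus
  Bernoulli-spike persistent translation steps whose FD exceeds the
  threshold at exactly the spike frame, exercising the censoring window.
* **Clinical measures.** Each delta is a linear coupling to percent
  weight change plus Gaussian noise, with slopes matched to the reported
  cohort-level changes (e.g. ≈0.175 BMI units and ≈0.53 kg per percent);
  ordinal food-frequency change items and one two-level item are
  generated by thresholding a noisy copy of the weight-change latent.
* **Reproducibility.** All randomness flows from one master seed through
  per-subject `SeedSequence` substreams, so enlarging a cohort never
  perturbs already-generated subjects.

## Reference study conditions

Tests and the acceptance script run a scaled-down reference study chosen
once: 20 nodes (190 edges), 5 factors, similarity 0.1, 120 training and
80 trial subjects, two 250-frame runs per session, age noise 1.5 y,
residual noise 3.0 y. The strong connectome drift makes the age model
nearly unbiased (prediction-vs-latent slope ≈ 0.97), which matters
because the attenuation slope inherits that factor multiplicatively:
under these conditions the 95% CI of the recovered months-per-percent
slope covers the injected 8.9 in ≥ 90% of replicate studies, and with
the coupling switched off the mean attenuation is statistically zero.

**What this does not show.** Real RSFC age models are far noisier
(observed-vs-predicted correlations of 0.2–0.45, MAE of 8–11 years);
with that much shrinkage the attenuation slope would be diluted toward
zero and its CI would not be trusted as a calibrated estimate of a
physiological coupling. The synthetic suite validates the *pipeline
arithmetic and statistical calibration under its own assumptions* —
linear connectome drift, Gaussian noise, no site effects, no
within-subject connectivity reliability floor — not the empirical
accuracy of brain-age prediction on any real cohort.

## Degenerate inputs and tie-breaks

Zero-variance nodes are reported by label and fail connectivity
computation; fully censored runs contribute zero frames and a session
with fewer than two surviving frames errors; a constant-age training set
returns a constant predictor; constant observed ages make r undefined
(error) while MAE remains available separately; all-tied ordinal inputs
are rejected. Model JSON uses a schema tag and version so corrupted or
foreign files fail loudly rather than mispredict.
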