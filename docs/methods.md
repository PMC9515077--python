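# Methods

This note documents the models, conventions, and numerical choices behind
`fillin`, in the order data flows through the pipeline.

## Scientific setting

The package re-implements the analysis of an event-related fMRI experiment
on lateral modulation and perceptual filling-in in early visual cortex.
Three radial sinusoidal gratings are shown while BOLD responses are
recorded: a *center* grating confined to two lateral crescents at 8°
eccentricity, a *scotoma* grating that is its pixelwise complement (the
crescents are blank, mean-luminance "artificial scotomata" that can
perceptually fill in during steady fixation), and a *full-field* grating.
Two findings structure the analysis: (1) adding the surround suppresses the
BOLD response in the crescents' cortical projection zones (full-field <
center — lateral inhibition), and (2) whether an observer reports
filling-in on a scotoma trial is not reflected in the mean BOLD amplitude
but *is* decodable from the multivoxel activation pattern.

No data from the original study are distributed; a synthetic generator
emulates the statistical structure the analyses assume, so every stage is
exercised end to end.

## Stimuli

The radial grating is G(θ) = B + B·C·cos(2πfθ), with θ the rotation angle
in degrees and f = 0.1 cycles per degree of rotation angle (36 cycles
around the clock).  The annular window is W(r) = exp(−(((r−r_E)²/2σ_r²)^P))
with r_E = 8°, σ_r = 1°; P = 3 for the main stimuli, P = 1000 for the
hard-edged localizer.  A ±30° wedge around both vertical meridians is
masked out, leaving two 120° crescents (arc length 8°·2π/3 ≈ 16.8° of
visual angle).  Center modulation = grating × W × mask; scotoma
modulation = grating × (1 − W·mask); their sum reconstructs the full-field
modulation pixel for pixel, which is tested as an invariant.

Conventions the source material leaves open:

* **Rotation-angle origin** — 0° at the upper vertical meridian, clockwise
  positive.  Only the symmetry about the vertical meridian matters; the
  direction is configurable in `PolarGrid.make`.
* **Crescent width** — the nominal ≈2.8° radial width is reproduced as the
  full width of W between its e⁻¹ crossings, which is 2σ_r√2 ≈ 2.83°
  *independent of P*.  (Full width at half maximum of the P = 3 window
  would be 2σ_r√2·(ln 2)^(1/6) ≈ 2.66°, which does not match the nominal
  value; the e⁻¹ reading does.)
* **Counterphase flicker** — "5 Hz" is read as five full contrast-reversal
  cycles per second: at a 60 Hz refresh the sign pattern has a 12-frame
  period, six frames per phase.
* Luminance is normalized to [0, 1] with no display gamma model.

## Protocols

Retinotopic mapping: a wedge stepping 22.5°/TR (TR = 3 s) revolves in
360/22.5 = 16 TRs = 48 s; an expanding ring covering 0.25°–10.6° in 0.86°
steps takes round(12.03) = 12 TRs = 36 s (the nearest-integer step count is
what makes the printed 36 s cycle and 8 cycles per 288 s run come out).
Scotoma localizer: 6-TR on/off blocks repeated six times, 72 TRs.  Main
experiment: 20 trials per run (5 center, 5 full-field, 10 scotoma, in
seeded random order), each trial 10 s of 5 Hz flicker plus 14 s blank on a
24 s grid, TR = 2 s, 240 TRs per run, 8 runs — 40/40/80 trials in total.
The pre-test staircase adjusts inducer contrast toward a ~50% filling-in
rate: more than 6 reports out of 10 raises contrast, fewer than 4 lowers
it; the step size (unspecified in the protocol) defaults to a documented
±1 dB and only the adjustment *direction* is used downstream.

## Synthetic data

One ROI's BOLD data is runs × TRs × voxels:

    y_v(t) = baseline + Σ_trials a_v(trial) · (boxcar ⊛ HRF)(t) + ε_v(t)

* **HRF** — canonical double gamma (shape-6 gamma minus shape-16 gamma / 6,
  peak at 5 s, normalized to peak 1).
* **Amplitudes** — percent-signal units on baseline 100: center 1.5,
  scotoma 1.2, full-field = center − suppression (default 0.5).  A fixed
  per-voxel, per-condition gain jitter (SD 0.1) makes voxel selection
  non-trivial.  The pipeline cohort additionally jitters the suppression
  magnitude across participants (SD 20%) so group effect sizes are finite.
* **Filling-in structure** — each scotoma trial is labeled fill/no-fill by
  a Bernoulli(0.5) draw (matching the ~50% report rate the staircase
  targets).  Two fixed orthogonal, zero-sum, unit-RMS voxel patterns are
  drawn once per simulation; the label's pattern, scaled by
  `pattern_strength`, is added to the trial amplitude.  Zero-sum patterns
  move no ROI-mean signal, so the univariate fill−no-fill contrast is null
  *by construction* while the pattern is linearly decodable — the study's
  dissociation is a structural property of the generator, and the analyses
  must recover it.
* **`pattern_strength` = 0.04** — calibrated once so that leave-one-run-out
  accuracy at the default SNR sits near 0.65–0.70, the ">60%" working
  point the analyses are meant to detect; not an estimate of any real
  effect size.
* **Noise** — stationary AR(1) per voxel (marginal SD 1.0, lag-1
  correlation 0.3), plus an optional linear drift (off by default).  No
  physiological noise model.
* **Gaze** — fixational scatter is a stationary bivariate AR(1) drift
  (lag-1 correlation 0.8 at 60 Hz, marginal SDs σ_H, σ_V, correlation ρ).
  Plain iid samples would be unusable here: at 60 Hz they imply median
  sample-to-sample velocities near 25°/s, so a 30°/s cleaning criterion
  would discard half of clean fixation.  Blinks are Poisson events (~0.2 s)
  flagged invalid with NaN positions; saccades are Poisson out-and-back
  ballistic excursions of 2–4° in which every step exceeds 30°/s, so the
  velocity filter removes the whole excursion.

What the generator does **not** emulate: retinotopic cortical geometry,
spatially correlated noise, physiological drift and motion artifacts,
non-stationary attention effects, and any coupling between gaze and BOLD.
Passing tests therefore validate the *analysis machinery and its
calibration*, not claims about real tissue.

## GLM

Runs are concatenated with one intercept per run (per-run baselines absorb
offset drift; the alternative single-intercept model is a config choice
away).  Conditions Center, FullField, ScotomaFill, ScotomaNoFill each get
one HRF-convolved boxcar regressor — fill and no-fill are separate columns
so their contrast is estimable.  Estimation is voxelwise OLS; t = c'β̂ /
√(σ̂²·c'(X'X)⁻¹c) with df = rows − columns.  No prewhitening by default
(an AR(1)-corrected fit is available but is not what "standard GLM" means
here).  β normalization divides each condition β by the voxel's baseline
(mean run-intercept) β; zero-baseline voxels are excluded with a warning.
Group inference: per participant the ROI mean of per-voxel contrast t is
taken; the n = 12 values are tested against zero with a one-sample t-test —
one-tailed (negative) for FullField − Center, matching the lateral-
inhibition hypothesis — with Cohen's d = t/√n and Bonferroni α = 0.05/12 =
0.0042 reported alongside.

## Time courses

Each 24 s trial yields a 12-TR ROI-mean epoch.  Percent change is relative
to the epoch's first TR (the onset TR), so curves start at 0.  Time-to-peak
is the 1-based argmax over TRs 2–12: the reference TR is excluded from the
peak search, and ties resolve to the earliest TR (deterministic and
conservative).  Fill vs no-fill time-to-peak is compared with a two-tailed
paired t-test at the same Bonferroni level.

## ROI selection

Voxels pass if their localizer t exceeds 5.09 (strict inequality), the
conventional threshold corresponding to |r| > 0.52 at the 72-TR localizer's
residual df ≈ 70; a helper recomputes a Bonferroni criterion from a
gray-matter voxel count, but since that count is not known the printed 5.09
stays the default.  Voxels responding more to the scotoma grating than the
center grating are then removed (ties kept — the removal rule is strict).
Dorsal/ventral subregions merge into six univariate ROIs (lV1…rV3);
hemispheres merge further into three MVPA ROIs (V1, V2, V3).  Selection is
monotone in the threshold and idempotent on its own output, both tested.
Retinotopic boundary delineation itself is manual surface work and out of
scope; subregion provenance is an input label.

## MVPA

Per run, each voxel's time series is z-scored across time and min–max
rescaled to [0, 1] (scope: per voxel per run; other scopes are config
options).  A trial's feature vector is the mean of epoch TRs 3–7 (1-based,
TR 1 = onset TR; offsets 4–12 s, the response peak).  Classification is a
linear SVM, C = 1, via scikit-learn's libsvm backend, with leave-one-run-out
cross-validation: 8 folds of 70 training / 10 test trials.  A training fold
with a single class is skipped with a warning.  The optimizer tolerance
defaults to 1e-2 — at these feature scales the fitted margin is
indistinguishable from tol = 1e-3 while permutation nulls (thousands of
refits) run several times faster; it is a config knob.

The group permutation test relabels trials *within each run* (preserving
each run's class counts, which is what the CV folds see), reruns the full
cross-validation for every participant, and averages across participants;
5000 iterations by default.  p = (1 + #{null ≥ observed}) / (1 + n_iter) —
the add-one estimator never returns 0.  An optional `early_stop_alpha`
aborts iteration once rejection at that level is arithmetically impossible;
the accept/reject decision is provably identical to the full run, which
makes Type-I-error Monte Carlos affordable, and the flag is off by default.
Accuracy is raw, not balanced (class imbalance is mild at a ~50% fill
rate); balanced accuracy is an option.

## Fixation stability

Cleaning removes invalid/missing samples, positions beyond the screen
bounds, and any sample terminating a movement faster than 30°/s (velocity =
Euclidean displacement × sampling rate between consecutive samples; the
first interval after a removed gap is not velocity-tested, since the
elapsed time there is unknown).  BCEA = 2kπσ_Hσ_V√(1−ρ²) with k = 1
(probability area 1 − e⁻¹ ≈ 63.2%); σ are sample SDs (ddof = 1), ρ the
Pearson correlation.  Ellipse containment uses the full sample covariance:
a point is inside the k-contour iff its squared Mahalanobis distance is ≤
2k — consistent with the area formula, which the eigendecomposition
reproduces exactly.  Condition contrasts use (a) a two-level
repeated-measures ANOVA, computed as F(1, n−1) = (paired t)² (the exact
algebraic identity, cross-checked against pingouin in the tests), and (b) a
bootstrap null (default 10,000 iterations): participants are resampled with
replacement and each sampled pair's condition assignment is randomly
swapped; the observed mean difference is referred to that null at 0.025 per
tail.  Note the sign-swap null with n = 6 participants has a one-tail p
floor of 2⁻⁶ ≈ 0.016 — below the 0.025 criterion, but a real granularity
limit of so small a sample.  Density maps are binned counts smoothed with a
0.1° Gaussian kernel and max-normalized to [0, 1] (the construction is a
re-implementation choice; bandwidth and grid are config keys).

## Pipeline and reproducibility

`RunConfig` holds every constant (5.09, 0.0042, 0.017, 5000, 10000, 30°/s,
k = 1, the TR 3–7 feature window, cohort sizes) as a named field with the
study value as default.  All randomness flows from the single config seed
through named substreams (`rng_for(seed, stage, participant, …)` spawns a
`SeedSequence` keyed by CRC32 of the names); a rerun of `run_study` with
the same config is bit-identical, which is tested.  Stage failures are
caught and recorded; downstream stages with satisfied inputs still run.

### Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline at the
study's design sizes (12 participants, 8 runs, 60 voxels per ROI, 6 gaze
participants) but scale iteration counts where a full-size run would add
nothing but wall-clock time: permutation tests use 100–200 iterations
(add-one p floor 1/101–1/201, well below the 0.017 criterion) instead of
5000, and Type-I-error Monte Carlos use the early-stop device above.  The
defaults in `RunConfig` remain the full-size values.

## Known limitations

* The generator's voxel counts and SNR are calibration choices, not
  estimates of the original data (which report neither).
* Group-level t statistics on synthetic cohorts are larger than the
  published ones: between-participant variability is modeled only as a
  suppression-magnitude jitter, not the full menagerie of inter-subject
  differences.  Signs, significance patterns, and the univariate/
  multivariate dissociation — not magnitudes — are the reproduction
  targets.
* The default fit does not prewhiten AR(1) noise; contrast t-values on
  autocorrelated data are mildly optimistic, exactly as in a standard
  unwhitened GLM.  Group inference operates on per-participant summaries
  and is insulated from this.
* `rm_anova_2` covers exactly the two-level repeated-measures case; it is
  not a general ANOVA.
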