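# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `sundose`, in the order the pipeline runs.

## Anthropometry

TBSA uses the Mosteller formula, `√(height·weight/3600)` with height in cm
and weight in kg. Exposure scoring uses a rule-of-nines segment table
(percentages of TBSA): head-and-neck 9, face 4.5, face-with-tight-hijab 3,
hand 2.5, foot 2, per-arm short-sleeve exposure 6 (part of upper arm,
lower arm, hand), per-leg short-bottom exposure 13.5 (including the foot),
full arm including hand 9. The canonical full-body partition
(head-and-neck 9, 2×arm 9, 2×leg 18, trunk front/back 18 each,
perineum 1) closes to exactly 100%.

Two conventions deserve a note:

* **The face percentage is ensemble-dependent.** The source scoring scheme
  counts the face as 4.5% for a hijab ensemble without socks but 3% for
  the hijab-with-socks ensemble (a tighter hijab style). Both values are
  kept as distinct named segments, bound to their respective ensembles, so
  each canonical ensemble reproduces its published percentage exactly
  (13.5 and 8). Compositional mode inherits the same binding.
* **Strict vs compositional mode.** Strict mode (the default) accepts only
  the five canonical ensembles, guaranteeing the published percentages.
  Compositional mode assembles the exposed-segment list for any
  top/bottom/hijab/socks combination: hijab reduces the head to the face,
  short sleeves expose the per-arm segment (otherwise only hands), a short
  bottom exposes the per-leg segment (otherwise the feet, which socks then
  cover). Adding any garment never increases the exposed percentage.

Percentages live on the 0–100 scale throughout, never as fractions.

## Dosimetry

Intensities are hourly means in W/m², binned half-open `[h, h+1)` and
labelled by start hour (local time). Hours missing from a series are
treated as zero — consistent with explicit nocturnal zeros in the packaged
table — unless strict mode is requested, which raises on gaps instead.

The W/m² → MED/h conversion divides energy flux by a threshold energy
`E_MED` (J/m²). **`E_MED` has no default.** Published thresholds for
Fitzpatrick III–IV skin are not mutually consistent across the unit
conventions in circulation (values near 7 J/cm² and near 70 J/cm² both
appear, an order of magnitude apart), so dose computations require the
threshold explicitly, and every recommendation operation alternatively
accepts a directly measured rate (`med_rate_override`, e.g. a cohort
median of 0.39 MED/h). This keeps the headline durations reproducible
without settling the unit question, which affects only the physical
interpretation of the threshold.

Dose over a window is a piecewise-constant integral; partial hours weight
proportionally, making dose exactly additive over adjacent windows and
linear in intensity. `peak_window` scans all contiguous windows of the
requested width and breaks ties by earliest start; `lowest_month`
minimizes the mean 06:00–18:00 intensity.

Time to 1 MED is `60/rate` minutes, by default floored to the nearest
30-minute multiple ("half-hour-down"), which turns 153.8 min at 0.39 MED/h
into the conventional 2.5 h; an exact mode is available. The minimum
recommended duration multiplies this by the Holick fraction (default 0.25)
for the reference exposed area (face + both arms with hands = 22.5% with
the default table). Clothing adjustment scales by
`reference% / exposed%`, conserving the area × time product: a hijab
ensemble at 13.5% yields 37.5 × 22.5/13.5 = 62.5 min/day. (A published
figure of 64.5 min for this case circulates; it is not derivable from the
stated quantities — the area-ratio result is 62.5 — so the formula result
is used and the discrepancy documented here rather than hard-coded.)

## Cohort statistics

* **Censoring.** Serum readings below the 8.1 ng/mL assay limit are stored
  as 8.0 with a `below_detection` flag. This produces heavy ties in the
  lower tail, which all downstream statistics must tolerate.
* **Status cutoffs.** Deficient < 20, insufficient 20–30, normal ≥ 30
  ng/mL, as half-open intervals `[0,20)`, `[20,30)`, `[30,∞)` so every
  nonnegative level is classified (the literal printed ranges "<20",
  "21–29", "≥30" leave gaps; standard Endocrine Society practice closes
  them this way).
* **Contingency tests.** Plain Pearson χ² without continuity correction,
  with degrees of freedom `(r−1)(c−1)`. Cells with expected counts below 5
  trigger a warning (the normal column of a deficiency-dominated cohort
  routinely does); a Monte Carlo permutation p-value with fixed margins is
  available as the exact-style alternative. Reported p-values are rounded
  to 2 decimals, 3 below 0.01, and "<0.001" below that; full precision is
  retained internally.
* **Correlations.** Spearman rho on average ranks (tie-aware), p from the
  large-sample approximation. A constant input yields a flagged undefined
  result rather than an exception.
* **Multinomial regression.** Status on exposure measures with normal as
  base category; the crude model has one exposure, the adjusted model adds
  the a priori confounders (age, parity, pre-pregnancy BMI, education,
  sunscreen use). Categorical confounders are dummy-coded against their
  first observed level. Unpenalized fits use Newton ML; quasi-separation
  is flagged when any |log-OR| exceeds 15, any coefficient or SE is
  non-finite, or the fit does not converge — rather than silently
  reporting astronomical odds ratios, which is the characteristic failure
  mode when a status category has only a handful of members. A
  ridge-stabilized fit (L2 penalty on non-intercept coefficients,
  penalized observed-information SEs, slightly conservative) is available;
  the unpenalized fit remains the default to mirror conventional practice.
* **Exposure covariates.** Per participant: exposed percentage and exposed
  TBSA from the modal diary ensemble, and the duration-weighted mean
  MED/h rate over the diary's exposure windows (when an intensity series
  and threshold are supplied).

## Synthetic data

The generator emulates the cohort structure the analysis assumes; its
defaults are the study conditions, not tuning knobs.

* **Cohort margins.** n = 204; hijab 96/204; sunscreen 26/204; age-group,
  parity, BMI-class, education and occupation frequencies follow the
  published characteristics table. Covariates are drawn independently —
  only margins are published, so any confounding must be configured
  explicitly. Continuous age/BMI are drawn uniformly within their class
  ranges; height is N(155, 5.5²) cm truncated to [140, 175] (a realistic
  adult-female range for the population), weight derives from BMI.
  Ensemble mix: hijab wearers split 60/40 between the no-socks and socks
  styles; women without hijab use long-long/short-long/short-short with
  probabilities 0.40/0.35/0.25 — chosen once as a plausible mix; no
  published breakdown exists.
* **Diaries.** 3 days of bouts; bout count per day is Poisson(69.75/7.5),
  durations uniform on {5..10} min, start times placed in the 10:00–13:00
  midday window with probability 29.1/69.75 and uniformly over the rest of
  06:00–18:00 otherwise, reproducing the published daily means (69.75 min
  total, 29.1 min midday) in expectation.
* **Serum marginal.** A mixture: exactly 42/204 of probability mass below
  the 8.1 detection limit, plus a left-truncated lognormal
  (μ = 2.683270, σ = 0.392797, truncation 8.1) above it, solved so the
  censored cohort has mean 14.7 and SD 6.5 ng/mL exactly. A plain
  two-parameter lognormal cannot satisfy all three published targets
  simultaneously (exact moment matching implies only ~13.5% below the
  limit); because the assay censors everything below 8.1, only the
  sub-detection *probability* is observable, so modeling that tail's shape
  is unnecessary and the mixture is the minimal sufficient family. The
  published moments are taken as post-censoring values (the plausible
  reading for a table computed from recorded data).
* **Dose → serum linkage.** The latent daily dose is exposed area ×
  mean midday outdoor minutes × month-mean midday MED rate (months drawn
  uniformly over the packaged series' seven months; threshold default
  90 kJ/m², chosen so typical midday rates sit near the published
  0.39 MED/h median). Serum links to dose through a Gaussian copula: the
  latent serum score is `w·Φ⁻¹(rank(dose)) + √(1−w²)·ε`, mapped through
  the marginal quantile function. This is additive
  baseline + slope×dose + noise on the latent scale with a
  rank-preserving standardization, so the serum marginal stays exactly
  calibrated at every effect size, and `w = 0` gives exact null structure.
  The weight for a target rank correlation uses the frozen empirical slope
  0.5997 (achieved rho per unit weight at default conditions, n = 204),
  valid for moderate targets (|rho| ≲ 0.55); infeasible targets raise a
  configuration error.
* **Attrition.** Optionally, the realized n is Binomial(n_recruited,
  retention) with retention 204/304 — a single uniform retention
  probability, not itemized exclusion reasons.
* **Intensity generator.** Gaussian-bump diurnal profiles (bin-midpoint
  evaluation, default peak 12.5 h, spread 3 h) with optional truncated
  noise; nocturnal bins are structurally zero.

What the generator does **not** emulate: covariate–covariate dependence,
seasonal recruitment imbalance, within-person day-to-day clothing
variation, measurement error in diaries, and any real geography or
meteorology. Passing tests therefore demonstrate that the pipeline
recovers structure *of this form*, not that real data meet these
assumptions.

## Problem sizes and numerical conventions

The validation suite uses 50 generator replicates at n = 204 for the
calibration bands and 20 replicates at n = 2000 for multinomial parameter
recovery — large enough that sampling noise sits well inside the bands
being checked, small enough to run comfortably on one CPU. Dose additivity
and χ² oracle equivalence are asserted to 1e-9; exposure-profile internal
consistency to 1e-9; published percentages and durations are exact
floating-point values and compared exactly. All randomness flows from a
single `numpy.random.Generator` seeded per call; identical configs and
seeds give bit-identical outputs, and regenerated analysis reports are
byte-identical.

## Known limitations

* No radiative-transfer or action-spectrum modeling: a single scalar MED
  threshold stands in for skin photobiology, and whether a given intensity
  record is erythemally weighted is the user's responsibility.
* The rule-of-nines ensemble scoring ignores posture, shading and garment
  geometry; it is a planimetric convention, not irradiance-weighted skin
  area.
* The ridge fit's standard errors come from the penalized information and
  are slightly conservative; they are meant for stabilized reporting, not
  formal inference at strong penalties.
* Below-detection serum values are a point mass at 8.0; no imputation of
  the censored tail is attempted, and rank-based analyses treat the tied
  floor values as exchangeable.
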