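# Methods

## The screening problem

Sarcopenic dysphagia is screened from the appearance of the anterior lower
neck: loss of muscle mass makes the clavicle protrude, producing recessed
areas and wrinkles whose boundaries show up as intensity corners in a
grayscale photograph. The pipeline turns a photograph into three numbers
(median pixel value, pixel IQR, FAST corner density), combines them with
age, sex and a BMI-underweight indicator in L1-penalised logistic models,
and reports held-out discrimination and Youden-thresholded operating
characteristics.

## Preprocessing

Crop → bottom half → grayscale → 5×5 median filter, on [0, 1] float
images. Choices where the procedure is under-determined:

* **Cropping is explicit.** The region of interest (jawline to sternal
  notch) is an anatomical judgement, so `CropSpec` is a required argument
  (`top:bottom:left:right`, 0-based, half-open); no landmark detection.
* **Grayscale weights.** ITU-R BT.601 luma (0.299 R + 0.587 G + 0.114 B),
  the common still-image convention; a plain channel average is available
  (`AVERAGE_WEIGHTS`).
* **Odd heights.** "Bottom half" keeps rows `[floor(H/2), H)` — the larger
  half, so no rows above the midline leak in.
* **Median-filter borders.** Edge replication (scipy `mode="nearest"`), so
  output dimensions equal input dimensions. Border conventions differ
  across image libraries; this one is a documented choice, not a claim of
  bit-compatibility with any particular tool.

## Image features

* **Pixel statistics** use type-7 (linear-interpolation) quantiles, the
  default of R, where this family of analyses is usually run.
* **FAST** is implemented from the segment-test definition: centre pixel
  *p* is a candidate iff some arc of ≥ `arc_length` contiguous pixels on
  the 16-pixel radius-3 Bresenham circle is uniformly brighter than
  I_p + t or darker than I_p − t. Defaults: `arc_length = 9` (the classic
  FAST-9/16 variant), threshold t = 2.5 on the 0–255 scale (pixel
  statistics stay on [0, 1], the scale of the reported group means
  0.40/0.45 — both scales are documented because mixing them changes the
  detector's behaviour by a factor of 255). Non-maximum suppression is on
  by default: a candidate survives only if its score — the maximal arc sum
  of |I_circle − I_p| − t over qualifying arcs — strictly exceeds every
  candidate 8-neighbour's, with ties resolved to the lexicographically
  smallest (row, col). The vectorised detector is verified against an
  exhaustive per-pixel, all-16-start oracle (exact set equality).
* **Corner density** is `count / (H·W) × scale`. With NMS the per-pixel
  density cannot exceed 1, yet the published dysphagic-group mean is
  1.10 "feature points per pixel"; the original normalisation is not
  recoverable from the description. The `scale` constant (default 1) is
  exposed so calibrations can express density in whatever per-area unit is
  needed; the synthetic table-mode cohorts simply treat the published
  values as the feature's distribution.
* **KDE curves** (for feature-density figures) use a Gaussian kernel with
  Silverman's rule `0.9·min(sd, IQR/1.349)·n^(−1/5)` on a 512-point grid
  spanning the data ± 3 bandwidths.

## Models

Logistic regression with an L1 penalty on standardised covariates;
objective `(1/n)·NLL + λ·Σ|β_j|`, intercept unpenalised. The solver is
proximal Newton: an IRLS quadratic approximation solved by cyclic
coordinate descent with soft-thresholding, warm-started along a
log-spaced decreasing λ path (60 points, ratio 1e−4). Convergence: max
coefficient change < 1e−7; every returned solution is checked against the
subgradient optimality conditions in the test suite, and the λ = 0 limit
reproduces the IRLS maximum-likelihood fit to < 1e−4.

Decisions where the procedure is under-determined:

* **λ rule**: λ-min (deviance-minimising over seeded 10-fold CV). The
  1-SE rule would drop more covariates; λ-min matches an analysis in which
  no covariates were dropped.
* **CV loss**: out-of-fold binomial deviance (misclassification would be
  coarser at n ≈ 200 training subjects).
* **Confidence intervals**: penalised estimates have no standard Wald
  theory, so covariates surviving selection are refit unpenalised and the
  OR table reports `exp(β̂ ± 1.96·SE)` from the refit. Predictions also use
  the refit coefficients, keeping the reported ORs and the scores of one
  model internally consistent.
* **Standardisation** is fit on training data only and frozen for test
  scoring; anything else leaks test information.
* **Coding**: sex indicator 1 = female (male reference); BMI < 18.5 kg/m²
  → underweight = 1 (reference: not underweight, boundary value 18.5 is
  not underweight).

## Evaluation

* 70/30 split is simple random (unstratified), `round(0.7·n)` training
  subjects (n = 308 → 216/92).
* The Youden cut-point is computed on **training** predictions and frozen
  before test scoring; computing it on the test set is available
  (`threshold_on="test"`) for sensitivity checks but leaks test labels.
  Candidates are midpoints between adjacent distinct scores (±∞
  sentinels); predict positive iff score ≥ threshold; J-ties resolve to
  the lower threshold (higher sensitivity — the safer screening error).
* ROC-AUC is the trapezoidal area over all thresholds (≡ Mann–Whitney
  statistic with ties ½); PR-AUC is average precision (step-wise, no
  interpolation). Undefined predictive values (zero denominators) are
  reported as NaN, never as 0.
* Group comparisons: Welch t-test by default ("independent t-test" is
  ambiguous; Welch does not assume equal variances). Chi-squared (no
  continuity correction) requires all expected cells > 5; otherwise a 2×2
  table falls back to Fisher's exact test.

## Synthetic data

No patient data are shared, so the generator defines the study conditions
the tests run under.

**Images.** A smooth vertical luminance gradient whose overall level rises
with severity (0.40 → 0.45, matching the direction of the published group
medians), plus `round(n_base·(1 + 3·severity))` dark sinusoidal wrinkle
strokes (Gaussian cross-profile, σ ≈ 1.2–2.0 px so they survive the 5×5
median filter), plus `round(recess_count·severity)` elliptical recesses —
darkened interior, bright Gaussian rim, the shadow/highlight pattern around
a protruding clavicle — plus i.i.d. Gaussian pixel noise (SD 0.02), clipped
to [0, 1]. Default size 256×128 (lower-half aspect). By construction all
three features increase with severity, which the test suite verifies over
a severity grid (0, 0.25, …, 1.0; 100 images per level).

**Cohorts.** Outcome ~ Bernoulli(prevalence 133/308). Latent severity:
affected Uniform(0.5, 1), unaffected Uniform(0, 0.5), blurred by N(0, 0.1)
noise so the classes overlap as the observed feature densities do.
Class-conditional variables default to the published development-cohort
group summaries (age 82.57 (8.01) vs 86.22 (7.47); BMI 21.01 (3.38) vs
16.90 (2.79); median pixel 0.40 (0.09) vs 0.45 (0.11); IQR 0.09 (0.05) vs
0.12 (0.06); corner density 0.44 (0.56) vs 1.10 (1.28); female 108/175 vs
72/133). Sampling respects physiologic bounds (age [65, 110], BMI
[10, 45], median pixel [0, 1], other features ≥ 0) **and** reproduces the
configured mean/SD exactly: a naive truncated normal would bias the
moments (for the pixel IQR the bias exceeds 3 SE at n = 5000), so the
parent parameters are solved numerically such that the *post-truncation*
moments equal the targets. For the corner density no truncated normal on
[0, ∞) can have SD ≥ mean, so a moment-matched gamma is used — its right
skew matches the observed density shape. Within class, variables are drawn
independently: between-feature correlations were never published, so none
are invented; this is a known limitation.

**What passing tests show — and don't.** The synthetic cohorts reproduce
the published group-wise first and second moments and the qualitative
geometry of the image texture, so they exercise the full pipeline under
realistic signal-to-noise. They do not reproduce the real features'
correlation structure, the camera/lighting physics, or the anatomy of real
necks; absolute performance numbers on synthetic cohorts are properties of
the generator, not estimates of clinical performance. The stable,
reproducible finding is directional: models with image features outperform
the same models without them.

## Problem sizes and numerics

Default analyses use n = 308 subjects (the development-cohort size) with
25-replicate averages for model comparisons; calibration checks use
n = 5000; interval-coverage simulations use 200 replicates at n = 2000.
IRLS converges to score max-norm < 1e−8 with step damping near
separation (coefficients past ±30 raise a separation error); CV folds are
re-dealt once if a fold lacks both classes, then rejected. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`; no
global state.
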