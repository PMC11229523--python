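# Methods

## Measurement model

A fruit is treated as an approximate ellipsoid photographed from three
orthogonal directions: two side views (X, Y) and a top view (Z).  Each view
yields a binary silhouette; pixel counts convert to projected areas through
a camera calibration, and the fruit's half-long/half-short axes come from a
rotation scan of the silhouettes.

### Silhouette extraction

Stages, in order, with their defaults (`imgproc.PreprocessConfig`):

1. **Color adjustment** — saturation gain 1.2 (HSV S channel) and contrast
   gain 1.2 (affine stretch about the image's global mean).  The source
   procedure names the effect ("increase the color difference"), not the
   operator; the affine-about-mean form is chosen because it is idempotent
   at gain 1 and parameter-free otherwise.
2. **Color segmentation** — default K-means on RGB with k = 3 (background,
   fruit, shadow), fixed seed 0, 10 restarts.  The background cluster is the
   border-majority label; the fruit is the non-background cluster whose
   largest connected component covers the image center.  An HSV in-range
   segmenter (hue ∈ [0.12, 0.55], saturation ≥ 0.15 — greens, excluding
   desaturated shadow) and a plain gray threshold are selectable
   alternatives.
3. **De-shadowing** — gray threshold 160, dark-is-foreground.  Cast shadows
   on a light backdrop are brighter than the fruit body, so they fall on
   the background side.
4. **De-pricking** — 5×5 median filter (replicate borders), followed by a
   morphological opening at the same 5 px scale and a 9×9 median smoothing
   pass.  The 5×5 median removes free-standing spikes but always leaves
   ~2 px base stubs where a spike meets the body (near the boundary, half
   the window is body); the opening and wider median plane those stubs off.
5. **Edge detection** — Canny, σ = 1, hysteresis thresholds 0.10/0.25 on the
   unit-scaled gradient.
6. **Contour fill** — dilation by ⌈gap_tolerance/2⌉ (default tolerance
   5 px), hole filling, matching erosion, largest connected component.
   Dilate–fill–erode is used instead of a plain closing because closing
   cannot bridge gaps in a 1 px curve.  A final single-pixel erosion
   recenters the outline: the filled region otherwise carries a sub-pixel
   outward bias (edge pixels straddle the boundary; residual prickle rims
   add to it).

All thresholds are configuration with the defaults above, tuned once on the
synthetic fixtures; the pipeline is deterministic given (image, config,
seed) and equivariant under 90° image rotation.

### Axes and areas

* Coordinates are row-major, origin top-left; angles counter-clockwise.
* A **chord** is the longest contiguous horizontal foreground run in a row
  (robust to stray holes; equals the row sum on hole-free masks).
* `measure_axes` rotates the mask (nearest-neighbor, expanded canvas)
  through θ ∈ {0, step, …, 180−step}, default step 1°, records the maximal
  chord per pose, and takes L1 = max, L3 = min.  Ties go to the
  first-attaining angle (this affects only the reported pose, not the
  lengths).  Half-axes: a = L1·mm_per_px/2, b = L3·mm_per_px/2.
* For a three-view fruit the axis search is **joint**: L1 and L3 are the
  global extrema over all three views' rotation profiles, so a and b are
  the largest half-long and smallest half-short axis of the three
  projected ellipses.  Per-view areas remain per-view.
* Areas: count of 1-pixels × mm²-per-px / 100 → cm².  CPA is the exact
  arithmetic mean of PA₁..PA₃.
* Geometric volumes take axes in cm so they land in ml:
  V_ellip = 4πa²b/3, V_parab = 4πab²/3.  The mm→cm conversion is forced by
  unit coherence of the reference dataset (axes ≈ 19.7/14.8 mm, volumes
  ≈ 18–24 ml).

### Calibration

`CameraCalibration` stores mm-per-px and mm²-per-px and enforces their
redundancy (|mm²_per_px − mm_per_px²| < 5 %).  The reference setup's printed
ratios, 0.126 px per mm and 0.016 px per mm², are read as the
pixels-per-unit direction (0.126² = 0.0159 ≈ 0.016 confirms consistency);
`from_pixel_ratios` accepts that direction explicitly.  Taken literally as
px/mm the numbers would put a 40 mm fruit at 5 px, so the stored convention
is the only physically usable one.

### Reference area oracle and error metric

`slice_integrate_area` implements the sector-sum reference measurement
A = Σ Δθᵢ·π·rᵢ²/360 over a closed profile (angles must sum to 360°), and
`mean_relative_error` the percent MRE between paired measurements.  Both are
used as oracles in the tests; the physical slicing protocol they belong to
is out of scope.

## Estimation

Model family: linear, quadratic, exponential (k₁e^{k₂X}), power (k₁X^{k₂})
on one predictor; multilinear on (a, b) or (PA₁, PA₂, PA₃); plus the two
direct geometric volume estimates.  Fitting is OLS for the linear-in-
parameters forms and true nonlinear least squares (scipy `curve_fit`,
initialized from the log-linearized fit) for exponential/power, because the
selection criteria are residuals on the original scale.

Metrics, computed on training data:

* R² = 1 − SSE/SST.
* RMSE = √(SSE/n) — denominator n, not n−p; back-calculation of SST from the
  published R² values and response SDs is consistent with n.
* χ² = Σ(yᵢ−ŷᵢ)²/ŷᵢ (Pearson-style).  The source never defines its χ²; this
  form is adopted because the published χ²/SSE ratios sit near 1/mean(y)
  across all three model tables (e.g. quadratic-CPA mass: 60·0.73²/1.82 ≈
  17.6 ≈ mean mass 18.01), which no other standard candidate matches.  It is
  a convention, not a validated reproduction, and is never used as an
  acceptance quantity.
* φ = (100 − RMSE)/100 × 100 %, implemented literally although it mixes
  units (RMSE is in grams or millilitres); it is the source's definition.

Ranking is a stable sort by R² descending, ties by χ² then RMSE ascending.

`reference_models()` registers all 65 published models (17 dimension-based,
34 projected-area-based, 14 geometric-volume-based) keyed by
(response, kind, predictors).  Two typographical quirks of the source table
are preserved as notes: the mass block lists the exponential-in-b model
twice and has no exponential-in-a row (the registry stores one copy and
leaves the slot absent), and the geometric ellipsoid-volume R² is stored as
0.902 where the running text shows a stray leading digit.

Grading uses mass intervals with boundaries at the midpoints between the
published per-class extremes: Small [10.73, 14.62), Medium [14.62, 19.465),
Large [19.465, 29.76] g; outside masses raise an error rather than
extrapolate.  Bounds are user-overridable.

## Synthetic data

### Images

`FruitImageSpec` renders a rotated ellipse by the pixel-center inequality
(the ground truth carries the exact semi-axes, pose and analytic area πab),
then layers: an offset desaturated shadow (background gray × 0.8, offset
(18, 12) px), the fruit body (green on near-white), 50 radial prickle spikes
(1–2 px wide, tapering, length ≤ 8 px — sized so that 5×5 median
de-pricking is plausible), and salt noise (default rate 5·10⁻⁴ in the test
fixtures).  The ground-truth mask excludes prickles, shadow and noise.  All
randomness comes from the spec's seed.

### Populations

The population generator models each fruit as a triaxial ellipsoid with
semi-axes p ≥ q (two near-equal long axes) and r (short vertical axis):

* p ~ N(19.72, 2.24²) mm; r conditionally normal given p with correlation
  0.85, N(14.76, 1.38²) marginally, clipped below 0.95·min(p, q);
* q = p·exp(N(0, 0.04)) — the top view is nearly circular, matching the
  reference dataset where π·(mean a)·(mean q) must reproduce the 12.24 cm²
  mean top-view area;
* projections PA₁ = πqr, PA₂ = πpr, PA₃ = πpq (cm²) with independent
  multiplicative noise, CV 1 % on the side views and 7 % on the top view;
* recorded axes a = max(p, q), b = r; V_ellip/V_parab from the exact
  formulas; measured volume V = V_parab·(1+ε), CV 7 %; mass
  M = ρ·V_ellip·(1+ε), CV 8 %, with effective density ρ = 0.7025 g/ml
  calibrated once by large-sample simulation so the default population's
  mean mass hits the 18.01 g target.

This reproduces the reference dataset's qualitative structure: the
ellipsoid volume tracks mass while the paraboloid volume tracks measured
volume, PA₁ and PA₂ are the most correlated directly measured pair (they
share the vertical axis and near-equal horizontal axes), and the b axis
correlates less with everything else.  One caveat: CPA, being the average
of the three areas, necessarily correlates with each PA more strongly than
any measured pair does, so correlation-ordering claims exclude it.

For closure tests the spec accepts an explicit `mass_model`; with
`zero_noise()` every noise scale (and the mid-axis jitter) is zeroed, making
identities exact: CPA = mean(PA), V_parab/V_ellip = b/a, and refitting the
generating law returns its coefficients to machine precision.

What the generator does **not** emulate: non-ellipsoidal shape irregularity,
texture and specular highlights, lighting gradients, occlusion, multi-fruit
scenes, and any distributional feature of the reference data beyond the
published per-characteristic means/SDs and class summaries.  Passing tests
therefore demonstrate algorithmic correctness on idealized near-ellipsoids,
not field robustness.

## Problem sizes and tolerances

The test and acceptance runs use: 20 rendered ellipse fixtures (semi-axes
45–90 px, random poses, 1° scan) for axis recovery at ±2 px; 16 fixtures
for the pixel-vs-analytic area MRE (< 2 %); 8 full photograph pipelines for
end-to-end area MRE; populations of n = 60 (the reference cohort size) for
mass-targeting and closure checks and n = 1200–4000 where correlation or
summary-statistic stability is asserted; 30-point noiseless designs for
coefficient recovery at 1e−6; and a 5-point grid per registry model for the
predict/formula round-trip at 1e−9.  Nearest-neighbor rotation changes mask
area by < 1 % on these fixture scales, which bounds the rotation-scan error
budget.

## Known limitations

* The single-pixel erosion at the end of the pipeline is calibrated to the
  synthetic renderer's crisp boundaries; heavily blurred real images may
  need a different boundary correction.
* K-means segmentation assumes the fruit is the dominant central
  non-background cluster; it will mis-select on images where the fruit is
  off-center or smaller than the shadow.
* The χ² convention (above) is an inference from published ratios and may
  not match the original computation.
* Exponential/power fits inherit `curve_fit`'s local convergence; the
  log-linear initialization makes failure unlikely on positive, monotone
  data but pathological inputs raise a fitting error rather than return
  garbage.
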