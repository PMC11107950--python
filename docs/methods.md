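# Methods

This note documents the models, numerical choices and limitations behind
`fundusmorph`.  It covers what each stage assumes, which constants matter and
why they hold their default values, and what the synthetic generators do and
do not emulate.

## Coordinate and sign conventions

All rasters use 0-based pixel indices with `x` = column and `y` = row
*increasing downward* (raster storage order).  Consequences:

* The OD–fovea angle `arctan((OD_y − fovea_y)/|OD_x − fovea_x|)` is negative
  when the disc sits **above** the fovea on the photograph, in either eye; the
  absolute horizontal separation makes the sign laterality-independent.
* OD orientation θ is the angle from the image horizontal toward increasing
  row index, wrapped to [−90°, 90°].  It is reported raw; the clinical
  interpretation of its sign differs between right and left eyes and is
  treated as metadata, not folded into the measurement.
* FPI defaults to `median(fundus) − median(fovea)`, so a fovea brighter than
  its background is *negative*.  The verbal definition ("foveal intensity
  adjusted for background") and this sign interpretation pull in opposite
  directions; both conventions are implemented
  (`brighter_is_negative=False` gives the other), the default follows the
  brighter-⇒-negative interpretation.  The choice is irrelevant to any
  magnitude-based analysis and flips only coefficient signs.

## Optic disc and fovea

The disc is summarized by its **moment-equivalent ellipse**: the ellipse with
the same normalized second central moments as the segmented region.  Axis
lengths are full lengths `4·sqrt(eigenvalue)`; orientation comes from the
leading eigenvector.  Masks are assumed to contain one connected disc;
specks below 25 px are discarded with a warning, while a second component of
≥ 25 px is treated as a segmentation failure and raises.  Rasterization makes
axis lengths accurate to well under 1% for discs of realistic size (≥ 100 px
diameter); orientation of a near-circular disc is intrinsically ill-posed, so
round-trip guarantees apply from ovality ≈ 1.1 upward.

Foveal masks are standardized to a filled circle at the input centroid
covering 1.00% of the canvas (radius `sqrt(0.01·H·W/π)`, rasterized at the
exact real radius, so the area is correct to one boundary ring of pixels).
This removes segmentation-shape noise from FPI and centroid estimates.

## Vessel metrics

**Calibres.**  Local width at a skeleton pixel is `2·EDT − 1` (twice the
Euclidean distance transform, minus one pixel because the transform measures
to the first *background* pixel center).  Measurement is restricted to the
standard annulus 0.5–1.0 disc diameters from the disc margin, with the disc
diameter taken as the mean fitted axis length.  Per-vessel median widths feed
the revised iterative pairwise combination: sort, pair widest with narrowest
into `k·sqrt(w₁² + w₂²)` (k = 0.88 arteries, 0.95 veins), carry the median of
odd-sized rounds, keep at most the six widest.  These branching coefficients
live in `CalibreConfig` and are exercised in tests only through an
independently coded oracle of the same published procedure.

**Tortuosity** is the length-weighted mean arc-to-chord ratio over skeleton
segments between branch/end points, segments shorter than 10 px ignored.
Arc length is computed on a polyline resampled every 5 skeleton pixels: raw
8-connected step sums overestimate length by up to ~8% depending on
orientation, while 5-px resampling keeps both the straight-line limit
(ratio 1.000) and the semicircle limit (π/2 within 0.05) correct.  Closed
loops have no defined chord and are skipped.  This is the canonical
*distance* tortuosity; curvature-based variants used by some toolboxes would
rank extreme shapes differently, but agree on the straight-vs-sinuous
ordering that matters here.

**Fractal dimension** is classic box counting on the binary vessel map (not
the skeleton): occupied-box counts over a dyadic ladder from 2 px to a
quarter of the image side, least-squares slope of log N vs log(1/ε), clipped
at the planar bound 2.  Partial edge boxes bias the slope slightly downward
(a filled 912² canvas measures ≈ 1.95); the ladder is fixed in
`FractalConfig` so values are comparable across eyes.

## Papillomacular arcade concavity

The main temporal arcade emanates from the disc and bows around the macula;
its inward curvature is the |quadratic coefficient| of a parabola fitted with
the image **row as abscissa** (the arcade opens sideways, toward the fovea):
`col = a·row² + b·row + c`.  Stages, with constants in `ArcadeConfig`:

1. Left-eye masks are mirrored so one code path serves both eyes (|a| is
   mirror-invariant).  Crop to the temporal half: 450 of 912 columns.
2. Pad 16 px; Euclidean distance transform; vessels thinner than 5 px
   (half-width < 2.5) are removed by thresholding the transform and
   morphologically reconstructing the survivors; area opening at 400 px.
3. Circle Hough transform on a 4× decimated skeleton, 16 radii geometrically
   spaced 60–1000 px.  The accumulator is padded on the fovea side because
   flat arcades have centers far beyond the cropped half.  Up to 3 peaks
   above 15 votes are kept and their ±45 px bands united — one circle cannot
   follow a strongly curved parabola's arms, two or three can.
4. Area opening at 150 px removes isolated fragments the bands caught;
   closing with a radius-7 disk bridges gaps.
5. The returned points are the medial axis of the *original* cropped mask
   restricted to the selected region (dilated by 2 px).  Skeletonizing the
   clipped selection itself would let the skeleton drift off the centerline
   wherever a band boundary cuts a vessel obliquely, biasing `a`.  Side
   branches shorter than 100 px between a branch point and a free end are
   pruned (classic spur pruning); the arcade itself, even when cut into
   pieces, is never free-and-attached, so it survives.
6. RANSAC: 500 minimal 3-point samples, inlier band 3 px, least-squares refit
   on the best consensus, error below 30% consensus.  Deterministic given the
   configured seed.  r² is reported on inliers.

Every stage failure raises an error naming the stage.  A debug mode dumps all
intermediate rasters for visual audit.  On synthetic sweeps
(a ∈ [0.0005, 0.005], ~20–30% distractor-branch pixels) recovery of |a| is
within a few percent, and a straight arcade returns |a| at numerical zero.
The Hough/opening/closing constants were chosen on these synthetic sweeps;
real arcades with strong branching asymmetry or pathology may need the
config adjusted, which is why all constants sit in one dataclass.

## Magnification correction and cohort selection

Littmann's relation `t = 1.37 · q · s` converts an image measurement `s`
(pixels) to retinal size, squared for areas.  The ocular magnification factor
`q(SER, CR)` is a pluggable strategy because published approximations differ;
the default is a schematic-eye composition: axial length
`AL = 2.96·CR − SER/2.7` (an emmetropic length proportional to corneal
radius, adjusted at 2.7 D per mm of ametropia) into Bennett's
`q = 0.01306·(AL − 1.82)`.  Nothing downstream depends on these constants
beyond `q > 0` and smoothness; analyses of standardized coefficients are
invariant to any fixed choice of `q` up to scale.

The selection funnel drops, in order and with per-step audit counts: rejected
image quality, user-supplied health exclusions (linked-record logic is out of
scope; the verdict enters as a boolean column), missing
refraction/keratometry/VA, corneal radius outside the within-sample
[0.5, 99.5] percentile interval (fixed bounds available for reproducible
fixtures), and visual acuity worse than 0.00 logMAR.  Counts always sum to
input minus output, and the survivor set is order-invariant.

## Statistical models

Continuous features and age are z-scored (sex is not), so coefficients are
D per SD.  OLS is fitted per refractive group (myopes: SER ≤ −0.50 D) via
statsmodels, with VIF (flag at 10) computed from its definition
`1/(1 − R²_j)` — infinite, not an exception, under perfect collinearity —
and Q-Q / residual-vs-fitted ordinates exposed for the usual visual checks.

Quantile regression runs on the full refractive range over 34 evenly spaced
levels from 0.005 to 0.995 (step 0.03; grid configurable).  The solver is
statsmodels' `QuantReg` (IRLS); at τ = 0.5 it agrees with an independent
least-absolute-deviations linear program to ~1e-7.  Confidence intervals:

* `ci="asymptotic"` (default): the robust Powell kernel-sandwich covariance,
  valid under heteroscedasticity; coverage ≈ 0.93–0.95 in location-scale
  simulations at n = 5000.
* `ci="bootstrap"`: xy-pair resampling with configurable replicates and seed,
  assumption-lighter but two to three orders of magnitude slower.  It is the
  method of choice when the design is small or exotic; asymptotic is the
  default so that coverage-style validation (hundreds of replicate fits)
  stays tractable.

Quantiles whose shorter tail would hold fewer than `min_tail_obs` (default
30) effective observations are refused with a recorded reason; remaining
quantiles are still returned.  No multiple-testing correction is applied
across quantiles: each eye belongs to one refractive quantile, so the per-τ
tests are not repeated tests of a single hypothesis, and the per-quantile
magnitudes are themselves the object of interest.  The intercept curve
reports the prediction at quantile-specific covariate means (eyes assigned to
their nearest grid quantile by empirical SER rank).

## Synthetic generators: what they do and do not show

**Scenes** place a rotated-ellipse disc, an exact-area circular fovea, and
parabolic artery/vein arcades drawn as constant-width tubes
(distance-transform thresholding around the centerline, so centerline widths
are known exactly), with optional sinusoidal tortuosity, short distractor
stubs (alternating classes so both masks carry equal load) and a flat-
background grayscale fundus.  Rendering is byte-deterministic given the
truth (including its seed).  They do **not** emulate: central light
reflexes, width taper along vessels, artery/vein crossings, pathology, or
photometric noise — so passing round-trips demonstrate correctness of the
measurement code, not robustness to real segmentation artifacts.

**Cohorts** use the location-scale construction
`SER = β₀ + Xβ + (1 + Xδ)·ε`, ε ~ N(0, σ²), σ = 2 D around a mildly myopic
intercept (−0.3 D): the true quantile slope is `β_j + δ_j·σ·Φ⁻¹(τ)` in
closed form, which is what makes coverage experiments exact.  The family
produces flat and monotone-in-τ effect curves; U-shaped curves (effects
large at both refractive extremes) lie outside it and are only checked
qualitatively through the reporting layer.  The generator raises if any
row's noise scale `1 + Xδ` is non-positive, so default δ magnitudes are kept
small (≤ 0.15 per feature).

## Problem sizes used in validation

The shipped validation uses 50-scene geometry sweeps, 4 × 20-seed concavity
sweeps with 14 distractor stubs, 500 random calibre multisets, and
quantile-regression simulations at n = 5000 with 200 replicates for CI
coverage — sizes at which every Monte-Carlo margin above is stable to the
digits quoted while a full run stays in the minutes range on one CPU.

## Known limitations

* Artery/vein identity is taken from the input masks; crossings and
  disentanglement are out of scope.
* Calibres summarize the annulus medians only; no per-vessel diameter
  profiles.
* The concavity pipeline's constants target 912×912 inputs; other working
  resolutions require rescaling `ArcadeConfig`.
* `q(SER, CR)` is an approximation; if axial length is available, a custom
  `q_strategy` should use it.
* Eyes are analyzed separately by laterality; within-person correlation
  between fellow eyes is not modelled.
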