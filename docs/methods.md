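# Methods

## Scope and data model

The package consumes (or simulates) four inputs: per-nucleus binary
masks (2D NPY arrays, one file per segmented tumor nucleus, laid out
`Cells/{patient}/{patch}/{cell_number}.npy` with non-consecutive cell
numbers), a rectangular ROI annotation table, a per-patient clinical
table with overall survival `OS` (years) and follow-up status `FUS`
(1 = deceased, 0 = censored), and raster slide images for patch
extraction. Nucleus segmentation itself (a deep network in the source
data) is out of scope: the masks are the interface.

Coordinates are image coordinates everywhere: origin top-left,
x = column, y = row, y increasing downward; angles measured from the
+x axis in that frame. All lengths are in pixels; the 40x scan
resolution of 0.25 µm/px is available as an optional conversion and is
never applied silently.

## Contour convention

The outer boundary is traced through foreground **pixel centers**
(Moore-neighbor tracing with Jacob's stopping criterion, 8-connected
foreground), so a shape w pixels wide has geometric extent w − 1.
Runs of collinear vertices are pruned; an axis-aligned filled rectangle
reduces to its 4 corners. The alternative half-pixel "marching"
contour was rejected because pixel-center geometry makes analytic
checks exact (a 40×20 rectangle has extents 39×19 between centers).
Masks must contain ≥ 5 foreground pixels in a single 8-connected
component; anything else is rejected with the nucleus identity in the
message. Because the released dataset's own contour tracer is
unknown, bit-compatibility with its published feature file is not
promised — conventions here are documented instead.

## Geometry

* **Convex hull**: scipy's Qhull; area by the shoelace formula
  (`ConvexHull.volume` in 2D).
* **Minimum-area rectangle**: rotating calipers — by the standard
  theorem one side of the optimal rectangle is collinear with a hull
  edge, so only hull-edge directions are examined. The reported angle
  lies in [−90°, 0): −90° means axis-aligned and the angle increases
  toward 0° as the rectangle rotates clockwise; ties are broken toward
  the smallest angle. The source data's `rectCenter` feature name is
  ambiguous (its documentation says both "top left point" and
  "center"); this implementation stores the **center** under that
  column and exposes the top-left corner separately as
  `MinAreaRect.top_left`.
* **Feret diameters**: the maximum is the largest pairwise distance
  between hull vertices; the minimum is the smallest width over
  hull-edge normal directions. Angles are reported in [−180°, 180°];
  `min_angle` is defined as the caliper direction (perpendicular to the
  supporting edge) — the source data does not define it, so the choice
  is documented here.
* **Ellipse fit**: direct algebraic least-squares conic fit constrained
  to an ellipse (Halir–Flusser, via scikit-image's `EllipseModel`) on
  the contour points; a moments-based fallback (inertia-equivalent
  ellipse of the mask) engages if the algebraic fit degenerates, and
  can be selected explicitly. Axis lengths are full lengths; area is
  πab on the semi-axes.
* **Ellipse perimeter**: Ramanujan's second approximation,
  h = ((a−b)/(a+b))², P = π(a+b)(1 + 3h/(10+√(4−3h))). Exact for
  circles; relative error < 1e−6 down to aspect ratio ≈ 0.2 and ≈ 0.4%
  in the degenerate flat-ellipse limit (asserted, not hidden, in
  tests).

The six shape factors follow the definitions in the README. The
identity elongation = 1/sf2 holds to floating-point rounding and is
asserted at 1e−9 relative.

## Patch extraction

Rectangles are half-open [x0, x1) × [y0, y1) in 0-based pixels — the
source data does not state inclusivity, and the half-open convention
makes the tiling count exactly ⌊w/stride⌋·⌊h/stride⌋. Fixed-size
windows (default 224) tile each ROI row-major from the top-left corner;
partial windows at the right/bottom edges are dropped, not padded,
since the protocol fixes the patch size and non-overlap. A patch is
discarded when the fraction of pixels with **all** channels above
`white_level` (default 220) strictly exceeds `max_white_fraction`
(default 0.5). The source protocol says only "mostly white", so both
knobs are exposed in the config; published patch counts are therefore
not expected to be bit-reproducible.

## Aggregation and design matrices

Per patient: arithmetic mean and sample standard deviation (n − 1
denominator; the source does not state its choice) of each of the 13
scalar geometric features (lengths, areas, the six factors; angles and
positions carry no shape information). Single-nucleus patients get a
missing std. Clinical cleaning maps 'neg'/'pos'/'no data' to
0/1/missing and drops rows without outcome.

Design assembly inner-joins features with the clinical table (never
fabricating patients), drops all-missing and zero-variance columns
with a warning, imputes remaining missing values by column mean
(complete-case analysis available via `impute="drop"`), and z-scores
every column. Standardization is a deliberate addition — the source is
silent — because it conditions the Newton iteration and makes
coefficients comparable across features; it does not change
concordance, which is rank-based.

## Survival validation

Cox proportional-hazards fitting is delegated to lifelines
(`CoxPHFitter`: Newton–Raphson with step-halving, Efron handling of
tied event times — the defensible default when the source does not
state its tie method; gradient tolerance 1e−7, max 100 steps). The
surface validates inputs (≥ 2 events, no missing values, positive
variances) and converts separation/singularity failures into typed
errors. An optional ridge `penalizer` (default 0, i.e. the plain
partial likelihood) exists for small cohorts where many correlated
geometric columns make the information matrix singular — e.g. smoke
runs with ≤ 30 patients against 26 covariates; study-scale fits
(n ≥ 100) run unpenalized.

Harrell's C is implemented directly (vectorized O(n²)): pair (i, j) is
comparable when i has the event and t_i < t_j, or t_i = t_j with j
censored; a comparable pair scores 1 if the earlier-event subject has
the higher risk score, ½ on score ties. Tied-event-time pairs are not
comparable.

Optimism correction: B bootstrap resamples (with replacement, full
size); per replicate, fit on the resample, evaluate on the resample
(c_boot) and on the original cohort (c_orig); optimism = mean(c_boot −
c_orig) is subtracted from the apparent C. Replicates whose fit fails
(separation or too few events in the resample) are skipped and
counted; more than 10% failures aborts. Replicate r draws its indices
from an independent substream keyed by (seed, r), so results are
identical regardless of execution order.

**CI nesting caveat.** A confidence interval *for the corrected
statistic* strictly requires a double bootstrap. The interval reported
here is the 2.5/97.5 percentile interval (linear-interpolation
quantiles) of the replicate-wise evaluate-on-original C values from the
same B replicates. It brackets the out-of-sample performance the
correction estimates, at a fraction of the cost, but it is not a
double-bootstrap CI; treat its coverage as approximate.

## Synthetic generator

The generator defines the conditions every test runs under.

* **Masks**: analytic shapes (disk, ellipse, rectangle, star-convex
  blob) rasterized by the pixel-center-in-shape rule — unambiguous, and
  it makes areas/extents checkable in closed form. Blobs are
  star-convex polygons (vertices at equally spaced polar angles, radii
  uniform in mean·(1 ± irregularity)), optionally anisotropically
  scaled and rotated; star-convexity guarantees valid single-component
  masks while exercising non-elliptical geometry. Rasterizations that
  pinch apart (very thin shapes) are rejected, and the cohort
  generator redraws them.
* **Survival**: T = −log U / (λ₀ · exp(xᵀβ)) with U ~ Uniform(0,1)
  (inverse-CDF sampling from an exponential-baseline Cox model, so the
  generated data satisfy the fitted model family exactly and closed-form
  checks exist), independent censoring C ~ Exp(λ_c), OS = min(T, C),
  FUS = 1{T ≤ C}.
* **Defaults** (chosen once as a plausible lymphoma-cohort scale):
  170 patients, 30 nuclei each; covariates standard normal; true
  β = (0.8, 0.5, 0.0); baseline hazard λ₀ = 0.15/yr; censoring
  λ_c = 0.08/yr (≈ one third to 40% censored); nucleus mean radius
  12 px with ±35% size jitter on 72×72 grids (diameters within the
  10–60 px band at 0.25 µm/px — the real size distribution is not
  published, so this is a free choice, not a calibration);
  irregularity 0.15 with 24 vertices.
* **Shape → hazard coupling**: a patient with linear predictor lp gets
  nuclei with mean axis ratio clip(0.80 − 0.12·lp, 0.30, 0.95), so
  higher-risk patients have more elongated nuclei and geometric
  features carry survival signal end to end. With β = 0 the ratio is
  constant across patients and geometry is uninformative by
  construction.
* **Slides**: near-white background (channels ≥ 245) with textured
  tissue rectangles (channels 70–200), so the whiteness filter's
  retained-patch count equals the analytic tiling count exactly.

What the generator does **not** emulate: staining color and H&E
texture, segmentation errors (masks are clean analytic shapes),
spatially correlated nucleus populations, informative censoring, or
non-proportional hazards. Passing tests therefore demonstrate the
correctness of the geometry and of the validation statistics under the
stated model — not that real tissue satisfies that model.

## Problem sizes

Test and validation runs use cohorts of 25–200 patients with 6–30
nuclei each, 30–200 bootstrap replicates, and 2000-subject survival
tables for chance-level concordance; the oracle suites sweep 100 random
blob fixtures at 0.1° angular resolution. These sizes keep the full
suite and the validation script comfortably reproducible on a single
CPU while leaving Monte-Carlo error well below the tolerances tested.
The pipeline's production default remains 1000 bootstrap replicates.

## Known limitations

* Exact numeric parity with the source dataset's released feature file
  is not guaranteed (unknown contour tracer and ellipse routine there;
  conventions here are fixed and documented instead).
* The percentile CI is approximate (see the nesting caveat).
* Mean imputation of clinical covariates is simplistic; complete-case
  analysis is available but no multiple imputation.
* The geometric feature set contains strongly correlated columns
  (esf/sf1/sf2/elongation are algebraically related); unpenalized Cox
  fits need enough events to support them, and very small cohorts
  require the ridge option.
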