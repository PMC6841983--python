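# Methods

`retimorph` quantifies the geometry of retinal microvascular networks from
binary vessel-segmentation masks, regionally (optic-disc and macula windows)
and globally (whole retina). This note documents the models, the estimators,
the synthetic data that stands in for fundus photographs, and the numerical
choices behind them.

## Pipeline

For every image the pipeline extracts up to three analysis windows — the
whole mask plus two square (or circular) regions of interest centred on the
optic disc and the macula, 1000 px by default — in that order: crop first,
then skeletonize the cropped window, then measure. All three metrics are
computed on the skeleton:

* **Box-counting dimension** `Db` — space-filling complexity,
  1 (curve-like) to 2 (plane-filling);
* **Lacunarity** `Λ` — gappiness/heterogeneity of the pattern;
* **Skeleton vessel density** — percent of window pixels on the centreline.

Circular ROIs keep their square bounding window; the corner pixels are
forced to background and still count in density denominators and box grids.
This reproduces the known artifact whereby circular windows read lower `Db`
and higher `Λ` than square windows of the same content, which
`compare_roi_shapes` measures directly.

ROI windows that would cross the image border are rejected by default; an
opt-in `clamp` flag shifts them inside and logs the shift. Silent truncation
would change `Db` and `Λ` incomparably between eyes.

## Skeletonization

Masks are thinned with Lee's topology-preserving 3-D thinning specialised to
2-D (`skimage.morphology.skeletonize(method="lee")`), the algorithm behind
the widely used ImageJ "Skeletonize (2D/3D)" plugin. Thinning can leave a
2×2 foreground block where two vessels cross; a deterministic post-pass
dissolves each block by deleting one pixel whose removal provably keeps its
neighbours connected (checked by labelling a surrounding window), or — at a
perfect X-crossing, where no such pixel exists — by deleting the top-left
pixel and re-bridging any stranded arm through an edge-adjacent connector.
Because every arm was connected through the deleted pixel, re-bridging
restores the original topology exactly. The result is unit-width (no 2×2
block) and preserves the number of 8-connected components; both properties
are asserted over 50 seeded synthetic trees in the test suite.

## Box-counting dimension

Settings follow the fixed-grid scan convention: square sampling elements,
12 grid origins, no grid rotation, box sizes up to 45% of the shorter
window side. Sizes are 20 distinct integers linearly spaced in
`[2, floor(0.45·min(H, W))]`; ε = 1 is excluded because `N(1)` equals the
foreground count and only flattens the regression. Origins are
deterministic offsets evenly spaced along the diagonal of the `[0, ε)²`
offset torus, recomputed per size — a reproducible stand-in for randomized
origin sampling. `N(ε)` counts occupied boxes, including boxes that
overlap the window boundary (presence/absence is unbiased by partial
boxes).

**Regression abscissa.** At sizes near 45% of the window, the integer grid
cover — `ceil(L/ε)` boxes per axis — deviates strongly from the power law
(e.g. 3×3 boxes where `(L/ε)² ≈ 4.9`), and an ordinary fit of `ln N`
against `ln(1/ε)` underestimates the dimension of a filled plane by ≈ 0.15.
The per-origin slope is therefore fitted against the *realized grid pitch*
`ε̂ = sqrt((H/c_H)·(W/c_W))` with `c_H, c_W` the per-axis cover counts.
This removes the integer-cover quantization exactly: a filled square fits
to 2.000 and a 1-px line to 1.000 at machine precision, the order-5
Sierpiński carpet to 1.900 (theory `log 8/log 3 ≈ 1.8928`) and the order-5
Koch curve to 1.251 (theory `log 4/log 3 ≈ 1.2619`; finite order and 1-px
rasterization bias it slightly, so its validation tolerance is widened to
±0.08). `Db` is the mean of the 12 per-origin slopes and `db_sd` their
standard deviation.

Counts at a fixed origin are non-increasing in ε only up to ±1 box of cover
quantization; the tests assert that bound rather than strict monotonicity.

## Lacunarity

For each origin and size the window is partitioned into non-overlapping
ε × ε boxes aligned to the shifted grid; boxes that do not fit wholly
inside the window are discarded, because partial boxes bias mass
statistics. With per-box foreground masses `m_i`,
`λ(origin, ε) = σ²/μ²` (population variance over squared mean), and `Λ` is
the unweighted mean of λ over all origins and sizes. This is the plain
squared coefficient of variation, *not* `1 + (σ/μ)²`: reference values for
retinal skeletons lie in `[0.3, 0.5]`, which is only consistent with the
CV² form. Closed-form anchors: a full image gives `Λ = 0`; a single
foreground pixel in a 100² window at ε = 10 gives `λ = 99`; an aligned
ε-checkerboard gives `λ = 1`. Scales where no full box fits, or where the
retained boxes hold no foreground, are skipped (recorded as NaN).

## Calibration, calibers, branching generations

* **Pixel scale.** `um_per_px` is the mean of the horizontal and vertical
  ratios between reference optic-disc dimensions (μm) and the measured
  disc dimensions (px). The reference dimensions are configuration inputs,
  not constants. A 200-px disc against 972 μm references gives the
  fundus-camera scale of 4.86 μm/px used throughout the examples.
* **Caliber.** The measurement point snaps to the nearest skeleton pixel;
  the local vessel direction is the principal axis of the surrounding
  skeleton pixels (radius 5 px), and the caliber is the foreground chord
  along the perpendicular, ray-marched at 0.1-px steps with nearest-pixel
  membership and averaged over five parallel normals (a single digital
  line can thread a staircase notch of an oblique edge). An axis-aligned
  w-px bar reads exactly w; against a brute-force perpendicular-profile
  oracle the agreement is within 0.6 px for widths 1–31 at 0°/30°/45°/90°.
  An isolated centreline point falls back to `2·EDT − 1`. On binary masks
  the external-wall/lumen distinction collapses: the caliber is the mask
  width, a known systematic difference from measurements on raw
  photographs.
* **Generations.** Trunk segments are generation 1. A single continuing
  child keeps its parent's generation. At a bifurcation with daughter
  ratio `r = smaller/larger`: if `r < symmetry_ratio` the larger daughter
  continues the parent's generation and the smaller starts the next; if
  `r ≥ symmetry_ratio` both advance. `symmetry_ratio = 0.8`
  operationalizes "relatively equal diameters" and is exposed as a
  parameter. Calibers attach to segments (sampled at midpoints), since
  diameters change at bifurcations and the rules compare daughters.

## Synthetic data

The generator provides two kinds of ground truth.

**Exact-dimension fractals** (line, filled square, Koch curve, Sierpiński
carpet) validate the metric estimators; the carpet's foreground count has
the closed form `8^order · (side/3^order)²`.

**Stochastic vascular trees** emulate fundus-camera-scale vasculature:
trunk calibers ≈ 20 px (≈ 97 μm at 4.86 μm/px) tapering to ≈ 4–6 px
(≈ 20–30 μm) over about five branching generations, skeleton coverage in
the single-digit to low-teens percent range, and an optional central
avascular zone for macula-like windows. Growth proceeds tip-by-tip with
truncated-normal segment lengths and branch angles; at each tip the vessel
bifurcates with probability `branch_prob`, and the asymmetry draw fixes
daughter calibers so that ground-truth generations follow exactly the rules
`assign_generations` implements (draws are kept away from the 0.8 rule
boundary, so recovery is essentially limited only by window-edge
truncation; measured ≥ 99% over 50 trees). Segments never enter the
avascular zone (tips steer around it), so carving it from the raster cannot
split a tree. `prune_prob` removes terminal segments after growth —
"vascular pruning".

Two presets define the regional conditions:

* `disc_like_params` — 12 trunks of caliber 20 px radiating from the
  window centre, branching densely over short segments (16 ± 4 px) for up
  to 7 generations: a centre-heavy cluster with skeleton density ≈ 11%
  and `Λ ≈ 0.6` at the 512-px window.
* `macula_like_params` — 10 roots of caliber 6 px entering from a
  peripheral ring and sweeping across the window around a 26-px avascular
  zone: an even field with density ≈ 8% and `Λ ≈ 0.4`.

Both directions — macula sparser *and* less lacunar than the disc — match
the healthy-retina regional pattern, and they are not independent: for
line-like patterns Λ rises as density falls, so the macula preset must be
substantially more spatially even to sit below the disc preset on both
axes. That coupling is the main reason these presets are calibrated as a
pair.

**Cohorts.** A synthetic cohort image is a `window × 2·window` canvas with
the group's disc-like tile on the left and macula-like tile on the right;
the manifest's ROI centres are the tile centres, so the default ROI
recovers each tile exactly. Group presets encode the disease directions:
glaucoma is a mild global attenuation (one fewer trunk, slightly lower
macular branching); diabetic retinopathy prunes half of the terminal
macular branches and enlarges the avascular zone (macular `Db` and density
drop) while its disc tile grows fewer, thicker, more strongly tapering
trunks (disc `Λ` rises). With 15 images per group these presets reproduce
the qualitative regional pattern: healthy macula below healthy disc on `Λ`
and density; DR macula lowest on `Db` and density with a distinct Tukey
letter; DR disc highest on `Λ`.

**What the generator does not emulate:** real photograph artifacts
(illumination, segmentation errors), arteriole/venule distinction, vessel
tortuosity beyond angular jitter, crossing-free planarity (strokes of
different trees may overlap), and the absolute metric values of any real
dataset. Passing the synthetic tests therefore shows the estimators and
statistics are correct and directionally faithful, not that any particular
real cohort will reproduce specific printed values.

## Statistics

* Regional contrasts within one group: two-tailed independent-samples
  t-test; the classical pooled-variance Student form by default, Welch's
  correction behind a flag.
* Whole-retina group effects: one-way ANOVA with Tukey HSD.
* Regional patterns: two-way ANOVA (region × diagnosis) via OLS with Type
  II sums of squares — identical to Type I/III on the balanced design —
  with Tukey HSD over the six cell means; the headline p-value is the
  interaction.
* Compact letter displays are built by the insert-and-absorb algorithm
  over the Tukey significance matrix, processing levels in descending-mean
  order; the letters are a deterministic function of the means and the
  matrix.

Degenerate inputs (zero within-group variance) are resolved by closed
form: `F = 0, p = 1` when the between-group variation is also zero, else
`F = ∞, p = 0`, with Tukey p-values 0/1 by mean equality. The two-way
interaction test's type-I error is calibrated by simulation: 2000 null
cohorts (6 cells × 5, standard normal) must reject at 5% ± 2%.

## Problem sizes and tolerances

The validation suite uses 729–1024 px fractal fixtures (order 5), 320-px
windows for the 50-tree skeleton/generation contracts, 512-px preset
windows for direction-of-effect runs (20 seeds per preset), and a
3 × 15-image cohort at the 512-px tile size for the end-to-end study;
these sizes keep a full run in a few CPU-minutes while leaving every
estimator in its asymptotic regime. Dimension tolerances are ±0.02 for
plane/line fixtures, ±0.05 for the carpet, ±0.08 for the rasterized Koch
curve; caliber tolerance is ±1 px against the profile oracle.

## Known limitations

* `Db` and `Λ` depend on the origin scheme and size series; absolute
  values are comparable only within a fixed configuration (the defaults
  pin one down).
* Whole-retina skeleton density as defined here (percent of all window
  pixels) is much lower than values reported by vessel-analysis tools
  whose density denominators are vessel-area based; cross-tool density
  comparisons are out of scope.
* The caliber estimator measures mask width, not wall-to-wall diameter.
* Synthetic trees are 2-D and hemodynamics-free; their parameters were
  chosen to emulate scale and coverage, not flow-consistent branching
  exponents.
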