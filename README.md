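# retimorph

Regional morphometry of retinal microvascular networks from binary vessel
masks.

Retinal fundus photography shows the microvascular tree non-invasively,
and its geometry changes with disease: diabetic retinopathy prunes and
remodels macular vessels, glaucoma attenuates the network globally. Because
the optic-disc region (large trunks, low branching generations) and the
macular region (fine arterioles around the foveal avascular zone) are
anatomically distinct, remodelling need not be uniform across the retina —
global averages can wash out regional signals. `retimorph` is a toolkit
for quantifying exactly that: it measures vessel geometry inside
disc-centred and macula-centred regions of interest as well as across the
whole retina, and compares diagnostic groups statistically. It is written
for image-analysis and ophthalmic-research groups working with
segmentation masks such as the HRF database's gold standards.

## What it computes

Given a binary vessel mask, each analysis window (whole retina, or a
1000-px square/circular ROI) is skeletonized and described by three
numbers:

* **Box-counting fractal dimension** `Db`: the grid of box size ε is
  scanned from 12 deterministic origins; for each origin,
  `Db = slope of ln N(ε) vs ln(1/ε̂)` where `N(ε)` is the number of
  occupied boxes, ε runs linearly from 2 px to 45% of the window, and ε̂
  is the realized grid pitch. `Db` is the mean over origins —
  1 for curve-like, 2 for plane-filling patterns.
* **Lacunarity** `Λ = mean over origins and sizes of (σ/μ)²` of the
  per-box foreground mass — 0 for translation-invariant patterns, large
  for gappy, clumped ones.
* **Skeleton vessel density**: percent of window pixels on the vessel
  centreline.

Around this core the package provides ROI extraction with exact corner
handling for circular windows, pixel-scale calibration from optic-disc
dimensions, vessel-caliber measurement, diameter-rule branching-generation
assignment, a synthetic-data module (exact-dimension fractals and seeded
vascular-tree simulations) that makes the whole pipeline testable without
any image download, and the group statistics: regional t-tests, one-way and two-way ANOVA
with Tukey HSD and compact letter displays.

See `docs/methods.md` for the estimator details and design rationale.

## Worked example

```python
from retimorph import (FractalFixtureSpec, box_count, lacunarity, make_fractal,
                       simulate_tree, disc_like_params, macula_like_params,
                       skeletonize, vessel_density, estimate_pixel_scale)

# 1. validate the estimator on a known fractal
carpet = make_fractal(FractalFixtureSpec("sierpinski_carpet", order=5, side=729))
fit = box_count(carpet)
print(f"carpet Db = {fit.db:.3f} +/- {fit.db_sd:.3f}  (theory 1.893)")

# 2. measure synthetic disc-like and macula-like vascular windows
for name, params in [("disc", disc_like_params(seed=0)),
                     ("macula", macula_like_params(seed=0))]:
    tree, mask = simulate_tree(params)
    sk = skeletonize(mask)
    print(f"{name:6s} Db = {box_count(sk).db:.3f}  lambda = {lacunarity(sk).lambda_mean:.3f}  "
          f"density = {vessel_density(sk).density_pct:.2f}%  max generation = {tree.max_generation()}")

# 3. calibrate pixel size from optic-disc dimensions
scale = estimate_pixel_scale(200, 200, 972, 972)
print(f"pixel scale = {scale.um_per_px:.2f} um/px")
```

prints

```
carpet Db = 1.906 +/- 0.002  (theory 1.893)
disc   Db = 1.713  lambda = 0.789  density = 8.55%  max generation = 7
macula Db = 1.726  lambda = 0.386  density = 8.81%  max generation = 5
pixel scale = 4.86 um/px
```

The carpet lands within 0.015 of its theoretical dimension. The two
vascular windows illustrate the regional contrast the package is built to
detect: for this seed the macula-like window is far more homogeneous
(Λ 0.39 vs 0.79) than the disc-like window, whose vessels cluster around
the centre; averaged over seeds the macula preset is also sparser. A
200-px optic disc against 972-μm reference dimensions gives the
fundus-camera scale of 4.86 μm/px, at which a 20-px trunk is a ~97 μm
first-generation vessel.

## Command line

```bash
retimorph simulate --out cohort --n-per-group 15 --seed 1   # synthetic cohort
retimorph analyze --manifest cohort/manifest.csv --out results --roi-size 512
retimorph compare-shapes --manifest cohort/manifest.csv --roi-size 512
```

`analyze` writes `metrics.csv` (one row per image × region),
`stats_global.csv`, `stats_regional.csv` and `run_report.txt`. For real
data, point `--manifest` at a CSV with columns
`image,mask,group,od_x,od_y,mac_x,mac_y`.

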