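# foodvol

Single-capture, depth-image food volumetry for dietary assessment.

Depth-sensing phones can quantify a meal from one photograph: the depth map
gives a 3-D view of the plate, the food's visible surface is closed against
the dish to get a volume, and density/composition tables turn volume into
weight, macronutrients and energy. `foodvol` implements that full pipeline —
plus a synthetic depth-scene simulator and the method-comparison statistics
used to evaluate such systems — so the approach can be studied, stress-tested
and extended entirely in software, without camera hardware or real meals. It
is aimed at researchers in nutrition informatics and computer-vision dietary
assessment.

## Method

Given a depth map `Z(u,v)` (z-depth in meters) and pinhole intrinsics
`(fx, fy, cx, cy)`:

1. **Back-projection.** Each valid pixel becomes a 3-D point
   `((u−cx)Z/fx, (v−cy)Z/fy, Z)` in the camera frame.
2. **Table plane.** RANSAC over seeded 3-point samples maximizes the inlier
   count at a distance threshold (default 5 mm, 500 iterations), then a
   total-least-squares refinement (smallest singular vector of the centered
   cloud) polishes the winning hypothesis. The unit normal **n** is oriented
   toward the camera, so `h(p) = n·p − d` is a point's height above the
   table.
3. **Surface.** A 2-D Delaunay triangulation of the pixel coordinates,
   lifted to 3-D, meshes the visible surface; triangles with a 3-D edge
   longer than 10× the median pixel spacing are removed (they bridge
   occlusion gaps, not surface).
4. **Cut and close.** A triangle belongs to item *i* iff all three vertices
   are labeled *i* by the segmentation; each item's open surface is closed
   straight down onto the dish base and integrated by the prism rule

   `V = Σ_triangles  A_proj · mean(max(h − b, 0))`

   with `A_proj` the footprint area in the table's tangent frame and `b` the
   dish-base height (flat plate or spherical-cap bowl).
5. **Nutrients.** `weight = V · density`; macros scale per 100 g from a food
   table; energy uses the table's kcal or the Atwater fallback
   `4·CHO + 4·protein + 9·fat`.

Agreement with a reference follows standard method-comparison practice:
bias = estimate − reference, absolute and percent errors, and 95% limits of
agreement `mean(bias) ± 2·SD(bias)`, with Bland–Altman plots, stratified by
meal type and capture angle.

The simulator renders meals of parametric solids (spherical caps, boxes,
cylinders, half-ellipsoids — all with closed-form volumes) on a plate by
per-pixel ray casting, adds structured-light-style noise
(`σ(z) = σ0 + σ1 z²`, grazing-incidence dropout, mm quantization), and
generates a 48-meal benchmark (equal thirds breakfast/cooked/snack with
4/3/1 items, balanced randomized 45°/90° capture angles per batch).

## Worked example

```sh
python examples/01_quantify_single_capture.py
```

```
estimated volume:   256.7 mL   (analytic 261.8 mL)
estimated weight:   256.7 g    (reference 261.8 g)
macros: 38.5 g carbohydrate, 5.1 g protein, 8.2 g fat, 257 kcal
```

A 5 cm hemisphere of mashed potato (density 1.00 g/mL) rendered at a nadir
view is recovered to −2%; the deficit is the half-pixel mask boundary plus
the dome limb a finite camera cannot see. The other examples show the noise
model (`02`), a 12-meal agreement study with stratified error tables and a
Bland–Altman plot (`03`), and the geometric intermediates with PLY export
(`04`).

The same pipeline is available from the shell:

```sh
foodvol simulate --seed 3 --out scene/
foodvol estimate --depth scene/depth.png --intrinsics scene/intrinsics.json \
                 --mask scene/mask.png --out items.csv
foodvol benchmark --n 48 --seed 0 --report report.csv
```

## Layout

- `src/foodvol/depth_geometry.py` — camera model, back-projection, RANSAC
  plane, Delaunay surface, depth-PNG / PLY I/O
- `src/foodvol/scene_sim.py` — solids, ray-cast renderer, noise model,
  benchmark generator, Monte-Carlo volume oracle
- `src/foodvol/segmentation.py` — height-above-plane segmenter, IoU /
  coverage metrics, simulated manual correction
- `src/foodvol/volumetry.py` — surface cutting, dish models, prism
  integration, the `estimate_meal` orchestrator
- `src/foodvol/nutrient_db.py` — food table schema and conversions (a
  bundled synthetic table stands in for a national composition database)
- `src/foodvol/evaluation.py` — bias/error/LoA statistics, stratified
  reports, Bland–Altman plots
- `src/foodvol/benchmark.py` — end-to-end benchmark harness
- `docs/methods.md` — models, assumptions, parameter choices, limitations
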