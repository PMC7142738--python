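# Methods

This note documents the models behind `foodvol`, the parameter defaults and
why they were chosen, what the synthetic benchmark does and does not
emulate, and the known limits of single-capture volumetry.

## Geometry conventions

Depths are **z-depths**: distance along the optical axis, not ray length —
the convention of common depth-map formats, applied consistently in the
renderer and in back-projection. The camera frame is right-handed with +x
right, +y down (image convention) and +z into the scene. Plane normals are
canonicalized toward the camera, so for a table seen from above the signed
distance `n·p − d` is a height: positive above the table. Depth PNGs are
16-bit grayscale in millimeters with 0 = invalid; zero, NaN and
out-of-range depths are demoted to invalid pixels and counted in the debug
log rather than raised as errors.

## Table-plane fit

RANSAC draws seeded 3-point samples (no global RNG anywhere in the
package), scores inliers at an absolute point-plane distance threshold, and
breaks count ties by lower inlier RMS. The winner is refined by total least
squares — the smallest right singular vector of the centered inlier cloud —
re-thresholded, and refined once more for stability.

* `iterations = 500`: for the benchmark scenes ≥ 75% of pixels are table,
  so the probability that 500 samples never draw 3 inliers is negligible;
  500 also keeps the fit deterministic-fast at 10⁵–10⁵·⁵ points.
* `inlier_threshold = 5 mm`: about 5× the sensor noise at 0.4 m, small
  enough that food pixels (≥ several mm above the table) barely contaminate
  the refinement.

## Surface triangulation and the edge filter

Because a single-view cloud is a perspective height field, Delaunay
triangulation runs in pixel coordinates and is lifted to 3-D. Triangles
with any 3-D edge longer than `max_edge` are discarded: such edges span
depth discontinuities (an item's silhouette against the table behind it),
not surface. The default is **10× the median 3-D spacing of horizontally
adjacent valid pixels**. A tighter 5× filter discards genuine steep flank
surface on noiseless domes (it cuts in at surface slopes around 3–5),
while true occlusion-bridge edges for portion-sized items span at least
`height·√2 ≳ 14 mm`, far above the 10× threshold (≈ 6–12 mm at the
default resolutions) — so 10× keeps real surface without readmitting
bridges. Zero-area faces are dropped.

## Cutting, closure and integration

A triangle is assigned to item *i* only when all three vertex pixels carry
label *i*; mixed-label triangles straddle boundaries and are dropped. This
biases volume low by roughly half a pixel of footprint along each item
outline (≈ 1–3% at the default resolutions) and is accounted for in the
stated tolerances. Items that end up with no triangles are excluded and
reported, not silently zeroed.

Each food surface is closed **straight down** onto the dish base: per
triangle, the footprint area projected onto the table's tangent frame times
the mean of the three vertex heights above the base, negative heights
clipped to zero. This prism rule is exact for height fields over the base,
needs no watertight mesh (a unit test checks it against trimesh's
divergence-theorem volume on a watertight box), and encodes the package's
hidden-volume convention: the unseen interior under the visible surface is
filled, concave overhangs are out of scope.

Dish bases are templates registered to the fitted plane: a flat plate at a
configurable offset (default 0 — the base is the table plane itself) or a
spherical-cap bowl evaluated as a height field. How a deployed system
obtains dish geometry from data is an open design question; a template is
the minimal defensible choice and is what the benchmark uses.

## Segmentation

The deployed systems this package models use a learned segmenter with a
manual fix-up step; learned segmentation is out of scope here (and
recognition is not the quantification problem). The stand-in is
deterministic: pixels whose back-projected point lies more than
`dish_height + min_height` above the fitted plane (defaults 0 + 3 mm) are
food candidates; 4-connected components of at least `min_region_px = 50`
pixels become items, labeled by decreasing size. The manual fix-up is
simulated by replacing items whose IoU against the reference outline falls
below a floor (default 70%) with the reference outline, and counting them —
enabling reports in the form "k of n items required adjustment". Both
overlap metrics encountered in this literature are provided: IoU and
coverage of the corrected area (`|A∩B|/|B|`), since published definitions
disagree. The benchmark's default quantification mask is the *corrected*
one, mirroring how such an app is actually used; the auto-segmenter's
outlines track the reference closely on noiseless renders (mean IoU in the
mid-90s, reported by the acceptance script), so this choice is not
load-bearing for the error statistics.

## Nutrient conversion

Weight = volume × density; macros scale per 100 g; energy prefers the
table's kcal column and falls back to Atwater 4/4/9. The bundled
25-food CSV is a **synthetic stand-in** with realistic densities and
compositions, shipped because national composition databases are not
redistributable; its schema
(`food_id,name,density_g_per_ml,cho_g_per_100g,protein_g_per_100g,fat_g_per_100g,kcal_per_100g`)
lets users drop in a real database.

## Synthetic scenes and the noise model

Foods are four primitives with closed-form volumes: spherical caps
(πh²(3r−h)/3), boxes (abc), vertical cylinders (πr²h) and half-ellipsoids
(⅔πabc). The default item pool spans realistic portion sizes (3–6 cm
footprints, 1–3 cm heights) with domes kept shallow (cap h/r ≤ 0.75,
ellipsoid height below the horizontal semi-axes), because steep domes are
the worst case for single-view capture (below). A radial layout with a
per-slot footprint cap guarantees items never intersect — ground-truth
volumes assume disjoint solids — and stay on the plate.

The noise model mimics structured-light error growth:
`σ(z) = σ0 + σ1·z²` Gaussian depth noise with σ0 = 0.5 mm and
σ1 = 3 mm/m² (≈ 1 mm total at 0.4 m), dropout of pixels whose viewing ray
meets the surface at more than 80° incidence, and 1 mm quantization. These
magnitudes are assumptions in the range of small active depth sensors, not
measured device constants, and are exposed for sensitivity analysis. One
non-obvious estimator interaction: zero-mean vertex jitter *inflates* the
expected projected area of near-degenerate limb triangles (|cross product|
is convex in the vertex positions), so mild noise can partially mask the
self-occlusion deficit; noisy runs scoring slightly better than noiseless
ones at oblique angles is expected behavior, not a bug.

The benchmark reproduces the evaluated study's design: `n` meals in equal
thirds of breakfasts (4 items), cooked meals (3) and snacks (1), the
capture angle drawn as a balanced randomized binary 45°/90° sequence within
each meal-type batch, everything reproducible from one seed. Capture
geometry defaults: 480×360 depth maps (fx = fy = 450) at 0.40 m for the
benchmark — phone depth sensors resolve far below photo resolution, and
this size keeps a 48-meal run at a few minutes — and close-range VGA
(640×480, fx = 600, 0.35 m) for the single-primitive scenes.

What the simulator does **not** emulate, and therefore what passing tests
cannot show about real data: irregular and deformable food shapes, touching
or overlapping items (the hard case for real cooked meals), mixed and
composite dishes, liquids and specular or translucent surfaces, RGB
appearance (and hence any learned segmentation), sensor calibration error,
and real density variability — the bundled densities are exact by
construction, while in practice density error adds directly to weight
error.

## The limits of a single capture

A single capture cannot see back-facing surface, and the straight-down
closure cannot invent it. For a hemisphere the test suite integrates the
visibility condition `n·(C−p) ≥ 0` numerically: at 45° inclination and
0.35 m range only ≈ 84–85% of the volume is on visible surface (≈ 91% for
a camera at infinity), and near-limb pixels are so foreshortened that the
last sampled ring sits millimeters from the true limb, costing a few
percent more. The pipeline's hemisphere recovery at 45° is therefore
≈ −22%, and no faithful implementation of this geometry can reach −10%.
Shallow domes, boxes and cylinders — whose tops are fully visible at 45° —
recover to within 1–8% at both angles, which is why the default pool keeps
domes shallow. The residual angle sensitivity of the benchmark (mean
absolute relative volume error ≈ 8% at 45° vs ≈ 3% at 90°, a gap of
≈ 5–6 points) is dominated by the same effect and represents the honest
cost of oblique single-view capture for rounded foods; flat-topped foods
show no angle effect.

For the s³ scaling law, captures are compared under geometric similarity
(camera distance scaled with the object): with a fixed camera, perspective
visibility shrinks with object size — a physical effect, not a property of
the integrator — and the law holds only up to that visibility change.

## Numerical choices

* RANSAC ties: higher inlier count wins; equal counts fall to lower inlier
  RMS. Collinear 3-point samples are skipped; all-collinear input raises a
  fit error.
* Segmentation label order: decreasing region size, stable for equal sizes.
* Heights are clipped at the base surface (negative prisms contribute 0);
  surfaces entirely on or below the base yield volume 0 with a warning.
* Limits of agreement use exactly ±2·SD with the sample (n−1) standard
  deviation; relative metrics divide per-meal by that meal's reference and
  average across meals, excluding (and counting) non-positive references.
* All RNG flows through `numpy.random.default_rng(seed)`; benchmark scenes
  carry derived per-scene seeds so any meal can be regenerated alone.

## Problem sizes

Default runs used throughout tests and the acceptance script: 48-meal
benchmarks at 480×360 (≈ 0.9 mm pixel footprint on the table), primitive
scenes at 640×480, Monte-Carlo oracles at 10⁶ samples, plane-recovery
stress at 400 points × 20 seeds. A full benchmark run (generation,
rendering, segmentation, estimation, statistics) takes ≈ 3 minutes on one
CPU core.
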