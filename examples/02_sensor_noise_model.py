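"""Effect of the structured-light noise model on a capture.

Renders a clean depth map, corrupts it with depth-dependent Gaussian noise,
grazing-incidence dropout and millimeter quantization, and compares the
volume estimated from the clean and the noisy capture.
"""

import numpy as np

from foodvol import (
    CameraIntrinsics,
    FoodSolid,
    LabelMask,
    SceneSpec,
    add_noise,
    analytic_volume,
    estimate_meal,
    render_depth,
)
from foodvol.nutrient_db import FoodRecord, FoodTable
from foodvol.volumetry import PipelineConfig

K = CameraIntrinsics(fx=450, fy=450, cx=239.5, cy=179.5, width=480, height=360)
solid = FoodSolid(kind="half_ellipsoid", params={"a": 0.05, "b": 0.04, "c": 0.025},
                  food_id="unit")
scene = SceneSpec(meal_type="snack", items=[solid], inclination_deg=45.0,
                  camera_distance_m=0.40)
foods = FoodTable([FoodRecord(food_id="unit", name="unit", density_g_per_ml=1.0,
                              cho_g_per_100g=10, protein_g_per_100g=5, fat_g_per_100g=2)])

depth, labels = render_depth(scene, K)
noisy = add_noise(depth, sigma0_m=0.0005, sigma1_per_m=0.003,
                  dropout_grazing_deg=80.0, quant_mm=1.0, seed=7, K=K)
print(f"valid pixels: clean {depth.n_valid}, noisy {noisy.n_valid} "
      f"({depth.n_valid - noisy.n_valid} dropped at grazing incidence)")

mask = LabelMask(labels=labels.astype(np.int32), food_ids={1: "unit"})
truth = analytic_volume(solid)
for name, d in [("clean", depth), ("noisy", noisy)]:
    est = estimate_meal(d, K, mask, cfg=PipelineConfig(seed=1), food_table=foods)
    v = est.items[0].volume_mL
    print(f"{name:5s} capture: {v:6.1f} mL  ({100 * (v - truth) / truth:+.1f}% vs "
          f"analytic {truth:.1f} mL)")
print("The oblique view loses the dome's back-facing flank; note that noise "
      "can partially mask that deficit: zero-mean vertex jitter inflates the "
      "expected projected area of near-degenerate limb triangles (|cross "
      "product| is convex), a small positive bias of the prism integrator.")
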