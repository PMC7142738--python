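"""Surface cutting, dish closure and prism volume integration."""

import math

import numpy as np
import pytest

from foodvol.depth_geometry import Plane, PointCloud, TriMesh, triangulate_surface
from foodvol.nutrient_db import FoodRecord, FoodTable
from foodvol.scene_sim import FoodSolid, SceneSpec, monte_carlo_volume, render_depth
from foodvol.segmentation import LabelMask
from foodvol.volumetry import (
    DishModel,
    FoodSurface,
    PipelineConfig,
    close_and_volume,
    cut_surface,
    estimate_meal,
)

TABLE = Plane.from_vector([0.0, 0.0, -1.0], -0.5)  # fronto-parallel table at z=0.5

UNIT_FOODS = FoodTable([
    FoodRecord(food_id="unit", name="unit-density food", density_g_per_ml=1.0,
               cho_g_per_100g=10.0, protein_g_per_100g=5.0, fat_g_per_100g=2.0),
])


def height_field_surface(height_fn, extent=0.06, n=121, label=1):
    """Synthetic densely sampled surface over the fronto-parallel TABLE:
    z = 0.5 - height(x, y).  Returns (FoodSurface, mask) on a pixel grid."""
    xs = np.linspace(-extent, extent, n)
    ys = np.linspace(-extent, extent, n)
    X, Y = np.meshgrid(xs, ys)
    H = height_fn(X, Y)
    pts = np.column_stack([X.ravel(), Y.ravel(), 0.5 - H.ravel()])
    rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    cloud = PointCloud(points=pts, pixel_index=np.column_stack([rows.ravel(), cols.ravel()]))
    mesh = triangulate_surface(cloud, max_edge_m=1.0)
    mask = LabelMask(labels=np.full((n, n), label, dtype=np.int32))
    return cut_surface(mesh, mask)[0], mask


class TestCutSurface:
    def make_mesh(self, n=8):
        rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        pts = np.column_stack([cols.ravel() * 0.01, rows.ravel() * 0.01, np.full(n * n, 0.5)])
        cloud = PointCloud(points=pts, pixel_index=np.column_stack([rows.ravel(), cols.ravel()]))
        return triangulate_surface(cloud, max_edge_m=1.0), n

    def test_uniform_mask_keeps_all_faces(self):
        mesh, n = self.make_mesh()
        mask = LabelMask(labels=np.ones((n, n), dtype=np.int32))
        surfaces = cut_surface(mesh, mask)
        assert len(surfaces) == 1
        assert surfaces[0].n_faces == mesh.n_faces

    def test_zero_mask_gives_no_surfaces(self):
        mesh, n = self.make_mesh()
        assert cut_surface(mesh, LabelMask(labels=np.zeros((n, n), dtype=np.int32))) == []

    def test_all_vertex_rule_on_checkerboard(self):
        """Brute-force check: a face belongs to item i iff all three vertex
        pixels carry label i; mixed faces are dropped."""
        mesh, n = self.make_mesh()
        labels = ((np.add.outer(np.arange(n), np.arange(n)) // 2) % 2 + 1).astype(np.int32)
        mask = LabelMask(labels=labels)
        surfaces = {s.label: s for s in cut_surface(mesh, mask)}
        kept = sum(s.n_faces for s in surfaces.values())
        assert kept < mesh.n_faces
        for lab, surf in surfaces.items():
            face_px = surf.mesh.pixel_index[surf.mesh.faces]
            face_labels = labels[face_px[..., 0], face_px[..., 1]]
            assert (face_labels == lab).all()

    def test_item_with_no_triangles_excluded(self):
        mesh, n = self.make_mesh()
        labels = np.ones((n, n), dtype=np.int32)
        labels[0, 0] = 2  # single pixel cannot own a full triangle
        surfaces = cut_surface(mesh, LabelMask(labels=labels))
        assert [s.label for s in surfaces] == [1]


class TestCloseAndVolume:
    def test_surface_on_base_is_zero(self):
        surf, _ = height_field_surface(lambda x, y: np.zeros_like(x))
        assert close_and_volume(surf, DishModel(), TABLE) == 0.0

    def test_flat_slab_exact(self):
        """A constant-height field over a square footprint integrates to
        exactly area x height."""
        surf, _ = height_field_surface(lambda x, y: np.full_like(x, 0.02), extent=0.05)
        vol = close_and_volume(surf, DishModel(), TABLE)
        assert vol == pytest.approx(0.10 * 0.10 * 0.02 * 1e6, rel=1e-12)

    def test_dense_hemisphere_within_2pct(self):
        r = 0.05
        surf, _ = height_field_surface(
            lambda x, y: np.sqrt(np.maximum(r**2 - x**2 - y**2, 0.0)), extent=0.055, n=161
        )
        vol = close_and_volume(surf, DishModel(), TABLE)
        assert vol == pytest.approx((2 / 3) * math.pi * r**3 * 1e6, rel=0.02)

    def test_matches_monte_carlo_oracle(self):
        solid = FoodSolid(kind="half_ellipsoid", params={"a": 0.05, "b": 0.04, "c": 0.03})
        surf, _ = height_field_surface(
            lambda x, y: 0.03 * np.sqrt(np.maximum(1 - (x / 0.05) ** 2 - (y / 0.04) ** 2, 0.0)),
            extent=0.055, n=161,
        )
        vol = close_and_volume(surf, DishModel(), TABLE)
        mc = monte_carlo_volume(solid, n_samples=500_000, seed=3)
        assert vol == pytest.approx(mc, rel=0.03)

    def test_prism_agrees_with_divergence_theorem_on_watertight_box(self):
        """The open-surface prism rule on a box's top face equals the
        divergence-theorem volume of the closed box mesh."""
        import trimesh

        surf, _ = height_field_surface(lambda x, y: np.full_like(x, 0.03), extent=0.04)
        prism = close_and_volume(surf, DishModel(), TABLE)
        closed = trimesh.creation.box(extents=(0.08, 0.08, 0.03))
        assert prism == pytest.approx(closed.volume * 1e6, rel=1e-9)

    def test_negative_heights_clipped(self):
        surf, _ = height_field_surface(lambda x, y: np.full_like(x, -0.01))
        assert close_and_volume(surf, DishModel(), TABLE) == 0.0

    def test_monotone_in_height(self):
        r = 0.04
        fn = lambda x, y: np.sqrt(np.maximum(r**2 - x**2 - y**2, 0.0))
        surf, _ = height_field_surface(fn, extent=0.05)
        v0 = close_and_volume(surf, DishModel(), TABLE)
        lifted = FoodSurface(
            label=surf.label,
            mesh=TriMesh(
                vertices=surf.mesh.vertices - [0, 0, 0.002],  # 2 mm toward camera
                faces=surf.mesh.faces,
                pixel_index=surf.mesh.pixel_index,
            ),
        )
        assert close_and_volume(lifted, DishModel(), TABLE) > v0

    def test_integrator_cubic_scaling(self):
        """Scaling the sampled surface by s scales the volume by exactly s^3."""
        r = 0.04
        fn = lambda x, y: np.sqrt(np.maximum(r**2 - x**2 - y**2, 0.0))
        surf, _ = height_field_surface(fn, extent=0.05)
        v1 = close_and_volume(surf, DishModel(), TABLE)
        for s in (0.5, 2.0):
            scaled = FoodSurface(
                label=1,
                mesh=TriMesh(
                    vertices=(surf.mesh.vertices - [0, 0, 0.5]) * s + [0, 0, 0.5],
                    faces=surf.mesh.faces,
                    pixel_index=surf.mesh.pixel_index,
                ),
            )
            assert close_and_volume(scaled, DishModel(), TABLE) == pytest.approx(
                s**3 * v1, rel=1e-9
            )

    def test_bowl_base_closed_form(self):
        """A flat surface at the bowl rim height encloses exactly the bowl's
        interior: a spherical cap of height D cut from a sphere of radius R."""
        R, D = 0.08, 0.03
        bowl = DishModel(kind="bowl", bowl_radius=R, depth=D)
        rim_rho = math.sqrt(D * (2 * R - D))
        surf, _ = height_field_surface(
            lambda x, y: np.where(x**2 + y**2 <= rim_rho**2, D, 0.0),
            extent=rim_rho, n=201,
        )
        vol = close_and_volume(surf, bowl, TABLE)
        expected = math.pi * D**2 * (3 * R - D) / 3 * 1e6
        assert vol == pytest.approx(expected, rel=0.01)

    def test_plate_offset_reduces_volume(self):
        surf, _ = height_field_surface(lambda x, y: np.full_like(x, 0.02), extent=0.05)
        v0 = close_and_volume(surf, DishModel(offset=0.0), TABLE)
        v5 = close_and_volume(surf, DishModel(offset=0.005), TABLE)
        assert v5 == pytest.approx(v0 * 0.015 / 0.02, rel=1e-9)


class TestSingleViewVisibility:
    def test_oblique_view_bounded_by_visibility_floor(self, vga_K):
        """At 45 degrees a hemisphere's back-facing crescent is invisible to
        a single capture.  The estimate must stay below the visible-volume
        bound (numerically integrated from the visibility condition
        n.(C-p) >= 0) and recover most of it."""
        r, d = 0.05, 0.35
        th = math.radians(45.0)
        cam = np.array([0.0, -d * math.cos(th), d * math.sin(th)])
        n = 1500
        x, y = np.meshgrid(np.linspace(-r, r, n), np.linspace(-r, r, n))
        z = np.sqrt(np.maximum(r**2 - x**2 - y**2, 0.0))
        inside = x**2 + y**2 < r**2
        facing = (x * (cam[0] - x) + y * (cam[1] - y) + z * (cam[2] - z)) >= 0
        dA = (2 * r / n) ** 2
        visible_mL = float((z * (inside & facing) * dA).sum()) * 1e6
        full_mL = (2 / 3) * math.pi * r**3 * 1e6
        # the crescent hides a substantial fraction even before sampling
        assert 0.80 < visible_mL / full_mL < 0.90

        solid = FoodSolid(kind="spherical_cap", params={"r": r, "h": r}, food_id="unit")
        scene = SceneSpec(meal_type="snack", items=[solid], inclination_deg=45.0,
                          camera_distance_m=d)
        depth, labels = render_depth(scene, vga_K)
        mask = LabelMask(labels=labels.astype(np.int32), food_ids={1: "unit"})
        est = estimate_meal(depth, vga_K, mask, cfg=PipelineConfig(seed=1),
                            food_table=UNIT_FOODS)
        vol = est.items[0].volume_mL
        assert vol < visible_mL  # cannot exceed what the camera saw
        assert vol > 0.88 * visible_mL  # near-limb sampling loses the rest


class TestEstimateMeal:
    def test_snack_hemisphere_90deg(self, vga_K):
        """Noiseless nadir capture of a hemisphere recovers weight within 2%
        at unit density."""
        solid = FoodSolid(kind="spherical_cap", params={"r": 0.05, "h": 0.05},
                          food_id="unit")
        scene = SceneSpec(meal_type="snack", items=[solid], inclination_deg=90.0)
        depth, labels = render_depth(scene, vga_K)
        mask = LabelMask(labels=labels.astype(np.int32), food_ids={1: "unit"})
        est = estimate_meal(depth, vga_K, mask, cfg=PipelineConfig(seed=1),
                            food_table=UNIT_FOODS)
        expected = (2 / 3) * math.pi * 0.05**3 * 1e6
        assert est.items[0].weight_g == pytest.approx(expected, rel=0.02)

    def test_meal_totals_are_item_sums(self, small_K):
        scene = SceneSpec(
            meal_type="breakfast",
            items=[
                FoodSolid(kind="box", params={"a": 0.03, "b": 0.03, "c": 0.02},
                          position=(x, y), food_id="unit")
                for x, y in [(-0.05, -0.05), (0.05, -0.05), (-0.05, 0.05), (0.05, 0.05)]
            ],
        )
        depth, labels = render_depth(scene, small_K)
        mask = LabelMask(labels=labels.astype(np.int32),
                         food_ids={i: "unit" for i in range(1, 5)})
        est = estimate_meal(depth, small_K, mask, cfg=PipelineConfig(seed=2),
                            food_table=UNIT_FOODS)
        assert len(est.items) == 4
        assert est.weight_g == sum(it.weight_g for it in est.items)
        assert est.total("cho_g") == sum(it.cho_g for it in est.items)
        assert (np.array([it.volume_mL for it in est.items]) >= 0).all()

    def test_deterministic(self, small_K):
        solid = FoodSolid(kind="cylinder", params={"radius": 0.03, "height": 0.02},
                          food_id="unit")
        depth, labels = render_depth(SceneSpec(meal_type="snack", items=[solid]), small_K)
        mask = LabelMask(labels=labels.astype(np.int32), food_ids={1: "unit"})
        a = estimate_meal(depth, small_K, mask, cfg=PipelineConfig(seed=5), food_table=UNIT_FOODS)
        b = estimate_meal(depth, small_K, mask, cfg=PipelineConfig(seed=5), food_table=UNIT_FOODS)
        assert a.items[0].volume_mL == b.items[0].volume_mL

    def test_missing_food_id_raises(self, small_K):
        from foodvol.errors import ConfigurationError

        solid = FoodSolid(kind="box", params={"a": 0.04, "b": 0.04, "c": 0.02})
        depth, labels = render_depth(SceneSpec(meal_type="snack", items=[solid]), small_K)
        mask = LabelMask(labels=labels.astype(np.int32))
        with pytest.raises(ConfigurationError):
            estimate_meal(depth, small_K, mask, food_table=UNIT_FOODS)
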