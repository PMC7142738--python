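"""Synthetic scene generation: analytic volumes, rendering, noise, benchmark."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foodvol.depth_geometry import backproject
from foodvol.errors import ConfigurationError
from foodvol.scene_sim import (
    BenchmarkConfig,
    DishSpec,
    FoodSolid,
    NoiseParams,
    PoolEntry,
    SceneSpec,
    add_noise,
    analytic_volume,
    make_benchmark,
    monte_carlo_volume,
    render_depth,
)
from tests.conftest import surface_distance


def snack(solid, angle=90.0, distance=0.35, dish=None):
    return SceneSpec(
        meal_type="snack", items=[solid], inclination_deg=angle,
        camera_distance_m=distance, dish=dish or DishSpec(),
    )


class TestAnalyticVolume:
    @pytest.mark.parametrize(
        "kind,params,expected_mL",
        [
            ("spherical_cap", {"r": 0.05, "h": 0.05}, (2 / 3) * math.pi * 0.05**3 * 1e6),
            ("box", {"a": 0.10, "b": 0.10, "c": 0.02}, 200.0),
            ("cylinder", {"radius": 0.03, "height": 0.01}, math.pi * 9e-4 * 0.01 * 1e6),
            ("half_ellipsoid", {"a": 0.06, "b": 0.04, "c": 0.02},
             (2 / 3) * math.pi * 0.06 * 0.04 * 0.02 * 1e6),
        ],
    )
    def test_closed_forms(self, kind, params, expected_mL):
        assert analytic_volume(FoodSolid(kind=kind, params=params)) == pytest.approx(expected_mL)

    @given(s=st.floats(0.2, 4.0))
    @settings(max_examples=30, deadline=None)
    def test_cubic_scaling(self, s):
        base = FoodSolid(kind="half_ellipsoid", params={"a": 0.05, "b": 0.03, "c": 0.02})
        scaled = FoodSolid(
            kind="half_ellipsoid",
            params={k: v * s for k, v in base.params.items()},
        )
        assert analytic_volume(scaled) == pytest.approx(s**3 * analytic_volume(base))

    def test_monte_carlo_oracle_agrees(self):
        for solid in [
            FoodSolid(kind="spherical_cap", params={"r": 0.04, "h": 0.025}),
            FoodSolid(kind="cylinder", params={"radius": 0.03, "height": 0.02}),
        ]:
            mc = monte_carlo_volume(solid, n_samples=400_000, seed=9)
            assert mc == pytest.approx(analytic_volume(solid), rel=0.01)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ConfigurationError):
            FoodSolid(kind="pyramid", params={"a": 1.0})
        with pytest.raises(ConfigurationError):
            FoodSolid(kind="spherical_cap", params={"r": 0.02, "h": 0.03})
        with pytest.raises(ConfigurationError):
            FoodSolid(kind="box", params={"a": 0.1, "b": -0.1, "c": 0.1})


class TestRenderDepth:
    def test_bare_table_depth(self, small_K):
        scene = SceneSpec(
            meal_type="custom", items=[], inclination_deg=90.0,
            camera_distance_m=0.6, dish=DishSpec(rim_height=0.0),
        )
        depth, labels = render_depth(scene, small_K)
        assert depth.valid.all()
        np.testing.assert_allclose(depth.values, 0.6, atol=1e-12)
        assert (labels == 0).all()

    def test_on_axis_sphere_depth(self, small_K):
        # hemisphere tip on the optical axis: depth at the principal point is d - r
        solid = FoodSolid(kind="spherical_cap", params={"r": 0.05, "h": 0.05})
        depth, labels = render_depth(snack(solid, distance=0.5), small_K)
        assert depth.values[60, 80] == pytest.approx(0.45, abs=1e-9)
        assert labels[60, 80] == 1

    def test_all_items_visible(self, small_K):
        scene = SceneSpec(
            meal_type="cooked",
            items=[
                FoodSolid(kind="box", params={"a": 0.04, "b": 0.04, "c": 0.02},
                          position=(-0.06, 0.0)),
                FoodSolid(kind="cylinder", params={"radius": 0.02, "height": 0.02},
                          position=(0.06, 0.0)),
                FoodSolid(kind="half_ellipsoid", params={"a": 0.03, "b": 0.02, "c": 0.02},
                          position=(0.0, 0.06)),
            ],
            inclination_deg=45.0,
        )
        _, labels = render_depth(scene, small_K)
        counts = {i: int((labels == i).sum()) for i in (1, 2, 3)}
        assert all(c > 0 for c in counts.values())

    @pytest.mark.parametrize("angle", [45.0, 90.0])
    def test_mask_consistent_with_backprojected_surface(self, small_K, angle):
        """Every labeled pixel back-projects onto the labeled solid's surface."""
        solids = [
            FoodSolid(kind="box", params={"a": 0.05, "b": 0.04, "c": 0.03},
                      position=(-0.05, 0.01), yaw_deg=30.0),
            FoodSolid(kind="spherical_cap", params={"r": 0.04, "h": 0.03},
                      position=(0.05, -0.01)),
        ]
        scene = SceneSpec(meal_type="custom", items=solids, inclination_deg=angle)
        depth, labels = render_depth(scene, small_K)
        cloud = backproject(depth, small_K)
        pose = scene.camera_pose()
        world = pose.camera_to_world(cloud.points)
        lab = labels[cloud.pixel_index[:, 0], cloud.pixel_index[:, 1]]
        for i, solid in enumerate(solids, start=1):
            pts = world[lab == i]
            assert pts.size
            assert surface_distance(pts, solid).max() < 1e-6

    def test_scene_json_roundtrip(self, tmp_path):
        solid = FoodSolid(kind="box", params={"a": 0.05, "b": 0.05, "c": 0.02},
                          position=(0.01, -0.02), food_id="bread_white")
        scene = snack(solid, angle=45.0)
        scene.to_json(tmp_path / "s.json")
        back = SceneSpec.from_json(tmp_path / "s.json")
        assert dataclasses.asdict(back) == dataclasses.asdict(scene)


class TestAddNoise:
    def test_zero_noise_is_identity(self, small_K):
        depth, _ = render_depth(snack(FoodSolid(kind="box", params={"a": 0.05, "b": 0.05, "c": 0.02})), small_K)
        out = add_noise(depth, sigma0_m=0.0, sigma1_per_m=0.0, dropout_grazing_deg=90.0,
                        quant_mm=0.0, seed=1)
        np.testing.assert_array_equal(out.values, depth.values)
        np.testing.assert_array_equal(out.valid, depth.valid)

    def test_noise_law_sd(self):
        from foodvol.depth_geometry import DepthMap

        depth = DepthMap(values=np.full((320, 320), 0.6))
        out = add_noise(depth, sigma0_m=0.001, sigma1_per_m=0.0, quant_mm=0.0, seed=3)
        sd = (out.values - 0.6).std()
        assert sd == pytest.approx(0.001, rel=0.05)

    def test_quantization_to_integer_mm(self):
        from foodvol.depth_geometry import DepthMap

        depth = DepthMap(values=np.random.default_rng(0).uniform(0.3, 0.8, (50, 50)))
        out = add_noise(depth, sigma0_m=0.0, sigma1_per_m=0.0, quant_mm=1.0, seed=0)
        mm = out.values[out.valid] * 1000
        np.testing.assert_allclose(mm, np.round(mm), atol=1e-9)

    def test_grazing_dropout(self, small_K):
        # a tall box viewed at 45 deg has near-grazing side surfaces
        solid = FoodSolid(kind="box", params={"a": 0.06, "b": 0.06, "c": 0.05})
        depth, _ = render_depth(snack(solid, angle=45.0), small_K)
        out = add_noise(depth, sigma0_m=0.0, sigma1_per_m=0.0,
                        dropout_grazing_deg=60.0, quant_mm=0.0, seed=0, K=small_K)
        assert out.n_valid < depth.n_valid

    def test_deterministic_per_seed(self):
        from foodvol.depth_geometry import DepthMap

        depth = DepthMap(values=np.full((40, 40), 0.5))
        a = add_noise(depth, seed=11)
        b = add_noise(depth, seed=11)
        c = add_noise(depth, seed=12)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


class TestMakeBenchmark:
    def test_composition_and_angle_balance(self):
        meals = make_benchmark(12, seed=5)
        by_type: dict = {}
        for scene, gt in meals:
            by_type.setdefault(scene.meal_type, []).append(scene)
            assert len(scene.items) == {"breakfast": 4, "cooked": 3, "snack": 1}[scene.meal_type]
            assert set(gt.volumes_mL) == set(gt.food_ids)
        assert {t: len(v) for t, v in by_type.items()} == {
            "breakfast": 4, "cooked": 4, "snack": 4
        }
        for scenes in by_type.values():
            angles = [s.inclination_deg for s in scenes]
            assert angles.count(45.0) == angles.count(90.0) == 2

    def test_seed_determinism(self):
        a = make_benchmark(6, seed=3)
        b = make_benchmark(6, seed=3)
        for (sa, ga), (sb, gb) in zip(a, b):
            assert dataclasses.asdict(sa) == dataclasses.asdict(sb)
            assert np.array_equal(ga.label_mask, gb.label_mask)
            assert ga.volumes_mL == gb.volumes_mL

    def test_snack_only_config(self):
        cfg = BenchmarkConfig(meal_types=("snack",))
        meals = make_benchmark(6, seed=1, config=cfg)
        assert len(meals) == 6
        assert all(len(s.items) == 1 for s, _ in meals)

    def test_ground_truth_weights_follow_density(self):
        from foodvol.nutrient_db import load_food_table

        table = load_food_table()
        for scene, gt in make_benchmark(3, seed=2):
            for lab, vol in gt.volumes_mL.items():
                rho = table[gt.food_ids[lab]].density_g_per_ml
                assert gt.weights_g[lab] == pytest.approx(vol * rho)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            make_benchmark(7, seed=0)  # not divisible by 3 meal types
        with pytest.raises(ConfigurationError):
            make_benchmark(6, seed=0, config=BenchmarkConfig(pool=[]))

    def test_items_disjoint_on_plate(self):
        """Radial layout keeps item footprints separated and on the plate."""
        for scene, _ in make_benchmark(12, seed=8):
            items = scene.items
            for i, a in enumerate(items):
                assert math.hypot(*a.position) + a.footprint_radius() <= scene.dish.radius + 1e-9
                for b in items[i + 1:]:
                    gap = math.hypot(a.position[0] - b.position[0],
                                     a.position[1] - b.position[1])
                    assert gap > a.footprint_radius() + b.footprint_radius()
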