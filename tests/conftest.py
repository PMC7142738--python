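import time

import numpy as np
import pytest

from foodvol import CameraIntrinsics
from foodvol.benchmark import run_benchmark
from foodvol.scene_sim import NoiseParams


@pytest.fixture(scope="session")
def small_K() -> CameraIntrinsics:
    """Low-resolution intrinsics for fast unit-test renders."""
    return CameraIntrinsics(fx=150.0, fy=150.0, cx=80.0, cy=60.0, width=160, height=120)


@pytest.fixture(scope="session")
def vga_K() -> CameraIntrinsics:
    """Close-range VGA intrinsics used for the primitive-recovery scenes."""
    return CameraIntrinsics(fx=600.0, fy=600.0, cx=319.5, cy=239.5, width=640, height=480)


@pytest.fixture(scope="session")
def bench48_noiseless():
    """The 48-meal noiseless synthetic benchmark run end to end (shared:
    it is the costliest fixture in the suite)."""
    t0 = time.perf_counter()
    res = run_benchmark(n_meals=48, seed=0, noise=None)
    res.elapsed_s = time.perf_counter() - t0
    return res


@pytest.fixture(scope="session")
def bench48_noisy():
    """Same benchmark with the default sensor-noise model enabled."""
    return run_benchmark(n_meals=48, seed=0, noise=NoiseParams())


def surface_distance(points: np.ndarray, solid) -> np.ndarray:
    """Distance from world-frame points to a solid's bounding surface
    (analytic, independent of the ray caster), for mask/render consistency."""
    import math

    p = solid.params
    x = points[:, 0] - solid.position[0]
    y = points[:, 1] - solid.position[1]
    z = points[:, 2] - solid.base_z
    th = math.radians(-solid.yaw_deg)
    xr = x * math.cos(th) - y * math.sin(th)
    yr = x * math.sin(th) + y * math.cos(th)
    if solid.kind == "spherical_cap":
        return np.abs(np.sqrt(xr**2 + yr**2 + (z - (p["h"] - p["r"])) ** 2) - p["r"])
    if solid.kind == "box":
        dx = np.abs(xr) - p["a"] / 2
        dy = np.abs(yr) - p["b"] / 2
        dz = np.maximum(z - p["c"], -z)
        return np.abs(np.maximum.reduce([dx, dy, dz]))
    if solid.kind == "cylinder":
        d_side = np.abs(np.sqrt(xr**2 + yr**2) - p["radius"])
        d_top = np.abs(z - p["height"])
        return np.minimum(d_side, d_top)
    # half_ellipsoid: implicit-function residual scaled by the gradient norm
    f = (xr / p["a"]) ** 2 + (yr / p["b"]) ** 2 + (z / p["c"]) ** 2 - 1.0
    g = 2 * np.sqrt(
        (xr / p["a"] ** 2) ** 2 + (yr / p["b"] ** 2) ** 2 + (z / p["c"] ** 2) ** 2
    )
    return np.abs(f) / np.maximum(g, 1e-12)
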