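"""Synthetic depth-scene simulator.

Generates meals of parametric food solids (spherical caps, boxes, cylinders,
half-ellipsoids) resting on a plate on a table, renders them to a z-depth
map by per-pixel ray casting, optionally corrupts the depth with a
structured-light-style noise model, and produces ground truth (analytic
volumes, label masks, true table plane) so the whole quantification
pipeline can be evaluated without camera hardware.

World frame: the table is the plane z=0 with +z up; the camera sits at a
configurable distance and inclination (45 deg or 90 deg from horizontal)
looking at the table center.  Rendered depths are z-depths in the camera
frame, matching :mod:`foodvol.depth_geometry` conventions.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .depth_geometry import CameraIntrinsics, DepthMap, Plane
from .errors import ConfigurationError, RenderError

__all__ = [
    "FoodSolid",
    "DishSpec",
    "NoiseParams",
    "CameraPose",
    "SceneSpec",
    "GroundTruth",
    "analytic_volume",
    "monte_carlo_volume",
    "render_depth",
    "add_noise",
    "make_benchmark",
    "BenchmarkConfig",
    "PoolEntry",
    "DEFAULT_POOL",
    "MEAL_ITEM_COUNTS",
]

MEAL_ITEM_COUNTS = {"breakfast": 4, "cooked": 3, "snack": 1}

_KINDS = ("spherical_cap", "box", "cylinder", "half_ellipsoid")


@dataclass
class FoodSolid:
    """A parametric food item resting on the support surface.

    Shape parameters (meters) by kind:

    * ``spherical_cap``: ``{"r": sphere radius, "h": cap height}`` (h <= r)
    * ``box``: ``{"a", "b", "c"}`` (footprint a x b, height c)
    * ``cylinder``: ``{"radius", "height"}`` (vertical axis)
    * ``half_ellipsoid``: ``{"a", "b", "c"}`` (semi-axes; c vertical)

    ``position`` is (x, y) on the table plane, ``yaw_deg`` the rotation
    about the table normal, ``base_z`` the height of the support surface
    the solid rests on (0 = bare table).
    """

    kind: str
    params: dict[str, float]
    position: tuple[float, float] = (0.0, 0.0)
    yaw_deg: float = 0.0
    food_id: str = "unspecified"
    base_z: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown solid kind {self.kind!r}")
        if any(v <= 0 for v in self.params.values()):
            raise ConfigurationError("all shape parameters must be positive")
        if self.kind == "spherical_cap" and self.params["h"] > self.params["r"] + 1e-12:
            raise ConfigurationError("cap height must not exceed sphere radius")

    @property
    def top_z(self) -> float:
        heights = {
            "spherical_cap": lambda p: p["h"],
            "box": lambda p: p["c"],
            "cylinder": lambda p: p["height"],
            "half_ellipsoid": lambda p: p["c"],
        }
        return self.base_z + heights[self.kind](self.params)

    def footprint_radius(self) -> float:
        """Radius of the smallest vertical cylinder containing the solid."""
        p = self.params
        if self.kind == "spherical_cap":
            # base circle of the cap (h <= r so the widest section is the base)
            return math.sqrt(max(p["h"] * (2 * p["r"] - p["h"]), 0.0))
        if self.kind == "box":
            return math.hypot(p["a"] / 2, p["b"] / 2)
        if self.kind == "cylinder":
            return p["radius"]
        return max(p["a"], p["b"])


def analytic_volume(solid: FoodSolid) -> float:
    """Closed-form volume of a solid in mL (1 m^3 = 1e6 mL)."""
    p = solid.params
    if solid.kind == "spherical_cap":
        v = math.pi * p["h"] ** 2 * (3 * p["r"] - p["h"]) / 3.0
    elif solid.kind == "box":
        v = p["a"] * p["b"] * p["c"]
    elif solid.kind == "cylinder":
        v = math.pi * p["radius"] ** 2 * p["height"]
    elif solid.kind == "half_ellipsoid":
        v = (2.0 / 3.0) * math.pi * p["a"] * p["b"] * p["c"]
    else:  # pragma: no cover - guarded in FoodSolid
        raise ConfigurationError(f"unknown solid kind {solid.kind!r}")
    return v * 1e6


def monte_carlo_volume(solid: FoodSolid, n_samples: int = 1_000_000, seed: int = 0) -> float:
    """Rejection-sampling volume oracle in mL.

    Samples uniformly in the solid's bounding box and counts membership via
    the defining inequalities — an estimate independent of both the
    closed-form volumes and the surface-integration pipeline, used to
    cross-check them.
    """
    rng = np.random.default_rng(seed)
    p = solid.params
    if solid.kind == "spherical_cap":
        rho = solid.footprint_radius()
        lo = np.array([-rho, -rho, 0.0])
        hi = np.array([rho, rho, p["h"]])
        cz = p["h"] - p["r"]

        def member(x, y, z):
            return x * x + y * y + (z - cz) ** 2 <= p["r"] ** 2
    elif solid.kind == "box":
        lo = np.array([-p["a"] / 2, -p["b"] / 2, 0.0])
        hi = np.array([p["a"] / 2, p["b"] / 2, p["c"]])

        def member(x, y, z):
            return np.ones_like(x, dtype=bool)
    elif solid.kind == "cylinder":
        r = p["radius"]
        lo = np.array([-r, -r, 0.0])
        hi = np.array([r, r, p["height"]])

        def member(x, y, z):
            return x * x + y * y <= r * r
    else:
        lo = np.array([-p["a"], -p["b"], 0.0])
        hi = np.array([p["a"], p["b"], p["c"]])

        def member(x, y, z):
            return (x / p["a"]) ** 2 + (y / p["b"]) ** 2 + (z / p["c"]) ** 2 <= 1.0

    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    inside = member(pts[:, 0], pts[:, 1], pts[:, 2])
    box_vol = float(np.prod(hi - lo))
    return box_vol * float(np.count_nonzero(inside)) / n_samples * 1e6


@dataclass
class DishSpec:
    """Dish the meal is served on, described in the table frame.

    ``flat_plate``: a disk of ``radius`` at ``offset`` above the table with
    a short vertical rim of ``rim_height`` at its edge.  ``bowl``: a
    spherical-cap interior of ``bowl_radius`` (sphere radius) and ``depth``
    (rim height above the bowl bottom).
    """

    kind: str = "flat_plate"
    radius: float = 0.12
    rim_height: float = 0.01
    offset: float = 0.0
    bowl_radius: float = 0.10
    depth: float = 0.04

    def __post_init__(self) -> None:
        if self.kind not in ("flat_plate", "bowl"):
            raise ConfigurationError(f"unknown dish kind {self.kind!r}")
        if self.kind == "bowl" and self.depth > self.bowl_radius:
            raise ConfigurationError("bowl depth cannot exceed its sphere radius")
        if self.offset < 0:
            raise ConfigurationError("dish surface cannot lie below the table")


@dataclass
class NoiseParams:
    """Structured-light-style depth noise.

    Gaussian depth error sigma(z) = sigma0 + sigma1 * z^2, pixel dropout at
    grazing incidence, and millimeter quantization (depth sensors report
    integer-ish depths).
    """

    sigma0_m: float = 0.0005
    sigma1_per_m: float = 0.003
    dropout_grazing_deg: float = 80.0
    quant_mm: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sigma0_m, self.sigma1_per_m, self.quant_mm) < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        if not (0 < self.dropout_grazing_deg <= 90):
            raise ConfigurationError("dropout angle must be in (0, 90] degrees")


@dataclass(frozen=True)
class CameraPose:
    """Rigid world->camera transform.  ``rotation`` columns are the camera
    axes expressed in world coordinates; ``position`` is the camera center."""

    position: np.ndarray
    rotation: np.ndarray

    def world_to_camera(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.position) @ self.rotation

    def camera_to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.position

    def table_plane_in_camera(self) -> Plane:
        """The true table plane (world z=0) expressed in the camera frame."""
        n_cam = self.rotation.T @ np.array([0.0, 0.0, 1.0])
        p_cam = self.world_to_camera(np.zeros(3))
        return Plane.from_vector(n_cam, float(n_cam @ p_cam))


def _camera_pose(inclination_deg: float, distance_m: float) -> CameraPose:
    """Camera at ``distance_m`` from the table center, elevated by the
    inclination angle from horizontal (90 = straight down), looking at the
    center.  +y (image down) points away from the camera's ground position."""
    th = math.radians(inclination_deg)
    pos = np.array([0.0, -distance_m * math.cos(th), distance_m * math.sin(th)])
    z_cam = -pos / np.linalg.norm(pos)  # toward the table center
    x_cam = np.array([1.0, 0.0, 0.0])
    y_cam = np.cross(z_cam, x_cam)
    y_cam /= np.linalg.norm(y_cam)
    return CameraPose(position=pos, rotation=np.column_stack([x_cam, y_cam, z_cam]))


@dataclass
class SceneSpec:
    """A complete synthetic meal scene."""

    meal_type: str
    items: list[FoodSolid]
    dish: DishSpec = field(default_factory=DishSpec)
    inclination_deg: float = 90.0
    camera_distance_m: float = 0.35
    noise: NoiseParams | None = None
    seed: int = 0
    meal_id: str = "meal"

    def __post_init__(self) -> None:
        if self.meal_type not in MEAL_ITEM_COUNTS and self.meal_type != "custom":
            raise ConfigurationError(f"unknown meal type {self.meal_type!r}")
        expected = MEAL_ITEM_COUNTS.get(self.meal_type)
        if expected is not None and len(self.items) != expected:
            raise ConfigurationError(
                f"{self.meal_type} meals must have {expected} items, "
                f"got {len(self.items)}"
            )
        if self.inclination_deg not in (45.0, 90.0):
            raise ConfigurationError("inclination must be 45 or 90 degrees")

    def camera_pose(self) -> CameraPose:
        return _camera_pose(self.inclination_deg, self.camera_distance_m)

    def to_json(self, path: str | Path) -> None:
        def _clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        Path(path).write_text(json.dumps(_clean(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneSpec":
        raw = json.loads(Path(path).read_text())
        raw["items"] = [
            FoodSolid(**{**it, "position": tuple(it["position"])})
            for it in raw["items"]
        ]
        raw["dish"] = DishSpec(**raw["dish"])
        if raw.get("noise") is not None:
            raw["noise"] = NoiseParams(**raw["noise"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Reference values for a scene, playing the role of the precision scale."""

    volumes_mL: dict[int, float]          # item label -> analytic volume
    food_ids: dict[int, str]              # item label -> food id
    label_mask: np.ndarray                # noiseless render labels
    table_plane: Plane                    # true table plane, camera frame
    weights_g: dict[int, float] = field(default_factory=dict)
    macros: dict[int, dict[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------


def _ray_plane_z(origin: np.ndarray, dirs: np.ndarray, z0: float) -> np.ndarray:
    """t for intersection with the horizontal plane z=z0 (inf if none ahead)."""
    dz = dirs[:, 2]
    t = np.full(len(dirs), np.inf)
    moving = np.abs(dz) > 1e-15
    t[moving] = (z0 - origin[2]) / dz[moving]
    t[t <= 0] = np.inf
    return t


def _ray_sphere(
    origin: np.ndarray, dirs: np.ndarray, center: np.ndarray, radius: float,
    zmin: float, zmax: float,
) -> np.ndarray:
    """Nearest positive t on a sphere restricted to z in [zmin, zmax]."""
    oc = origin - center
    a = np.einsum("ij,ij->i", dirs, dirs)
    b = 2.0 * dirs @ oc
    c = oc @ oc - radius * radius
    disc = b * b - 4 * a * c
    t = np.full(len(dirs), np.inf)
    ok = disc >= 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    for sign in (-1.0, 1.0):  # near root first; far root fills where near is cut away
        tc = (-b + sign * sq) / (2 * a)
        z = origin[2] + tc * dirs[:, 2]
        good = ok & (tc > 1e-9) & (z >= zmin - 1e-12) & (z <= zmax + 1e-12)
        t = np.where(good & (tc < t), tc, t)
    return t

def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ray_box(
    origin: np.ndarray, dirs: np.ndarray, solid: FoodSolid
) -> np.ndarray:
    p = solid.params
    R = _rot_z(-solid.yaw_deg)
    o = R @ (origin - np.array([*solid.position, solid.base_z]))
    d = dirs @ R.T
    lo = np.array([-p["a"] / 2, -p["b"] / 2, 0.0])
    hi = np.array([p["a"] / 2, p["b"] / 2, p["c"]])
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - o) / d
        t2 = (hi - o) / d
    tnear = np.nanmax(np.minimum(t1, t2), axis=1)
    tfar = np.nanmin(np.maximum(t1, t2), axis=1)
    t = np.where((tnear <= tfar) & (tfar > 0), np.where(tnear > 1e-9, tnear, tfar), np.inf)
    t[t <= 1e-9] = np.inf
    return t


def _cylinder_side(
    origin: np.ndarray,
    dirs: np.ndarray,
    center_xy: tuple[float, float],
    radius: float,
    z0: float,
    z1: float,
) -> np.ndarray:
    """Nearest positive t on the lateral surface of a vertical cylinder."""
    ox, oy = origin[0] - center_xy[0], origin[1] - center_xy[1]
    dx, dy = dirs[:, 0], dirs[:, 1]
    a = dx * dx + dy * dy
    b = 2 * (ox * dx + oy * dy)
    c = ox * ox + oy * oy - radius * radius
    disc = b * b - 4 * a * c
    t = np.full(len(dirs), np.inf)
    ok = (disc >= 0) & (a > 1e-15)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    for sign in (-1.0, 1.0):
        tc = np.where(ok, (-b + sign * sq) / (2 * np.where(a > 1e-15, a, 1.0)), np.inf)
        z = origin[2] + tc * dirs[:, 2]
        good = ok & (tc > 1e-9) & (z >= z0 - 1e-12) & (z <= z1 + 1e-12)
        t = np.where(good & (tc < t), tc, t)
    return t


def _ray_cylinder(
    origin: np.ndarray, dirs: np.ndarray, solid: FoodSolid
) -> np.ndarray:
    p = solid.params
    cx, cy = solid.position
    z0, z1 = solid.base_z, solid.base_z + p["height"]
    ox, oy = origin[0] - cx, origin[1] - cy
    dx, dy = dirs[:, 0], dirs[:, 1]
    a = dx * dx + dy * dy
    b = 2 * (ox * dx + oy * dy)
    c = ox * ox + oy * oy - p["radius"] ** 2
    disc = b * b - 4 * a * c
    t = np.full(len(dirs), np.inf)
    ok = (disc >= 0) & (a > 1e-15)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    for sign in (-1.0, 1.0):
        tc = np.where(ok, (-b + sign * sq) / (2 * np.where(a > 1e-15, a, 1.0)), np.inf)
        z = origin[2] + tc * dirs[:, 2]
        good = ok & (tc > 1e-9) & (z >= z0 - 1e-12) & (z <= z1 + 1e-12)
        t = np.where(good & (tc < t), tc, t)
    # top cap
    tc = _ray_plane_z(origin, dirs, z1)
    hx = origin[0] + tc * dirs[:, 0] - cx
    hy = origin[1] + tc * dirs[:, 1] - cy
    good = np.isfinite(tc) & (hx * hx + hy * hy <= p["radius"] ** 2)
    t = np.where(good & (tc < t), tc, t)
    return t


def _ray_half_ellipsoid(
    origin: np.ndarray, dirs: np.ndarray, solid: FoodSolid
) -> np.ndarray:
    p = solid.params
    R = _rot_z(-solid.yaw_deg)
    o = R @ (origin - np.array([*solid.position, solid.base_z]))
    d = dirs @ R.T
    scale = np.array([p["a"], p["b"], p["c"]])
    os_, ds = o / scale, d / scale
    a = np.einsum("ij,ij->i", ds, ds)
    b = 2.0 * ds @ os_
    c = os_ @ os_ - 1.0
    disc = b * b - 4 * a * c
    t = np.full(len(dirs), np.inf)
    ok = disc >= 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    for sign in (-1.0, 1.0):
        tc = (-b + sign * sq) / (2 * a)
        z = o[2] + tc * d[:, 2]
        good = ok & (tc > 1e-9) & (z >= -1e-12)
        t = np.where(good & (tc < t), tc, t)
    return t


def _ray_solid(origin: np.ndarray, dirs: np.ndarray, solid: FoodSolid) -> np.ndarray:
    if solid.kind == "spherical_cap":
        p = solid.params
        center = np.array([*solid.position, solid.base_z + p["h"] - p["r"]])
        return _ray_sphere(
            origin, dirs, center, p["r"], solid.base_z, solid.base_z + p["h"]
        )
    if solid.kind == "box":
        return _ray_box(origin, dirs, solid)
    if solid.kind == "cylinder":
        return _ray_cylinder(origin, dirs, solid)
    return _ray_half_ellipsoid(origin, dirs, solid)


def _ray_dish(origin: np.ndarray, dirs: np.ndarray, dish: DishSpec) -> np.ndarray:
    """Dish surface hits (labelled background, like the table)."""
    t = np.full(len(dirs), np.inf)
    if dish.kind == "flat_plate":
        if dish.offset > 0:
            tc = _ray_plane_z(origin, dirs, dish.offset)
            h = origin[None, :2] + tc[:, None] * dirs[:, :2]
            good = np.isfinite(tc) & (np.einsum("ij,ij->i", h, h) <= dish.radius**2)
            t = np.where(good & (tc < t), tc, t)
        # rim: a thin vertical wall (side surface only) at the plate edge
        tc = _cylinder_side(
            origin, dirs, (0.0, 0.0), dish.radius, 0.0, dish.offset + dish.rim_height
        )
        t = np.minimum(t, tc)
    else:  # bowl: interior spherical cap, bottom touching the table at z=0
        center = np.array([0.0, 0.0, dish.bowl_radius])
        tc = _ray_sphere(origin, dirs, center, dish.bowl_radius, 0.0, dish.depth)
        t = np.minimum(t, tc)
    return t


def render_depth(
    scene: SceneSpec, K: CameraIntrinsics, max_range_m: float = 5.0
) -> tuple[DepthMap, np.ndarray]:
    """Ray-cast the scene to a z-depth map and an item label mask.

    The label mask holds the 1-based item index of the nearest hit per
    pixel (0 = background: table, dish, or no return).  Noise is **not**
    applied here; pass the result through :func:`add_noise`.
    """
    pose = scene.camera_pose()
    u, v = np.meshgrid(np.arange(K.width), np.arange(K.height))
    dirs_cam = np.column_stack(
        [
            (u.ravel() - K.cx) / K.fx,
            (v.ravel() - K.cy) / K.fy,
            np.ones(u.size),
        ]
    )
    dirs_world = dirs_cam @ pose.rotation.T  # t along these rays IS z-depth
    origin = pose.position

    t_best = _ray_plane_z(origin, dirs_world, 0.0)  # table
    labels = np.zeros(u.size, dtype=np.uint8)
    t_dish = _ray_dish(origin, dirs_world, scene.dish)
    t_best = np.minimum(t_best, t_dish)
    for i, solid in enumerate(scene.items, start=1):
        t_i = _ray_solid(origin, dirs_world, solid)
        closer = t_i < t_best
        t_best = np.where(closer, t_i, t_best)
        labels = np.where(closer, np.uint8(i), labels)

    depth_vals = t_best.reshape(K.height, K.width)
    valid = np.isfinite(depth_vals) & (depth_vals < max_range_m)
    if not valid.any():
        raise RenderError("no scene geometry inside the camera frustum")
    labels = labels.reshape(K.height, K.width)
    labels[~valid] = 0
    depth = DepthMap(
        values=np.where(valid, depth_vals, 0.0), valid=valid, max_range_m=max_range_m
    )
    return depth, labels


# ---------------------------------------------------------------------------
# sensor noise
# ---------------------------------------------------------------------------


def _incidence_angles(depth: DepthMap, K: CameraIntrinsics) -> np.ndarray:
    """Per-pixel angle (deg) between the viewing ray and the local surface
    normal, estimated by finite differences of the back-projected grid."""
    h, w = depth.shape
    u, v = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    z = np.where(depth.valid, depth.values, np.nan)
    X = (u - K.cx) * z / K.fx
    Y = (v - K.cy) * z / K.fy
    P = np.stack([X, Y, z], axis=-1)
    dPdv, dPdu = np.gradient(P, axis=(0, 1))
    n = np.cross(dPdu.reshape(-1, 3), dPdv.reshape(-1, 3)).reshape(h, w, 3)
    nn = np.linalg.norm(n, axis=-1)
    rays = np.stack([(u - K.cx) / K.fx, (v - K.cy) / K.fy, np.ones_like(u)], axis=-1)
    rn = np.linalg.norm(rays, axis=-1)
    cosang = np.abs(np.einsum("ijk,ijk->ij", n, rays)) / np.where(
        nn * rn > 0, nn * rn, 1.0
    )
    ang = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    ang[~np.isfinite(ang) | (nn == 0)] = 0.0
    return ang


def add_noise(
    depth: DepthMap,
    sigma0_m: float = 0.0005,
    sigma1_per_m: float = 0.003,
    dropout_grazing_deg: float = 80.0,
    quant_mm: float = 1.0,
    seed: int = 0,
    K: CameraIntrinsics | None = None,
) -> DepthMap:
    """Apply the structured-light noise model to a clean depth map.

    Per-pixel Gaussian depth error with sigma(z) = sigma0 + sigma1 * z^2,
    dropout of pixels whose viewing-ray incidence on the local surface
    exceeds ``dropout_grazing_deg`` (grazing surfaces return no signal),
    then quantization to ``quant_mm`` millimeters.  Incidence dropout needs
    intrinsics; it is skipped when ``K`` is None.  Deterministic per seed.
    """
    if min(sigma0_m, sigma1_per_m, quant_mm) < 0 or not (0 < dropout_grazing_deg <= 90):
        raise ConfigurationError("invalid noise parameters")
    rng = np.random.default_rng(seed)
    values = depth.values.copy()
    valid = depth.valid.copy()
    sigma = sigma0_m + sigma1_per_m * values**2
    noise = rng.normal(0.0, 1.0, size=values.shape) * sigma
    values = np.where(valid, values + noise, values)
    if K is not None and dropout_grazing_deg < 90.0:
        angles = _incidence_angles(depth, K)
        valid &= angles <= dropout_grazing_deg
    if quant_mm > 0:
        q = quant_mm / 1000.0
        values = np.round(values / q) * q
    values = np.where(valid, values, 0.0)
    return DepthMap(values=values, valid=valid, max_range_m=depth.max_range_m)


# ---------------------------------------------------------------------------
# benchmark generation
# ---------------------------------------------------------------------------


@dataclass
class PoolEntry:
    """One food in the item pool: a shape family plus realistic size ranges
    (meters) and the food id used for density/composition lookup."""

    kind: str
    food_id: str
    ranges: dict[str, tuple[float, float]]

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        params = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in self.ranges.items()}
        if self.kind == "spherical_cap":
            # h sampled as a fraction of r keeps caps shallow (food mounds)
            params["h"] = params["r"] * params.pop("h_frac")
        return params


# Portion-sized primitives; domes kept shallow (h/r, c/min(a,b) well below 1)
# because single-view capture cannot see the lower back of a steep dome.
DEFAULT_POOL: list[PoolEntry] = [
    PoolEntry("spherical_cap", "rice_cooked", {"r": (0.035, 0.045), "h_frac": (0.4, 0.7)}),
    PoolEntry("spherical_cap", "mashed_potato", {"r": (0.03, 0.045), "h_frac": (0.4, 0.75)}),
    PoolEntry("box", "bread_white", {"a": (0.04, 0.06), "b": (0.04, 0.06), "c": (0.012, 0.025)}),
    PoolEntry("box", "cheese_hard", {"a": (0.03, 0.05), "b": (0.03, 0.05), "c": (0.01, 0.02)}),
    PoolEntry("box", "cake_sponge", {"a": (0.04, 0.06), "b": (0.04, 0.06), "c": (0.02, 0.03)}),
    PoolEntry("cylinder", "beef_patty", {"radius": (0.025, 0.04), "height": (0.012, 0.022)}),
    PoolEntry("cylinder", "pancake", {"radius": (0.03, 0.042), "height": (0.008, 0.015)}),
    PoolEntry("half_ellipsoid", "chicken_breast", {"a": (0.035, 0.045), "b": (0.025, 0.035), "c": (0.014, 0.022)}),
    PoolEntry("half_ellipsoid", "potato_boiled", {"a": (0.03, 0.04), "b": (0.022, 0.032), "c": (0.015, 0.025)}),
    PoolEntry("half_ellipsoid", "apple_half", {"a": (0.03, 0.038), "b": (0.03, 0.038), "c": (0.018, 0.026)}),
]


@dataclass
class BenchmarkConfig:
    """Study-design configuration for the synthetic benchmark.

    Defaults mirror the evaluated study conditions: equal thirds of
    breakfasts (4 items), cooked meals (3 items) and snacks (1 item);
    capture at 45 or 90 degrees assigned by a balanced randomized binary
    sequence within each meal-type batch.
    """

    meal_types: tuple[str, ...] = ("breakfast", "cooked", "snack")
    pool: list[PoolEntry] = field(default_factory=lambda: list(DEFAULT_POOL))
    dish: DishSpec = field(default_factory=DishSpec)
    camera_distance_m: float = 0.40
    noise: NoiseParams | None = None
    # radial item layouts keep items disjoint on the plate (meal-count -> radius)
    layout_radius_m: dict[int, float] = field(
        default_factory=lambda: {1: 0.0, 3: 0.065, 4: 0.068}
    )


_HORIZONTAL_PARAMS = {
    "spherical_cap": ("r", "h"),  # scale h with r so the cap shape stays valid
    "box": ("a", "b"),
    "cylinder": ("radius",),
    "half_ellipsoid": ("a", "b"),
}


def _place_items(
    entries: list[PoolEntry], rng: np.random.Generator, cfg: BenchmarkConfig
) -> list[FoodSolid]:
    n = len(entries)
    radius = cfg.layout_radius_m[n]
    jitter_max = 0.003 if n > 1 else 0.0
    # worst-case center distance between adjacent layout slots; footprints
    # must fit inside half of it so solids never intersect (ground-truth
    # volumes assume disjoint solids)
    if n > 1:
        min_gap = 2 * radius * math.sin(math.pi / n) - 2 * jitter_max * math.sqrt(2)
        max_footprint = min_gap / 2 * 0.999
    else:
        max_footprint = math.inf
    phase = float(rng.uniform(0, 360))
    items = []
    for i, entry in enumerate(entries):
        ang = math.radians(phase + 360.0 * i / n)
        jitter = rng.uniform(-jitter_max, jitter_max, size=2) if n > 1 else np.zeros(2)
        pos = (
            radius * math.cos(ang) + float(jitter[0]),
            radius * math.sin(ang) + float(jitter[1]),
        )
        solid = FoodSolid(
            kind=entry.kind,
            params=entry.sample(rng),
            position=pos,
            yaw_deg=float(rng.uniform(0, 360)),
            food_id=entry.food_id,
            base_z=cfg.dish.offset,
        )
        fp = solid.footprint_radius()
        if fp > max_footprint:
            scale = max_footprint / fp
            for key in _HORIZONTAL_PARAMS[solid.kind]:
                solid.params[key] *= scale
        items.append(solid)
    return items


def _balanced_angles(n: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced randomized binary sequence of 45/90 captures (half each,
    +-1 when n is odd)."""
    angles = np.array([45.0] * (n // 2) + [90.0] * (n - n // 2))
    if n % 2 == 1 and rng.integers(2) == 0:
        angles = angles[::-1].copy()
    rng.shuffle(angles)
    return angles


def make_benchmark(
    n_meals: int = 48,
    seed: int = 0,
    config: BenchmarkConfig | None = None,
    K: CameraIntrinsics | None = None,
    food_table=None,
) -> list[tuple[SceneSpec, GroundTruth]]:
    """Generate the synthetic meal benchmark.

    ``n_meals`` is split equally across meal types (must divide evenly);
    within each meal-type batch, capture angles follow a balanced
    randomized 45/90 sequence.  Fully reproducible from ``seed``.  Ground
    truth holds analytic volumes, the noiseless label mask, the true table
    plane and (when a food table is supplied) true weights and macros.
    """
    from .nutrient_db import load_food_table, volume_to_weight, weight_to_macros

    cfg = config or BenchmarkConfig()
    if not cfg.pool:
        raise ConfigurationError("item pool is empty")
    n_types = len(cfg.meal_types)
    if n_meals < n_types or n_meals % n_types != 0:
        raise ConfigurationError(
            f"n_meals must be a positive multiple of {n_types}"
        )
    if K is None:
        K = CameraIntrinsics(fx=450.0, fy=450.0, cx=239.5, cy=179.5, width=480, height=360)
    if food_table is None:
        food_table = load_food_table()

    rng = np.random.default_rng(seed)
    per_batch = n_meals // n_types
    out: list[tuple[SceneSpec, GroundTruth]] = []
    for meal_type in cfg.meal_types:
        angles = _balanced_angles(per_batch, rng)
        for j in range(per_batch):
            n_items = MEAL_ITEM_COUNTS[meal_type]
            picks = rng.choice(len(cfg.pool), size=n_items, replace=False)
            entries = [cfg.pool[int(p)] for p in picks]
            items = _place_items(entries, rng, cfg)
            scene = SceneSpec(
                meal_type=meal_type,
                items=items,
                dish=cfg.dish,
                inclination_deg=float(angles[j]),
                camera_distance_m=cfg.camera_distance_m,
                noise=cfg.noise,
                seed=int(rng.integers(2**31)),
                meal_id=f"{meal_type}_{j:03d}",
            )
            _, mask = render_depth(scene, K)
            volumes = {i: analytic_volume(s) for i, s in enumerate(items, start=1)}
            food_ids = {i: s.food_id for i, s in enumerate(items, start=1)}
            weights, macros = {}, {}
            for lab, vol in volumes.items():
                rec = food_table[food_ids[lab]]
                w = volume_to_weight(vol, rec)
                weights[lab] = w
                cho, protein, fat, kcal = weight_to_macros(w, rec)
                macros[lab] = {
                    "cho_g": cho, "protein_g": protein, "fat_g": fat, "kcal": kcal
                }
            out.append(
                (
                    scene,
                    GroundTruth(
                        volumes_mL=volumes,
                        food_ids=food_ids,
                        label_mask=mask,
                        table_plane=scene.camera_pose().table_plane_in_camera(),
                        weights_g=weights,
                        macros=macros,
                    ),
                )
            )
    return out
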