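"""Camera model, depth-map back-projection, robust table-plane extraction
and visible-surface triangulation.

Conventions
-----------
* Depths are **z-depths**: distance along the optical axis, not ray length.
* Camera frame is right-handed: +x right, +y down (image convention),
  +z into the scene; the camera sits at the origin.
* Plane normals are unit vectors canonicalized to point **toward the
  camera**, i.e. ``normal . (0,0,-1) >= 0``.  For a table seen from above
  this makes ``n.p - d`` the signed height of a point above the table.
* All geometry is in meters; volumes are reported in mL downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.spatial import Delaunay, QhullError

from .errors import (
    ConfigurationError,
    EmptyCloudError,
    PlaneFitError,
    TriangulationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CameraIntrinsics",
    "DepthMap",
    "PointCloud",
    "Plane",
    "TriMesh",
    "backproject",
    "ransac_plane",
    "triangulate_surface",
    "default_max_edge",
    "load_depth_png",
    "save_depth_png",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera intrinsics (focal lengths and principal point in pixels)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ConfigurationError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ConfigurationError("principal point must lie inside the image")

    def to_json(self, path: str | Path, depth_scale_mm: float = 1.0) -> None:
        payload = {
            "fx": self.fx,
            "fy": self.fy,
            "cx": self.cx,
            "cy": self.cy,
            "width": self.width,
            "height": self.height,
            "depth_scale_mm": depth_scale_mm,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> tuple["CameraIntrinsics", float]:
        """Load intrinsics plus the depth scale (mm per stored unit)."""
        raw = json.loads(Path(path).read_text())
        scale = float(raw.pop("depth_scale_mm", 1.0))
        return cls(
            fx=float(raw["fx"]),
            fy=float(raw["fy"]),
            cx=float(raw["cx"]),
            cy=float(raw["cy"]),
            width=int(raw["width"]),
            height=int(raw["height"]),
        ), scale


@dataclass
class DepthMap:
    """Per-pixel z-depth in meters with a validity mask.

    ``values`` is a (height, width) float array; entries where ``valid`` is
    False carry no depth (sensor dropout).  Zero/NaN/out-of-range depths are
    demoted to invalid on construction and counted in the log.
    """

    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    max_range_m: float = 5.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ConfigurationError("depth map must be 2-D")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ConfigurationError("validity mask shape must match depth values")
        finite = np.isfinite(self.values)
        in_range = finite & (self.values > 0) & (self.values < self.max_range_m)
        demoted = int(np.count_nonzero(self.valid & ~in_range))
        if demoted:
            logger.debug("depth map: %d pixels demoted to invalid", demoted)
        self.valid &= in_range

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


@dataclass
class PointCloud:
    """Back-projected 3-D points (camera frame) with their source pixels.

    ``points`` is (N, 3); ``pixel_index`` is (N, 2) holding (row, col) of the
    originating depth pixel, in row-major pixel order.
    """

    points: np.ndarray
    pixel_index: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.pixel_index = np.asarray(self.pixel_index, dtype=np.intp).reshape(-1, 2)
        if len(self.points) != len(self.pixel_index):
            raise ConfigurationError("points and pixel_index length mismatch")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Plane:
    """Plane {x : normal . x = offset} with a unit normal facing the camera."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = float(np.linalg.norm(n))
        if abs(norm - 1.0) > 1e-9:
            raise ConfigurationError("plane normal must be a unit vector")
        object.__setattr__(self, "normal", n)

    @classmethod
    def from_vector(cls, normal: np.ndarray, offset: float) -> "Plane":
        """Normalize and canonicalize the normal toward the camera (-z side)."""
        n = np.asarray(normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise PlaneFitError("degenerate plane normal")
        n = n / norm
        d = float(offset) / norm
        # camera looks along +z; "toward camera" means normal . (0,0,-1) >= 0
        if n[2] > 0:
            n, d = -n, -d
        return cls(normal=n, offset=d)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """n.p - d; positive on the camera side of the plane ("above" a table)."""
        return np.asarray(points, dtype=np.float64) @ self.normal - self.offset

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (origin, e1, e2): a point on the plane and an in-plane
        orthonormal frame, for 2-D coordinates over the plane."""
        n = self.normal
        seed = np.array([1.0, 0.0, 0.0])
        if abs(n[0]) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(seed, n)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return self.offset * n, e1, e2


@dataclass
class TriMesh:
    """Triangle mesh over back-projected points.

    ``vertices`` (V, 3) meters, ``faces`` (F, 3) vertex indices, and
    ``pixel_index`` (V, 2) the source pixel of each vertex.
    """

    vertices: np.ndarray
    faces: np.ndarray
    pixel_index: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.intp).reshape(-1, 3)
        self.pixel_index = np.asarray(self.pixel_index, dtype=np.intp).reshape(-1, 2)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ConfigurationError("face index out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        """3-D triangle areas in m^2."""
        v = self.vertices
        a, b, c = (v[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def to_trimesh(self):
        """Convert to a :mod:`trimesh` mesh (for PLY export / inspection)."""
        import trimesh as _tm

        return _tm.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def export_ply(self, path: str | Path) -> None:
        self.to_trimesh().export(str(path), encoding="ascii")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def backproject(depth: DepthMap, K: CameraIntrinsics) -> PointCloud:
    """Back-project a depth map through the inverse pinhole model.

    A pixel (col=u, row=v) with z-depth z maps to
    ``((u - cx) z / fx, (v - cy) z / fy, z)``.  Invalid pixels produce no
    point; points are emitted in row-major pixel order.
    """
    if depth.shape != (K.height, K.width):
        raise ConfigurationError(
            f"depth shape {depth.shape} does not match intrinsics "
            f"({K.height}, {K.width})"
        )
    rows, cols = np.nonzero(depth.valid)
    if rows.size == 0:
        raise EmptyCloudError("depth map has no valid pixels")
    z = depth.values[rows, cols]
    x = (cols - K.cx) * z / K.fx
    y = (rows - K.cy) * z / K.fy
    return PointCloud(
        points=np.column_stack([x, y, z]),
        pixel_index=np.column_stack([rows, cols]),
    )


def _tls_plane(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane: smallest eigenvector of the centered covariance."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    # SVD is numerically safer than forming the covariance explicitly
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    if s[0] < 1e-15 or (len(s) > 1 and s[1] / s[0] < 1e-12):
        raise PlaneFitError("points are collinear; plane is underdetermined")
    return normal, float(normal @ centroid)


def ransac_plane(
    cloud: PointCloud,
    inlier_threshold_m: float = 0.005,
    iterations: int = 500,
    seed: int = 0,
    diagnostics: dict | None = None,
) -> tuple[Plane, np.ndarray]:
    """Robust plane fit by random sample consensus.

    Repeatedly fits planes to seeded 3-point samples, keeps the hypothesis
    with the most inliers (absolute point-plane distance <= threshold; ties
    broken by lower inlier RMS distance), then refines by total least
    squares on the winning inliers and re-thresholds once.  Deterministic
    for a fixed seed.

    Returns the refined plane (normal toward the camera) and the inlier
    indices into ``cloud.points``.  When a ``diagnostics`` dict is passed,
    ``best_sample_inliers`` (the best raw hypothesis count) is stored in it.
    """
    pts = cloud.points
    n_pts = len(pts)
    if n_pts < 3:
        raise PlaneFitError(f"need >= 3 points, got {n_pts}")
    if inlier_threshold_m <= 0:
        raise ConfigurationError("inlier threshold must be positive")
    rng = np.random.default_rng(seed)

    best_count = -1
    best_rms = np.inf
    best_normal: np.ndarray | None = None
    best_d = 0.0
    for _ in range(iterations):
        idx = rng.choice(n_pts, size=3, replace=False)
        a, b, c = pts[idx]
        normal = np.cross(b - a, c - a)
        nn = np.linalg.norm(normal)
        if nn < 1e-12:  # collinear sample
            continue
        normal = normal / nn
        d = float(normal @ a)
        dist = np.abs(pts @ normal - d)
        inliers = dist <= inlier_threshold_m
        count = int(np.count_nonzero(inliers))
        if count < 3:
            continue
        rms = float(np.sqrt(np.mean(dist[inliers] ** 2)))
        if count > best_count or (count == best_count and rms < best_rms):
            best_count, best_rms = count, rms
            best_normal, best_d = normal, d
    if best_normal is None:
        raise PlaneFitError("all sampled hypotheses were collinear")
    if diagnostics is not None:
        diagnostics["best_sample_inliers"] = best_count

    inlier_idx = np.nonzero(np.abs(pts @ best_normal - best_d) <= inlier_threshold_m)[0]
    normal, d = _tls_plane(pts[inlier_idx])
    plane = Plane.from_vector(normal, d)
    inlier_idx = np.nonzero(np.abs(plane.signed_distance(pts)) <= inlier_threshold_m)[0]
    if len(inlier_idx) >= 3:
        # one more TLS pass on the re-thresholded set stabilizes the fit
        normal, d = _tls_plane(pts[inlier_idx])
        plane = Plane.from_vector(normal, d)
        inlier_idx = np.nonzero(
            np.abs(plane.signed_distance(pts)) <= inlier_threshold_m
        )[0]
    return plane, inlier_idx


def default_max_edge(cloud: PointCloud, factor: float = 5.0) -> float:
    """Occlusion-filter edge length: ``factor`` x median 3-D spacing of
    horizontally adjacent valid pixels."""
    order = np.lexsort((cloud.pixel_index[:, 1], cloud.pixel_index[:, 0]))
    pix = cloud.pixel_index[order]
    pts = cloud.points[order]
    same_row = pix[1:, 0] == pix[:-1, 0]
    adjacent = same_row & (pix[1:, 1] - pix[:-1, 1] == 1)
    if not adjacent.any():
        return factor * 0.005  # sparse cloud fallback: 5 mm nominal spacing
    gaps = np.linalg.norm(pts[1:][adjacent] - pts[:-1][adjacent], axis=1)
    return factor * float(np.median(gaps))


def triangulate_surface(cloud: PointCloud, max_edge_m: float | None = None) -> TriMesh:
    """Mesh the visible surface by Delaunay triangulation in pixel space.

    The cloud is a perspective height field, so a 2-D Delaunay triangulation
    of the source pixel coordinates, lifted to the 3-D points, tessellates
    the visible surface.  Triangles with any 3-D edge longer than
    ``max_edge_m`` are discarded: they bridge depth discontinuities
    (occlusion boundaries) rather than sample a surface.  Zero-area faces
    are dropped.
    """
    if len(cloud) < 3:
        raise TriangulationError(f"need >= 3 points, got {len(cloud)}")
    if max_edge_m is None:
        max_edge_m = default_max_edge(cloud)
    uv = cloud.pixel_index[:, ::-1].astype(np.float64)  # (col, row)
    try:
        tri = Delaunay(uv)
    except QhullError as exc:  # e.g. all pixels collinear
        raise TriangulationError(f"Delaunay triangulation failed: {exc}") from exc
    faces = tri.simplices
    v = cloud.points
    e0 = np.linalg.norm(v[faces[:, 1]] - v[faces[:, 0]], axis=1)
    e1 = np.linalg.norm(v[faces[:, 2]] - v[faces[:, 1]], axis=1)
    e2 = np.linalg.norm(v[faces[:, 0]] - v[faces[:, 2]], axis=1)
    keep = np.maximum(np.maximum(e0, e1), e2) <= max_edge_m
    faces = faces[keep]
    areas = 0.5 * np.linalg.norm(
        np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]]),
        axis=1,
    )
    faces = faces[areas > 0.0]
    return TriMesh(vertices=v, faces=faces, pixel_index=cloud.pixel_index)


# ---------------------------------------------------------------------------
# depth PNG I/O (16-bit grayscale, value = depth in millimeters, 0 = invalid)
# ---------------------------------------------------------------------------


def save_depth_png(depth: DepthMap, path: str | Path, depth_scale_mm: float = 1.0) -> None:
    """Write depth as a 16-bit grayscale PNG (units of ``depth_scale_mm`` mm)."""
    mm = np.where(depth.valid, depth.values * 1000.0 / depth_scale_mm, 0.0)
    mm = np.clip(np.round(mm), 0, 65535).astype(np.uint16)
    Image.fromarray(mm).save(str(path))


def load_depth_png(
    path: str | Path, depth_scale_mm: float = 1.0, max_range_m: float = 5.0
) -> DepthMap:
    """Read a 16-bit grayscale depth PNG; zero pixels are invalid."""
    arr = np.asarray(Image.open(str(path)), dtype=np.float64)
    valid = arr > 0
    return DepthMap(
        values=arr * depth_scale_mm / 1000.0, valid=valid, max_range_m=max_range_m
    )
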