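"""Per-item volume estimation: cut the visible surface by the segmentation,
close each food surface against the dish base, and integrate.

The integrator is a prism rule: each surface triangle contributes its
footprint area — projected onto the table's tangent frame — times the mean
of its three vertex heights above the base surface (negative heights
clipped to zero).  This closes the open visible surface "straight down"
onto the dish, which is exact for height fields over the base and robust
to the open boundaries a single-view mesh necessarily has.  Volume hidden
behind the item in a single capture (back-facing surface at oblique views)
is not recoverable and is the dominant error source at 45 degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .depth_geometry import (
    CameraIntrinsics,
    DepthMap,
    Plane,
    PointCloud,
    TriMesh,
    backproject,
    default_max_edge,
    ransac_plane,
    triangulate_surface,
)
from .errors import ConfigurationError
from .nutrient_db import (
    FoodTable,
    ItemEstimate,
    MealEstimate,
    load_food_table,
    volume_to_weight,
    weight_to_macros,
)
from .segmentation import LabelMask

logger = logging.getLogger(__name__)

__all__ = [
    "DishModel",
    "FoodSurface",
    "PipelineConfig",
    "cut_surface",
    "close_and_volume",
    "estimate_meal",
]


@dataclass
class DishModel:
    """Dish base surface as a height field over the fitted table plane.

    ``flat_plate``: constant ``offset`` above the table (0 = food rests on
    the table plane itself).  ``bowl``: spherical-cap interior of sphere
    radius ``bowl_radius`` and rim depth ``depth``, centered at ``center``
    in the table's 2-D tangent coordinates; outside the bowl footprint the
    base is the table.
    """

    kind: str = "flat_plate"
    offset: float = 0.0
    bowl_radius: float = 0.10
    depth: float = 0.04
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("flat_plate", "bowl"):
            raise ConfigurationError(f"unknown dish kind {self.kind!r}")
        if self.offset < 0:
            raise ConfigurationError("dish base cannot lie below the table plane")
        if self.kind == "bowl" and self.depth > self.bowl_radius:
            raise ConfigurationError("bowl depth cannot exceed its sphere radius")

    def height(self, xi: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """Base-surface height above the table at tangent coords (xi, eta)."""
        xi = np.asarray(xi, dtype=float)
        eta = np.asarray(eta, dtype=float)
        if self.kind == "flat_plate":
            return np.full(np.broadcast(xi, eta).shape, self.offset)
        rho2 = (xi - self.center[0]) ** 2 + (eta - self.center[1]) ** 2
        rim_rho2 = self.depth * (2 * self.bowl_radius - self.depth)
        inside = rho2 < rim_rho2
        h = self.bowl_radius - np.sqrt(np.maximum(self.bowl_radius**2 - rho2, 0.0))
        return np.where(inside, h, 0.0)


@dataclass
class FoodSurface:
    """The visible surface restricted to one segmented item."""

    label: int
    mesh: TriMesh

    @property
    def n_faces(self) -> int:
        return self.mesh.n_faces


def cut_surface(mesh: TriMesh, mask: LabelMask) -> list[FoodSurface]:
    """Split the visible surface into per-item food surfaces.

    A triangle belongs to item i iff all three of its vertices' source
    pixels carry label i; triangles with mixed labels straddle item
    boundaries and are dropped (this biases volume slightly low — about
    half a pixel of footprint along each item's outline).
    """
    rows = mesh.pixel_index[:, 0]
    cols = mesh.pixel_index[:, 1]
    if rows.size and (rows.max() >= mask.shape[0] or cols.max() >= mask.shape[1]):
        raise ConfigurationError("mesh pixel indices fall outside the mask")
    vertex_labels = mask.labels[rows, cols]
    face_labels = vertex_labels[mesh.faces]  # (F, 3)
    uniform = (face_labels[:, 0] == face_labels[:, 1]) & (
        face_labels[:, 0] == face_labels[:, 2]
    )
    surfaces = []
    for item in mask.item_labels():
        keep = uniform & (face_labels[:, 0] == item)
        if not keep.any():
            logger.warning("item %d has no surface triangles; excluded", item)
            continue
        surfaces.append(
            FoodSurface(
                label=int(item),
                mesh=TriMesh(
                    vertices=mesh.vertices,
                    faces=mesh.faces[keep],
                    pixel_index=mesh.pixel_index,
                ),
            )
        )
    return surfaces


def close_and_volume(
    surface: FoodSurface, base: DishModel, table: Plane
) -> float:
    """Close a food surface against the dish base and integrate its volume.

    Prism rule per triangle: footprint area in the table tangent frame
    times the mean vertex height above the base surface, heights clipped at
    zero.  Returns mL; always >= 0.
    """
    if surface.n_faces == 0:
        logger.warning("item %d: empty surface, volume 0", surface.label)
        return 0.0
    origin, e1, e2 = table.basis()
    rel = surface.mesh.vertices - origin
    xi = rel @ e1
    eta = rel @ e2
    h = table.signed_distance(surface.mesh.vertices)
    above = np.maximum(h - base.height(xi, eta), 0.0)
    f = surface.mesh.faces
    x = np.column_stack([xi, eta])
    a, b, c = x[f[:, 0]], x[f[:, 1]], x[f[:, 2]]
    e1v, e2v = b - a, c - a
    area2d = 0.5 * np.abs(e1v[:, 0] * e2v[:, 1] - e1v[:, 1] * e2v[:, 0])
    mean_h = above[f].mean(axis=1)
    volume_m3 = float(np.sum(area2d * mean_h))
    if volume_m3 == 0.0:
        logger.warning("item %d lies entirely on/below the base surface", surface.label)
    return volume_m3 * 1e6


@dataclass
class PipelineConfig:
    """Tunables of the quantification pipeline."""

    ransac_iterations: int = 500
    ransac_threshold_m: float = 0.005
    # 10x median pixel spacing: still well below the ~height*sqrt(2) span of a
    # true occlusion bridge, but keeps genuinely steep (near-vertical) surface
    max_edge_factor: float = 10.0
    seed: int = 0


def estimate_meal(
    depth: DepthMap,
    K: CameraIntrinsics,
    mask: LabelMask,
    food_ids: dict[int, str] | None = None,
    dish: DishModel | None = None,
    cfg: PipelineConfig | None = None,
    food_table: FoodTable | None = None,
    meal_id: str = "meal",
    table: Plane | None = None,
) -> MealEstimate:
    """Run the full quantification chain on one capture.

    back-project -> robust table-plane fit -> surface triangulation ->
    per-item cut -> closed-volume integration -> density and composition
    conversion.  Deterministic given ``cfg.seed``.  A pre-fitted ``table``
    plane can be supplied to skip the RANSAC stage.
    """
    cfg = cfg or PipelineConfig()
    dish = dish or DishModel()
    food_table = food_table or load_food_table()
    if depth.shape != mask.shape:
        raise ConfigurationError("depth map and label mask shapes differ")
    if food_ids is None:
        food_ids = mask.food_ids
    missing = [lab for lab in mask.item_labels() if lab not in food_ids]
    if missing:
        raise ConfigurationError(f"labels without food_id assignment: {missing}")

    cloud: PointCloud = backproject(depth, K)
    if table is None:
        table, _ = ransac_plane(
            cloud,
            inlier_threshold_m=cfg.ransac_threshold_m,
            iterations=cfg.ransac_iterations,
            seed=cfg.seed,
        )
    mesh = triangulate_surface(
        cloud, max_edge_m=default_max_edge(cloud, cfg.max_edge_factor)
    )
    surfaces = cut_surface(mesh, mask)
    present = {s.label for s in surfaces}
    excluded = [lab for lab in mask.item_labels() if lab not in present]

    items = []
    for surf in surfaces:
        vol = close_and_volume(surf, dish, table)
        rec = food_table[food_ids[surf.label]]
        weight = volume_to_weight(vol, rec)
        cho, protein, fat, kcal = weight_to_macros(weight, rec)
        items.append(
            ItemEstimate(
                label=surf.label,
                food_id=rec.food_id,
                volume_mL=vol,
                weight_g=weight,
                cho_g=cho,
                protein_g=protein,
                fat_g=fat,
                kcal=kcal,
            )
        )
    return MealEstimate(meal_id=meal_id, items=items, excluded_labels=excluded)
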