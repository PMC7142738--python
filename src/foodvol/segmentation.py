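"""Per-item food masks and segmentation-performance metrics.

The deployed system segmented food with a learned model and let the user
fix bad outlines by hand.  Here segmentation is geometric — pixels whose
back-projected points rise above the fitted table plane, split into
connected components — and the manual fix is simulated by replacing items
whose overlap with the reference falls below a floor.  Two overlap metrics
are provided because both appear in practice: coverage of the corrected
area, and intersection over union.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .depth_geometry import CameraIntrinsics, DepthMap, Plane, backproject
from .errors import ConfigurationError, UndefinedMetricError

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMask",
    "auto_segment",
    "coverage_ratio",
    "iou",
    "simulate_correction",
    "match_labels",
]


@dataclass
class LabelMask:
    """Integer label image: 0 = non-food, k>0 = item k.

    ``food_ids`` maps labels to food identifiers for nutrient lookup.
    Labels partition the image by construction (one label per pixel).
    """

    labels: np.ndarray
    food_ids: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ConfigurationError("label mask must be 2-D")
        if self.labels.min() < 0:
            raise ConfigurationError("labels must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def item_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)

    def area(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def save_png(self, path: str | Path) -> None:
        if self.labels.max() > 255:
            raise ConfigurationError("more than 255 items cannot be stored as 8-bit PNG")
        Image.fromarray(self.labels.astype(np.uint8), mode="L").save(str(path))
        if self.food_ids:
            sidecar = Path(path).with_suffix(".json")
            sidecar.write_text(
                json.dumps({str(k): v for k, v in self.food_ids.items()}, indent=2)
            )

    @classmethod
    def load_png(cls, path: str | Path, food_ids_path: str | Path | None = None) -> "LabelMask":
        labels = np.asarray(Image.open(str(path)), dtype=np.int32)
        food_ids: dict[int, str] = {}
        sidecar = Path(food_ids_path) if food_ids_path else Path(path).with_suffix(".json")
        if sidecar.exists():
            food_ids = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        return cls(labels=labels, food_ids=food_ids)


def auto_segment(
    depth: DepthMap,
    K: CameraIntrinsics,
    table: Plane,
    dish_height_m: float = 0.0,
    min_height_m: float = 0.003,
    min_region_px: int = 50,
) -> LabelMask:
    """Height-above-plane segmentation.

    Pixels whose back-projected point lies more than ``dish_height_m +
    min_height_m`` above the fitted table plane are food candidates;
    4-connected candidate components with at least ``min_region_px`` pixels
    become items, labeled 1..N in decreasing size order.  Deterministic.
    """
    cloud = backproject(depth, K)
    heights = table.signed_distance(cloud.points)
    candidate = np.zeros(depth.shape, dtype=bool)
    rows, cols = cloud.pixel_index[:, 0], cloud.pixel_index[:, 1]
    candidate[rows, cols] = heights > (dish_height_m + min_height_m)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    comp, n_comp = ndimage.label(candidate, structure=structure)
    labels = np.zeros(depth.shape, dtype=np.int32)
    if n_comp == 0:
        logger.warning("auto_segment: no pixels above the table plane")
        return LabelMask(labels=labels)
    sizes = ndimage.sum_labels(candidate, comp, index=np.arange(1, n_comp + 1))
    keep = [(int(sz), i + 1) for i, sz in enumerate(sizes) if sz >= min_region_px]
    keep.sort(key=lambda t: (-t[0], t[1]))  # big first; stable for equal sizes
    for new_label, (_, old) in enumerate(keep, start=1):
        labels[comp == old] = new_label
    if not keep:
        logger.warning("auto_segment: all regions below min_region_px")
    return LabelMask(labels=labels)


def _areas(a: LabelMask, b: LabelMask, label_a: int, label_b: int):
    if a.shape != b.shape:
        raise ConfigurationError("masks must have the same shape")
    A = a.labels == label_a
    B = b.labels == label_b
    return A, B


def coverage_ratio(
    uncorrected: LabelMask, corrected: LabelMask, item: int, corrected_item: int | None = None
) -> float:
    """Percent of the corrected item area covered by the uncorrected one:
    ``100 |A ∩ B| / |B|`` with A the uncorrected and B the corrected area."""
    A, B = _areas(uncorrected, corrected, item, corrected_item if corrected_item is not None else item)
    nb = np.count_nonzero(B)
    if nb == 0:
        raise UndefinedMetricError(f"corrected area for item {item} is empty")
    return 100.0 * np.count_nonzero(A & B) / nb


def iou(
    uncorrected: LabelMask, corrected: LabelMask, item: int, corrected_item: int | None = None
) -> float:
    """Intersection over union of the two item areas, in percent."""
    A, B = _areas(uncorrected, corrected, item, corrected_item if corrected_item is not None else item)
    union = np.count_nonzero(A | B)
    if union == 0:
        raise UndefinedMetricError(f"item {item} is empty in both masks")
    return 100.0 * np.count_nonzero(A & B) / union


def match_labels(truth: LabelMask, auto: LabelMask) -> dict[int, int | None]:
    """Greedy one-to-one matching of reference items to auto-segmented
    regions by largest pixel overlap.  Returns truth label -> auto label
    (None when nothing overlaps)."""
    if truth.shape != auto.shape:
        raise ConfigurationError("masks must have the same shape")
    pairs = []
    for t in truth.item_labels():
        tmask = truth.labels == t
        overlapping, counts = np.unique(auto.labels[tmask], return_counts=True)
        for lab, cnt in zip(overlapping, counts):
            if lab != 0:
                pairs.append((int(cnt), t, int(lab)))
    pairs.sort(reverse=True)
    matched: dict[int, int | None] = {t: None for t in truth.item_labels()}
    used: set[int] = set()
    for _, t, a in pairs:
        if matched[t] is None and a not in used:
            matched[t] = a
            used.add(a)
    return matched


def simulate_correction(
    truth: LabelMask, auto: LabelMask, iou_floor_pct: float = 70.0
) -> tuple[LabelMask, int]:
    """Simulate the manual segmentation fix.

    Each reference item is matched to an auto-segmented region; items whose
    IoU against their match falls below ``iou_floor_pct`` (or that have no
    match) are replaced by the reference outline.  Returns the corrected
    mask — labeled with the reference item labels — and the number of items
    corrected.  A floor of 0 never corrects.
    """
    matching = match_labels(truth, auto)
    corrected = np.zeros_like(truth.labels)
    n_corrected = 0
    for t, a in matching.items():
        score = 0.0
        if a is not None:
            score = iou(auto, truth, a, corrected_item=t)
        if a is not None and (score >= iou_floor_pct or iou_floor_pct == 0.0):
            corrected[auto.labels == a] = t
        else:
            corrected[truth.labels == t] = t
            n_corrected += 1
    if iou_floor_pct == 0.0:
        # vacuous floor: keep auto regions even when unmatched items exist
        n_corrected = 0
        corrected = np.zeros_like(truth.labels)
        for t, a in matching.items():
            if a is not None:
                corrected[auto.labels == a] = t
    return LabelMask(labels=corrected, food_ids=dict(truth.food_ids)), n_corrected
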