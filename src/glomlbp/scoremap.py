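"""Score-map post-processing: thresholds, area filtering, centroids, crops.

The pipeline mirrors how a scored slide is reduced to detections: a first
threshold on the raw signed scores (default 0, keeping the glomerulus-like
negative side), an area filter that discards connected regions too small or
too large to be glomeruli, a second, stricter threshold on the min-max
normalized map, and finally per-component centroids mapped back to slide
pixels with an auto-crop box around each.

The two thresholds deliberately live on two scales: raw signed scores for
medulla/background removal, and the [0, 1] normalized map for the final
isolation step (its typical working range is 0.15-0.35).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DegenerateScoreMapError
from .detector import ScoreMap

#: 8-connectivity structuring element for component labeling.
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PostprocessConfig:
    """Score-map to detections parameters.

    raw_threshold : applied to signed scores (cells strictly below pass).
    area_min, area_max : inclusive component-area bounds in score-map cells;
        sensible values depend on stride and calibration.
    final_threshold : applied to the min-max normalized map, in [0, 1].
    crop_side : auto-crop box side in ORIGINAL slide pixels; defaults to the
        scan window side when None.
    """

    raw_threshold: float = 0.0
    area_min: int = 6
    area_max: int = 50
    final_threshold: float = 0.25
    crop_side: int | None = None

    def __post_init__(self) -> None:
        if not self.area_min < self.area_max:
            raise ConfigError("area_min must be < area_max")
        if self.area_min <= 0:
            raise ConfigError("area bounds must be positive")
        if not 0.0 <= self.final_threshold <= 1.0:
            raise ConfigError("final_threshold must lie in [0, 1]")
        if self.crop_side is not None and self.crop_side <= 0:
            raise ConfigError("crop_side must be positive")


@dataclass
class DetectionSet:
    """Accepted glomerulus candidates in original-slide pixel coordinates.

    centroids_xy : (N, 2) float array of (x=column, y=row) window centers.
    boxes : (N, 4) int array of clipped crop boxes (x0, y0, x1, y1),
        half-open, side ``crop_side`` before clipping.
    scores : per-detection minimum normalized score (lower = stronger).
    """

    centroids_xy: np.ndarray
    boxes: np.ndarray
    scores: np.ndarray
    slide_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.centroids_xy)

    @classmethod
    def empty(cls, slide_id: str = "", provenance: dict | None = None) -> "DetectionSet":
        return cls(
            centroids_xy=np.empty((0, 2), dtype=np.float64),
            boxes=np.empty((0, 4), dtype=np.int64),
            scores=np.empty(0, dtype=np.float64),
            slide_id=slide_id,
            provenance=provenance or {},
        )


def normalize_map(score_map: ScoreMap | np.ndarray) -> np.ndarray:
    """Min-max rescale signed scores to [0, 1]; 0 is most glomerulus-like."""
    grid = score_map.grid if isinstance(score_map, ScoreMap) else np.asarray(score_map)
    lo, hi = float(np.min(grid)), float(np.max(grid))
    if hi == lo:
        raise DegenerateScoreMapError("degenerate score map: all scores identical")
    return (grid - lo) / (hi - lo)


def candidate_mask(score_map: ScoreMap | np.ndarray, raw_threshold: float = 0.0) -> np.ndarray:
    """Cells whose signed score is strictly below the raw threshold."""
    grid = score_map.grid if isinstance(score_map, ScoreMap) else np.asarray(score_map)
    return grid < raw_threshold


def area_filter(mask: np.ndarray, area_min: int, area_max: int) -> np.ndarray:
    """Keep 8-connected components with area in [area_min, area_max]."""
    if area_min > area_max:
        raise ConfigError("area_min must be <= area_max")
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    areas = np.bincount(labels.ravel())[1:]  # skip background
    keep = (areas >= area_min) & (areas <= area_max)
    return keep[labels - 1] & (labels > 0)


def final_detections(score_map: ScoreMap, config: PostprocessConfig | None = None) -> DetectionSet:
    """Full post-processing pipeline: thresholds -> area filter -> centroids.

    Component centroids are unweighted means of cell coordinates, mapped to
    slide pixels at the window centers; an empty result is a valid (empty)
    DetectionSet, not an error.
    """
    config = config or PostprocessConfig()
    provenance = {
        "raw_threshold": config.raw_threshold,
        "area_min": config.area_min,
        "area_max": config.area_max,
        "final_threshold": config.final_threshold,
        "stride": score_map.stride,
        "window_side": score_map.window_side,
        "calibration": score_map.calibration,
    }
    mask = candidate_mask(score_map, config.raw_threshold)
    mask = area_filter(mask, config.area_min, config.area_max)
    if not mask.any():
        return DetectionSet.empty(score_map.slide_id, provenance)
    norm = normalize_map(score_map)
    mask &= norm < config.final_threshold
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return DetectionSet.empty(score_map.slide_id, provenance)

    index = np.arange(1, n + 1)
    cent = ndimage.center_of_mass(mask, labels, index)  # (row, col) means
    ci = np.array([c[0] for c in cent])
    cj = np.array([c[1] for c in cent])
    min_scores = ndimage.minimum(norm, labels, index)

    x, y = score_map.cell_to_slide(ci, cj)
    sh, sw = score_map.slide_shape
    x = np.clip(x, 0, sw - 1)
    y = np.clip(y, 0, sh - 1)

    crop_side = config.crop_side or score_map.window_side
    half = crop_side / 2.0
    ux0 = np.round(x - half).astype(np.int64)
    uy0 = np.round(y - half).astype(np.int64)
    x0 = np.clip(ux0, 0, sw)
    y0 = np.clip(uy0, 0, sh)
    x1 = np.clip(ux0 + crop_side, 0, sw)
    y1 = np.clip(uy0 + crop_side, 0, sh)
    boxes = np.stack([x0, y0, x1, y1], axis=1)

    return DetectionSet(
        centroids_xy=np.stack([x, y], axis=1),
        boxes=boxes,
        scores=np.asarray(min_scores, dtype=np.float64),
        slide_id=score_map.slide_id,
        provenance=provenance,
    )


def crop_detections(slide: np.ndarray, detections: DetectionSet) -> list[np.ndarray]:
    """Extract each detection box from the original (uncalibrated) slide.

    Boxes are already clipped to slide bounds, so edge detections yield
    smaller patches.
    """
    crops = []
    for x0, y0, x1, y1 in detections.boxes:
        crops.append(slide[int(y0) : int(y1), int(x0) : int(x1)])
    return crops
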