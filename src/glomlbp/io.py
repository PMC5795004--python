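"""File I/O, run configuration, and logging for the detection pipeline.

Conventions: all coordinates in CSVs are 0-based (x = column, y = row) in
ORIGINAL slide pixels; calibrated coordinates never leak into outputs.
Slides resized during acquisition (e.g. human sections scanned at half
resolution) are handled uniformly through the calibration factor.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detector import ScanConfig, ScoreMap
from .errors import FormatError, GlomLBPError
from .features import FeatureConfig
from .scoremap import DetectionSet, PostprocessConfig

logger = logging.getLogger("glomlbp")


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@contextmanager
def stage_timer(name: str):
    """Log wall time of a pipeline stage (informational only)."""
    t0 = time.perf_counter()
    yield
    logger.info("stage %s: %.2f s", name, time.perf_counter() - t0)


# --------------------------------------------------------------------------
# images


def read_slide(path: str | Path, level: int = 0) -> np.ndarray:
    """Read an image file as 8-bit H x W x 3 RGB.

    PNG/JPEG go through Pillow; plain, tiled and pyramidal TIFF through
    tifffile (``level`` selects the pyramid level where present).  Grayscale
    is replicated to three channels; an alpha channel is dropped with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in {".tif", ".tiff"}:
            import tifffile

            with tifffile.TiffFile(path) as tf:
                series = tf.series[0]
                if getattr(series, "levels", None) and len(series.levels) > 1:
                    arr = series.levels[min(level, len(series.levels) - 1)].asarray()
                else:
                    arr = series.asarray()
        elif suffix in {".png", ".jpg", ".jpeg"}:
            from PIL import Image

            with Image.open(path) as im:
                arr = np.asarray(im)
        else:
            raise FormatError(f"unsupported image format '{suffix}': {path}")
    except FormatError:
        raise
    except Exception as exc:  # unreadable file, truncated stream, ...
        raise FormatError(f"could not read image {path}: {exc}") from exc
    return _to_rgb8(arr, path)


def _to_rgb8(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        return np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:
        logger.warning("dropping alpha channel of %s", path)
        return arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr
    raise FormatError(f"unsupported image layout {arr.shape} in {path}")


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an 8-bit image as PNG/JPEG (Pillow) or TIFF (tifffile)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, image)
    else:
        from PIL import Image

        Image.fromarray(image).save(path)


def save_score_map(score_map: ScoreMap, tiff_path: str | Path, preview_path: str | Path | None = None) -> None:
    """Write the raw grid as 32-bit float TIFF, plus an optional PNG preview.

    The preview is min-max stretched with low (glomerulus-like) scores dark.
    """
    import tifffile

    tifffile.imwrite(tiff_path, score_map.grid.astype(np.float32))
    if preview_path is not None:
        from .scoremap import normalize_map

        norm = normalize_map(score_map)
        write_image(preview_path, np.round(norm * 255).astype(np.uint8))


def load_score_map(tiff_path: str | Path, scan: ScanConfig, slide_shape: tuple[int, int], slide_id: str = "") -> ScoreMap:
    import tifffile

    grid = tifffile.imread(tiff_path).astype(np.float64)
    ch = int(round(slide_shape[0] * scan.calibration))
    cw = int(round(slide_shape[1] * scan.calibration))
    return ScoreMap(
        grid=grid,
        window_side=scan.window_side,
        stride=scan.stride,
        calibration=scan.calibration,
        slide_shape=slide_shape,
        calibrated_shape=(ch, cw),
        slide_id=slide_id,
    )


# --------------------------------------------------------------------------
# CSV tables


def save_detections_csv(detections: DetectionSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "slide_id": detections.slide_id,
            "centroid_x": detections.centroids_xy[:, 0],
            "centroid_y": detections.centroids_xy[:, 1],
            "box_x0": detections.boxes[:, 0],
            "box_y0": detections.boxes[:, 1],
            "box_x1": detections.boxes[:, 2],
            "box_y1": detections.boxes[:, 3],
            "score": detections.scores,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def load_detections_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_truth_csv(slide_id: str, centroids_xy: np.ndarray, path: str | Path, radii: np.ndarray | None = None) -> None:
    data = {
        "slide_id": slide_id,
        "x": np.asarray(centroids_xy)[:, 0],
        "y": np.asarray(centroids_xy)[:, 1],
    }
    if radii is not None:
        data["radius"] = radii
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.2f")


def load_truth_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"truth CSV {path} lacks columns: {sorted(missing)}")
    return df


def draw_overlay(slide: np.ndarray, detections: DetectionSet, thickness: int = 5) -> np.ndarray:
    """Burn green detection boxes into a copy of the slide."""
    out = np.array(slide, copy=True)
    green = np.array([0, 200, 0], dtype=out.dtype)
    h, w = out.shape[:2]
    for x0, y0, x1, y1 in detections.boxes:
        x0, y0 = int(max(x0, 0)), int(max(y0, 0))
        x1, y1 = int(min(x1, w)), int(min(y1, h))
        t = thickness
        out[y0 : min(y0 + t, y1), x0:x1] = green
        out[max(y1 - t, y0) : y1, x0:x1] = green
        out[y0:y1, x0 : min(x0 + t, x1)] = green
        out[y0:y1, max(x1 - t, x0) : x1] = green
    return out


# --------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters in one round-trippable object."""

    feature: FeatureConfig = field(default_factory=FeatureConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    post: PostprocessConfig = field(default_factory=PostprocessConfig)
    match_radius: float = 288.0
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "feature": asdict(self.feature),
            "scan": asdict(self.scan),
            "post": asdict(self.post),
            "match_radius": self.match_radius,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        d["feature"]["radii"] = list(self.feature.radii)
        d["feature"]["channels"] = list(self.feature.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            f = dict(d.get("feature", {}))
            if "radii" in f:
                f["radii"] = tuple(f["radii"])
            if "channels" in f:
                f["channels"] = tuple(f["channels"])
            return cls(
                feature=FeatureConfig(**f),
                scan=ScanConfig(**d.get("scan", {})),
                post=PostprocessConfig(**d.get("post", {})),
                match_radius=float(d.get("match_radius", 288.0)),
                seed=int(d.get("seed", 0)),
                log_level=str(d.get("log_level", "INFO")),
            )
        except TypeError as exc:
            raise GlomLBPError(f"invalid config: {exc}") from exc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
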