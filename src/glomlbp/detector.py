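"""Linear max-margin detector: training and whole-slide sliding-window scoring.

The classifier is a linear soft-margin SVM (box constraint C=1, no feature
standardization) on mrcLBP descriptors.  Scores follow the score-map
convention: glom(+), the glomerulus class, sits on the NEGATIVE side of the
decision function, so low (dark) score-map values mark likely glomeruli.

Scanning resizes the slide by a resolution-matching "calibration" factor,
then scores a stride-spaced grid of windows.  Rather than re-cropping and
re-interpolating per window, LBP bin-index maps are precomputed once per
(channel, radius) over the whole calibrated slide; because a histogram only
uses centers whose full neighborhood lies inside the window's center region,
the per-window histograms are bit-identical to featurizing each window as a
standalone patch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np
from sklearn.svm import SVC

from .errors import ConfigError, GlomLBPError
from .features import FeatureConfig, _CHANNEL_INDEX, _center_side, as_rgb
from .lbp import histogram_from_bin_map, lbp_bin_map

MODEL_FORMAT_TAG = "glomlbp-linear-svm/1"


@dataclass(frozen=True)
class ScanConfig:
    """Sliding-window geometry.

    window_side : window side in calibrated pixels (equals the training
        patch side).
    stride : spacing between successive window corners, calibrated pixels.
    calibration : resize factor applied to the slide before scanning so its
        resolution matches the training patches (e.g. 0.5 halves the slide).
    """

    window_side: int = 576
    stride: int = 64
    calibration: float = 1.0

    def __post_init__(self) -> None:
        if self.window_side <= 0 or self.stride <= 0:
            raise ConfigError("window_side and stride must be positive")
        if self.stride > self.window_side:
            raise ConfigError(
                f"stride ({self.stride}) must not exceed window_side ({self.window_side})"
            )
        if not self.calibration > 0:
            raise ConfigError("calibration must be positive")


@dataclass
class DetectorModel:
    """Trained linear detector: score(x) = weights . x + bias.

    Under the stored label convention, glomerulus-like (glom(+)) features
    score negative and background features score positive.
    """

    weights: np.ndarray
    bias: float
    feature_config: FeatureConfig
    n_pos: int
    n_neg: int
    seed: int
    label_convention: str = "glom(+) scores negative"

    def score(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=np.float64))
        return x @ self.weights + self.bias

    # -- serialization: a self-describing text (JSON) format -----------------
    def save(self, path: str | Path) -> None:
        doc = {
            "format": MODEL_FORMAT_TAG,
            "label_convention": self.label_convention,
            "weights": [float(w) for w in self.weights],
            "bias": float(self.bias),
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "seed": self.seed,
            "feature_config": {
                "radii": list(self.feature_config.radii),
                "channels": list(self.feature_config.channels),
                "center_fraction": self.feature_config.center_fraction,
                "patch_side": self.feature_config.patch_side,
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DetectorModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != MODEL_FORMAT_TAG:
            raise GlomLBPError(f"unrecognized model format in {path}")
        fc = doc["feature_config"]
        return cls(
            weights=np.asarray(doc["weights"], dtype=np.float64),
            bias=float(doc["bias"]),
            feature_config=FeatureConfig(
                radii=tuple(fc["radii"]),
                channels=tuple(fc["channels"]),
                center_fraction=fc["center_fraction"],
                patch_side=fc["patch_side"],
            ),
            n_pos=int(doc["n_pos"]),
            n_neg=int(doc["n_neg"]),
            seed=int(doc["seed"]),
            label_convention=doc["label_convention"],
        )


def train_detector(
    pos_features: np.ndarray,
    neg_features: np.ndarray,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
) -> DetectorModel:
    """Fit the linear SVM on glom(+) and glom(-) feature rows.

    Linear kernel, box constraint 1, no standardization; the fit is
    deterministic given row order, so callers should pass rows in a canonical
    (filename-sorted) order.  Weights are oriented so glom(+) rows score
    negative.
    """
    pos = np.atleast_2d(np.asarray(pos_features, dtype=np.float64))
    neg = np.atleast_2d(np.asarray(neg_features, dtype=np.float64))
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise GlomLBPError("both classes need at least one feature row")
    if pos.shape[1] != neg.shape[1]:
        raise GlomLBPError(
            f"feature dimension mismatch: {pos.shape[1]} vs {neg.shape[1]}"
        )
    for name, mat in (("glom(+)", pos), ("glom(-)", neg)):
        bad = np.where(~np.isfinite(mat).all(axis=1))[0]
        if bad.size:
            raise GlomLBPError(f"non-finite {name} feature rows: {bad.tolist()}")

    x = np.vstack([pos, neg])
    # glom(+) -> class 0, glom(-) -> class 1: sklearn's decision function is
    # positive for class 1, which puts glom(+) on the negative side directly.
    y = np.concatenate([np.zeros(len(pos), dtype=int), np.ones(len(neg), dtype=int)])
    clf = SVC(kernel="linear", C=1.0, random_state=seed)
    clf.fit(x, y)
    w = clf.coef_[0].astype(np.float64)
    b = float(clf.intercept_[0])
    # Defensive orientation check; the label mapping above already ensures it.
    if np.median(pos @ w + b) > np.median(neg @ w + b):
        w, b = -w, -b
    return DetectorModel(
        weights=w,
        bias=b,
        feature_config=feature_config or FeatureConfig(),
        n_pos=len(pos),
        n_neg=len(neg),
        seed=seed,
    )


@dataclass
class ScoreMap:
    """Grid of signed window scores plus the geometry to map cells to pixels.

    grid[i, j] is the model score of the window whose top-left corner is at
    calibrated pixel (i*stride, j*stride).
    """

    grid: np.ndarray
    window_side: int
    stride: int
    calibration: float
    slide_shape: tuple[int, int]  # original slide (H, W)
    calibrated_shape: tuple[int, int]  # slide (H', W') after calibration
    slide_id: str = ""

    def cell_to_slide(self, i, j) -> tuple[np.ndarray, np.ndarray]:
        """Map grid cell(s) to the window-center position in ORIGINAL slide px.

        Returns (x, y) = (column, row).  Calibrated coordinates are divided
        by the calibration factor, the inverse of the scan-time resize.
        """
        i = np.asarray(i, dtype=np.float64)
        j = np.asarray(j, dtype=np.float64)
        y = (i * self.stride + self.window_side / 2.0) / self.calibration
        x = (j * self.stride + self.window_side / 2.0) / self.calibration
        return x, y

    def slide_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Inverse of :meth:`cell_to_slide` (fractional cell coordinates)."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        i = (y * self.calibration - self.window_side / 2.0) / self.stride
        j = (x * self.calibration - self.window_side / 2.0) / self.stride
        return i, j


def grid_shape(height: int, width: int, window_side: int, stride: int) -> tuple[int, int]:
    """Rows/cols of stride-spaced windows fully inside a height x width image."""
    if height < window_side or width < window_side:
        raise GlomLBPError(
            f"slide {height}x{width} smaller than one {window_side}px window"
        )
    return (
        (height - window_side) // stride + 1,
        (width - window_side) // stride + 1,
    )


def _calibrate(slide: np.ndarray, calibration: float) -> np.ndarray:
    if calibration == 1.0:
        return slide
    from skimage.transform import resize

    h, w = slide.shape[:2]
    out_shape = (
        max(1, int(round(h * calibration))),
        max(1, int(round(w * calibration))),
    )
    resized = resize(
        slide.astype(np.float64),
        out_shape + slide.shape[2:],
        order=1,
        anti_aliasing=calibration < 1.0,
        preserve_range=True,
    )
    return resized


def scan_slide(
    slide: np.ndarray,
    model: DetectorModel,
    scan: ScanConfig | None = None,
    slide_id: str = "",
) -> ScoreMap:
    """Score every sliding-window position of a slide into a ScoreMap."""
    scan = scan or ScanConfig()
    rgb = as_rgb(slide)
    orig_shape = rgb.shape[:2]
    cal = _calibrate(rgb, scan.calibration)
    ch, cw = cal.shape[:2]
    nrows, ncols = grid_shape(ch, cw, scan.window_side, scan.stride)

    fc = model.feature_config
    win = scan.window_side
    crop_side = _center_side(win, fc.center_fraction)
    crop_off = (win - crop_side) // 2

    # Whole-slide bin maps per (channel, radius); bin_maps[(c, r)][i, j] is the
    # bin of center pixel (i + r, j + r) in calibrated slide coordinates.
    bin_maps = {
        (c, r): lbp_bin_map(cal[:, :, _CHANNEL_INDEX[c]].astype(np.float64), r)
        for c in fc.channels
        for r in fc.radii
    }

    block_order = fc.block_order()
    grid = np.empty((nrows, ncols), dtype=np.float64)
    feat = np.empty(fc.n_features, dtype=np.float64)
    for i in range(nrows):
        y0 = i * scan.stride + crop_off
        for j in range(ncols):
            x0 = j * scan.stride + crop_off
            for k, (c, r) in enumerate(block_order):
                # valid centers of the standalone crop: inset r from its edges
                sub = bin_maps[(c, r)][
                    y0 : y0 + crop_side - 2 * r, x0 : x0 + crop_side - 2 * r
                ]
                feat[10 * k : 10 * (k + 1)] = histogram_from_bin_map(sub)
            grid[i, j] = feat @ model.weights + model.bias

    return ScoreMap(
        grid=grid,
        window_side=win,
        stride=scan.stride,
        calibration=scan.calibration,
        slide_shape=orig_shape,
        calibrated_shape=(ch, cw),
        slide_id=slide_id,
    )


class SecondStageClassifier(Protocol):
    """Hook for refining candidate crops with a second classifier.

    Accepts a sequence of RGB candidate patches and returns a boolean
    keep/discard array of the same length.
    """

    def __call__(self, patches: list[np.ndarray]) -> np.ndarray: ...


def pass_through_classifier(patches: list[np.ndarray]) -> np.ndarray:
    """Default second stage: keep every candidate."""
    return np.ones(len(patches), dtype=bool)
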