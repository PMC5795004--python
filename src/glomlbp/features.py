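"""Multi-radial color LBP (mrcLBP) descriptor.

A patch is described by 10-bin LBP histograms computed on the central region
of each RGB channel at several radii, concatenated in a fixed channel-major
order (R1 R3 R9 R27 G1 G3 G9 G27 B1 B3 B9 B27 for the defaults), giving a
120-dimensional vector.  Restricting to the center region (1/6 of the patch
width by default) keeps the descriptor focused on the glomerular interior of
a centered training patch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, GlomLBPError
from .lbp import LBPBlock, histogram_from_bin_map, lbp_bin_map

logger = logging.getLogger(__name__)

_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


@dataclass(frozen=True)
class FeatureConfig:
    """Geometry of the mrcLBP descriptor.

    radii : LBP circle radii in pixels, in concatenation order.
    channels : color channels in concatenation order.
    center_fraction : side of the analyzed central square as a fraction of
        the patch side.
    patch_side : nominal training-patch/window side in pixels; used to
        validate that the center region can host the largest radius.
    """

    radii: tuple[int, ...] = (1, 3, 9, 27)
    channels: tuple[str, ...] = ("R", "G", "B")
    center_fraction: float = 1.0 / 6.0
    patch_side: int = 576

    def __post_init__(self) -> None:
        if not self.radii or any(int(r) <= 0 for r in self.radii):
            raise ConfigError("radii must be positive integers")
        if not self.channels or any(c not in _CHANNEL_INDEX for c in self.channels):
            raise ConfigError("channels must be a non-empty subset of R, G, B")
        if not 0.0 < self.center_fraction <= 1.0:
            raise ConfigError("center_fraction must lie in (0, 1]")
        if self.patch_side <= 0:
            raise ConfigError("patch_side must be positive")
        side = _center_side(self.patch_side, self.center_fraction)
        if side < 2 * max(self.radii) + 1:
            raise ConfigError(
                f"center region ({side} px) cannot host LBP radius {max(self.radii)}"
            )
        object.__setattr__(self, "radii", tuple(int(r) for r in self.radii))
        object.__setattr__(self, "channels", tuple(self.channels))

    @property
    def n_features(self) -> int:
        return len(self.radii) * len(self.channels) * 10

    def block_order(self) -> list[tuple[str, int]]:
        """(channel, radius) pairs in concatenation order, e.g. [('R', 1), ...]."""
        return [(c, r) for c in self.channels for r in self.radii]


@dataclass(frozen=True)
class MRCFeature:
    """A concatenated mrcLBP descriptor with its block layout."""

    values: np.ndarray
    blocks: tuple[LBPBlock, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))


def _center_side(side: int, fraction: float) -> int:
    # round-half-up on the fractional side length
    return int(np.floor(fraction * side + 0.5))


def center_region(patch: np.ndarray, center_fraction: float) -> np.ndarray:
    """Axis-aligned central square crop of a patch.

    The side is round(center_fraction * min(H, W)); offsets are floored, so
    an odd margin leaves the extra pixel on the bottom/right.
    """
    if not 0.0 < center_fraction <= 1.0:
        raise ConfigError("center_fraction must lie in (0, 1]")
    h, w = patch.shape[:2]
    side = _center_side(min(h, w), center_fraction)
    if side < 1:
        raise GlomLBPError(
            f"center fraction {center_fraction} of a {h}x{w} patch is empty"
        )
    oy, ox = (h - side) // 2, (w - side) // 2
    return patch[oy : oy + side, ox : ox + side]


def as_rgb(patch: np.ndarray) -> np.ndarray:
    """Coerce a patch to H x W x 3; grayscale is replicated with a warning."""
    patch = np.asarray(patch)
    if patch.ndim == 2:
        logger.warning("grayscale patch replicated to 3 identical channels")
        return np.stack([patch] * 3, axis=-1)
    if patch.ndim == 3 and patch.shape[2] == 3:
        return patch
    raise GlomLBPError(f"expected an RGB patch, got shape {patch.shape}")


def mrc_feature(patch: np.ndarray, config: FeatureConfig | None = None) -> MRCFeature:
    """mrcLBP descriptor of one patch.

    The center region is extracted once; each (channel, radius) histogram is
    computed on that same standalone crop (larger radii simply have fewer
    valid centers), then blocks are concatenated in ``config.block_order()``.
    """
    config = config or FeatureConfig()
    rgb = as_rgb(patch)
    crop = center_region(rgb, config.center_fraction)
    blocks: list[LBPBlock] = []
    for chan, radius in config.block_order():
        plane = crop[:, :, _CHANNEL_INDEX[chan]]
        try:
            bin_map = lbp_bin_map(plane, radius)
        except GlomLBPError as exc:
            raise GlomLBPError(f"block ({chan}, r={radius}): {exc}") from exc
        blocks.append(
            LBPBlock(histogram_from_bin_map(bin_map), channel=chan, radius=radius)
        )
    values = np.concatenate([b.bins for b in blocks])
    return MRCFeature(values=values, blocks=tuple(blocks))


def featurize_patches(
    patches, config: FeatureConfig | None = None
) -> np.ndarray:
    """Stack mrcLBP descriptors of an iterable of patches into a matrix."""
    config = config or FeatureConfig()
    rows = [mrc_feature(p, config).values for p in patches]
    if not rows:
        return np.empty((0, config.n_features))
    return np.vstack(rows)


def featurize_directory(
    directory: str | Path, config: FeatureConfig | None = None
) -> tuple[np.ndarray, list[str]]:
    """Featurize every image in a directory, sorted by filename.

    Returns (feature matrix, filenames).  The canonical filename sort keeps
    downstream training order-independent of filesystem enumeration.
    """
    from .io import read_slide  # deferred: io imports nothing from here

    directory = Path(directory)
    names = sorted(
        p.name
        for p in directory.iterdir()
        if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
    )
    if not names:
        raise GlomLBPError(f"no image files found in {directory}")
    config = config or FeatureConfig()
    matrix = featurize_patches(
        (read_slide(directory / n) for n in names), config
    )
    return matrix, names
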