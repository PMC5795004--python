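"""Circular 8-neighbor local binary patterns (LBP) with rotation-grouped binning.

An LBP code is an 8-bit string obtained by thresholding eight points on a
circle of a given radius against the center pixel: points whose (bilinearly
interpolated) intensity is greater than or equal to the center are assigned 1,
the rest 0.  Codes with at most two circular 0<->1 transitions are "uniform";
58 of the 256 possible codes are uniform.  Histogramming groups uniform codes
by their number of 1-bits (9 bins, for 0..8 ones) and pools every non-uniform
code into a tenth bin, yielding the compact 10-bin descriptor used throughout
this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NeighborhoodOutOfBoundsError, RegionTooSmallError

N_NEIGHBORS = 8
N_BINS = 10
#: Comparison tolerance for "neighbor >= center" on interpolated intensities.
#: Guards exact ties (e.g. constant regions) against float round-off in the
#: bilinear weights; negligible relative to the 0..255 intensity scale.
_TIE_TOL = 1e-6
#: Sub-pixel offsets closer than this to an integer are snapped, so the four
#: axis-aligned neighbors sample exact pixels.
_SNAP_TOL = 1e-9


def neighbor_offsets(radius: float) -> np.ndarray:
    """(dy, dx) offsets of the 8 circle points, neighbor 0 along +x.

    Angles increase toward +y (row-increasing), so neighbor k sits at
    (radius*sin(2*pi*k/8), radius*cos(2*pi*k/8)) relative to the center.
    """
    angles = 2.0 * np.pi * np.arange(N_NEIGHBORS) / N_NEIGHBORS
    off = np.stack([radius * np.sin(angles), radius * np.cos(angles)], axis=1)
    snapped = np.rint(off)
    close = np.abs(off - snapped) < _SNAP_TOL
    off[close] = snapped[close]
    return off


@dataclass(frozen=True)
class LBPCode:
    """One 8-bit circular LBP code.

    ``bits[k]`` is the threshold result for neighbor k; ``value`` is the
    base-2 interpretation with neighbor 0 as the least-significant bit.
    """

    bits: tuple[int, ...]
    value: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.bits) != N_NEIGHBORS or any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 8 binary values")
        object.__setattr__(
            self, "value", sum(b << k for k, b in enumerate(self.bits))
        )

    @classmethod
    def from_value(cls, value: int) -> "LBPCode":
        if not 0 <= value <= 255:
            raise ValueError(f"LBP code value out of range: {value}")
        return cls(tuple((value >> k) & 1 for k in range(N_NEIGHBORS)))


def _as_value(code: "LBPCode | int") -> int:
    return code.value if isinstance(code, LBPCode) else int(code)


def circular_transitions(code: "LBPCode | int") -> int:
    """Number of 0<->1 changes traversing the bits circularly (even, 0..8)."""
    v = _as_value(code)
    bits = [(v >> k) & 1 for k in range(N_NEIGHBORS)]
    return sum(bits[k] != bits[(k + 1) % N_NEIGHBORS] for k in range(N_NEIGHBORS))


def is_uniform(code: "LBPCode | int") -> bool:
    """True iff the code has at most two circular transitions."""
    return circular_transitions(code) <= 2


def bin_index(code: "LBPCode | int") -> int:
    """Rotation-grouped bin: popcount (0..8) for uniform codes, 9 otherwise."""
    v = _as_value(code)
    if is_uniform(v):
        return int(v).bit_count()
    return 9


# Code value -> bin index, used by the vectorized histogram path.
_BIN_LUT = np.array([bin_index(v) for v in range(256)], dtype=np.uint8)


def _bilinear_shift(img: np.ndarray, inset: int, dy: float, dx: float) -> np.ndarray:
    """Sample ``img`` at (y+dy, x+dx) for every center in the inset interior.

    Centers are pixels at least ``inset`` away from every border, so the
    bilinear support of any offset with |dy|,|dx| <= inset stays in bounds.
    """
    h, w = img.shape
    y0, x0 = int(np.floor(dy)), int(np.floor(dx))
    fy, fx = dy - y0, dx - x0

    def block(ey: int, ex: int) -> np.ndarray:
        return img[
            inset + y0 + ey : h - inset + y0 + ey,
            inset + x0 + ex : w - inset + x0 + ex,
        ]

    out = (1.0 - fy) * (1.0 - fx) * block(0, 0)
    if fx:
        out = out + (1.0 - fy) * fx * block(0, 1)
    if fy:
        out = out + fy * (1.0 - fx) * block(1, 0)
        if fx:
            out = out + fy * fx * block(1, 1)
    return out


def lbp_code_map(channel_image: np.ndarray, radius: int) -> np.ndarray:
    """LBP code values for every pixel whose full neighborhood fits the grid.

    Returns an (H-2r, W-2r) uint8 array; entry (i, j) is the code of center
    pixel (i+r, j+r).  Raises :class:`RegionTooSmallError` if no center fits.
    """
    img = np.asarray(channel_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("channel_image must be 2-D")
    r = int(radius)
    if r <= 0:
        raise ValueError("radius must be a positive integer")
    h, w = img.shape
    if h <= 2 * r or w <= 2 * r:
        raise RegionTooSmallError(
            f"region {h}x{w} too small for LBP radius {r} (needs > {2 * r} per side)"
        )
    centers = img[r : h - r, r : w - r]
    codes = np.zeros(centers.shape, dtype=np.uint8)
    for k, (dy, dx) in enumerate(neighbor_offsets(r)):
        neigh = _bilinear_shift(img, r, dy, dx)
        codes |= (neigh >= centers - _TIE_TOL).astype(np.uint8) << k
    return codes


def lbp_bin_map(channel_image: np.ndarray, radius: int) -> np.ndarray:
    """Rotation-grouped bin index (0..9) at every valid center pixel."""
    return _BIN_LUT[lbp_code_map(channel_image, radius)]


def lbp_code(channel_image: np.ndarray, center: tuple[int, int], radius: int) -> LBPCode:
    """LBP code at one center pixel, given as (row, col).

    The full circular neighborhood (including bilinear support) must lie
    inside the grid.
    """
    img = np.asarray(channel_image, dtype=np.float64)
    h, w = img.shape
    row, col = center
    r = int(radius)
    if not (r <= row <= h - 1 - r and r <= col <= w - 1 - r):
        raise NeighborhoodOutOfBoundsError(
            f"center ({row}, {col}) with radius {r} leaves the {h}x{w} grid"
        )
    c = img[row, col]
    bits = []
    for dy, dx in neighbor_offsets(r):
        y, x = row + dy, col + dx
        y0, x0 = int(np.floor(y)), int(np.floor(x))
        fy, fx = y - y0, x - x0
        val = (1 - fy) * (1 - fx) * img[y0, x0]
        if fx:
            val += (1 - fy) * fx * img[y0, x0 + 1]
        if fy:
            val += fy * (1 - fx) * img[y0 + 1, x0]
            if fx:
                val += fy * fx * img[y0 + 1, x0 + 1]
        bits.append(1 if val >= c - _TIE_TOL else 0)
    return LBPCode(tuple(bits))


@dataclass(frozen=True)
class LBPBlock:
    """One normalized 10-bin LBP histogram for a (channel, radius) pair."""

    bins: np.ndarray
    channel: str | None
    radius: int

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=np.float64)
        if b.shape != (N_BINS,):
            raise ValueError("LBPBlock needs exactly 10 bins")
        object.__setattr__(self, "bins", b)


def histogram_from_bin_map(bin_map: np.ndarray) -> np.ndarray:
    """Counts of bin indices, L2-normalized (all-zero stays all-zero)."""
    counts = np.bincount(bin_map.ravel(), minlength=N_BINS).astype(np.float64)
    norm = np.linalg.norm(counts)
    if norm > 0:
        counts /= norm
    return counts


def lbp_histogram(
    channel_image: np.ndarray, radius: int, channel: str | None = None
) -> LBPBlock:
    """Unit-norm 10-bin LBP histogram over all valid centers of a region."""
    bins = histogram_from_bin_map(lbp_bin_map(channel_image, radius))
    return LBPBlock(bins=bins, channel=channel, radius=int(radius))
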