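"""Synthetic slides with planted glomerulus-like disks on tubule-like background.

The generator does not aim for visual realism; it reproduces the one
statistical property the texture detector exploits: object and background
differ in the frequency of local intensity transitions across scales.  The
background is band-limited colored noise at a coarse spatial frequency
(mimicking tubule granularity); each planted "glomerulus" is a disk of
finer-frequency, differently colored noise, blended into the background over
a few pixels so there is no trivially detectable hard edge.  Planted
centroids and radii are recorded as ground truth, so the whole detection
pipeline can be exercised and scored without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GlomLBPError, PlacementError

#: disk boundary is blended into the background over this many pixels
EDGE_BLEND_PX = 5.0


@dataclass(frozen=True)
class TextureSpec:
    """Band-limited colored-noise texture parameters.

    freq_band : (low, high) spatial-frequency band in cycles/pixel kept by
        the band-pass; lower bands give coarser granularity.
    color_mean / color_std : per-channel (R, G, B) intensity mean and
        standard deviation on the 8-bit scale.
    """

    freq_band: tuple[float, float]
    color_mean: tuple[float, float, float]
    color_std: tuple[float, float, float]


#: Coarse pink-ish background: granularity on the tens-of-pixels scale, the
#: way tubular cross-sections tile a cortex at low power.
BACKGROUND_TEXTURE = TextureSpec(
    freq_band=(0.01, 0.05),
    color_mean=(205.0, 150.0, 170.0),
    color_std=(26.0, 24.0, 24.0),
)
#: Fine purple-ish object texture: few-pixel granularity, the way packed
#: capillary loops and nuclei speckle a glomerular tuft.
GLOM_TEXTURE = TextureSpec(
    freq_band=(0.08, 0.25),
    color_mean=(160.0, 125.0, 175.0),
    color_std=(28.0, 26.0, 28.0),
)


@dataclass(frozen=True)
class SyntheticSlideSpec:
    width: int = 2000
    height: int = 2000
    n_glomeruli: int = 30
    glom_radius_range: tuple[float, float] = (120.0, 200.0)
    background_texture: TextureSpec = BACKGROUND_TEXTURE
    glom_texture: TextureSpec = GLOM_TEXTURE
    seed: int = 0


@dataclass
class SyntheticSlide:
    """A generated slide with its planted ground truth."""

    image: np.ndarray  # H x W x 3 uint8
    centroids_xy: np.ndarray  # (N, 2) float, (x, y) disk centers
    radii: np.ndarray  # (N,) float
    spec: SyntheticSlideSpec


def band_noise(shape: tuple[int, int], freq_band: tuple[float, float], rng) -> np.ndarray:
    """Unit-variance, zero-mean noise band-passed to a spatial-frequency annulus."""
    lo, hi = freq_band
    white = rng.standard_normal(shape)
    spec = np.fft.rfft2(white)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.rfftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    spec *= (f >= lo) & (f <= hi)
    out = np.fft.irfft2(spec, s=shape)
    sd = out.std()
    if sd == 0:  # band too narrow for this grid; keep a flat field
        return np.zeros(shape)
    return (out - out.mean()) / sd


def _texture_image(shape: tuple[int, int], tex: TextureSpec, rng) -> np.ndarray:
    """H x W x 3 float image of independent per-channel band noise."""
    out = np.empty(shape + (3,))
    for c in range(3):
        out[:, :, c] = tex.color_mean[c] + tex.color_std[c] * band_noise(
            shape, tex.freq_band, rng
        )
    return out


def _disk_blend_mask(size: int, radius: float) -> np.ndarray:
    """Smooth disk membership: 1 inside, 0 outside, smoothstep over the blend."""
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    d = np.hypot(yy - c, xx - c)
    t = np.clip((radius - d) / EDGE_BLEND_PX, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _place_disks(
    rng, n: int, radius_range: tuple[float, float], width: int, height: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample non-overlapping disks fully inside the slide.

    Centers first, radii second.  Centers are spread by seeded
    best-candidate sampling (each new center is the most isolated of a
    random candidate batch), which maximizes how far apart the planted
    objects sit at the requested density; each radius is then the sampled
    target capped by the distance to the slide edge and by 0.46x the
    distance to the nearest other center, which guarantees pairwise
    non-overlap with a gap.  At the default density (30 disks of 120-200 px
    in a 2000 px slide) the sampled radii sum to more area than sequential
    random packing can place, so crowded slides are biased toward the small
    end of the radius range; a disk whose cap falls below the range minimum
    is a placement failure.
    """
    r_lo, r_hi = radius_range
    if r_lo > r_hi or r_lo <= 0:
        raise GlomLBPError("invalid glom_radius_range")
    targets = rng.uniform(r_lo, r_hi, size=n)
    # Keep centers this far from the slide border when space allows, so every
    # planted object lies in the sliding window's field of view (in a real
    # gigapixel slide the un-scannable border strip is negligible; at desk
    # scale it would otherwise swallow a large fraction of the objects).
    margin = min(260.0, (min(width, height) - 2 * r_lo) / 2 + r_lo)
    margin = max(margin, r_lo)
    n_candidates = 600

    def batch(size: int) -> tuple[np.ndarray, np.ndarray]:
        return (
            rng.uniform(margin, width - margin, size=size),
            rng.uniform(margin, height - margin, size=size),
        )

    # best-candidate init: each new center is the most isolated candidate
    centers = np.empty((0, 2))
    for _ in range(n):
        xs, ys = batch(n_candidates)
        if len(centers):
            d = np.hypot(
                centers[None, :, 0] - xs[:, None], centers[None, :, 1] - ys[:, None]
            ).min(axis=1)
        else:
            d = np.full(n_candidates, np.inf)
        best = int(np.argmax(d))
        centers = np.vstack([centers, [xs[best], ys[best]]])

    def nearest_dist(pts: np.ndarray) -> np.ndarray:
        if len(pts) == 1:
            return np.full(1, np.inf)
        dist = np.hypot(
            pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1]
        )
        np.fill_diagonal(dist, np.inf)
        return dist.min(axis=1)

    # refinement sweeps: greedily move each point to a more isolated spot;
    # pushes the configuration toward even spacing, which is what keeps
    # objects individually resolvable on the score-map grid
    for _sweep in range(8):
        for i in range(n):
            others = np.delete(centers, i, axis=0)
            xs, ys = batch(n_candidates)
            d = np.hypot(
                others[None, :, 0] - xs[:, None], others[None, :, 1] - ys[:, None]
            ).min(axis=1)
            best = int(np.argmax(d))
            cur = np.hypot(
                others[:, 0] - centers[i, 0], others[:, 1] - centers[i, 1]
            ).min()
            if d[best] > cur:
                centers[i] = (xs[best], ys[best])

    # radii: sampled target, capped so neighbors keep a clear background gap
    # (windows straddling a narrower gap would bridge adjacent score blobs)
    gap = 45.0
    nearest = nearest_dist(centers)
    edge = np.minimum.reduce(
        [centers[:, 0], width - centers[:, 0], centers[:, 1], height - centers[:, 1]]
    )
    radii = np.minimum.reduce([targets, edge, 0.5 * (nearest - gap)])
    radii = np.maximum(radii, r_lo)  # floor at the range minimum ...
    dist = np.hypot(
        centers[:, None, 0] - centers[None, :, 0],
        centers[:, None, 1] - centers[None, :, 1],
    )
    np.fill_diagonal(dist, np.inf)
    # ... but never at the cost of overlap or leaving the slide
    if np.any(radii[:, None] + radii[None, :] > dist) or np.any(radii > edge):
        raise PlacementError(
            f"cannot place {n} non-overlapping disks of radius >= {r_lo}; "
            "request fewer or smaller glomeruli"
        )
    return centers, radii


def make_slide(spec: SyntheticSlideSpec | None = None) -> SyntheticSlide:
    """Render a synthetic slide; fully deterministic given ``spec.seed``."""
    spec = spec or SyntheticSlideSpec()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    img = _texture_image(shape, spec.background_texture, rng)

    if spec.n_glomeruli > 0:
        centers, radii = _place_disks(
            rng, spec.n_glomeruli, spec.glom_radius_range, spec.width, spec.height
        )
        for (x, y), r in zip(centers, radii):
            size = int(np.ceil(2 * r)) + 3
            uy0 = int(round(y)) - size // 2
            ux0 = int(round(x)) - size // 2
            y0, x0 = max(uy0, 0), max(ux0, 0)
            y1 = min(uy0 + size, spec.height)
            x1 = min(ux0 + size, spec.width)
            m = _disk_blend_mask(size, r)[
                y0 - uy0 : y1 - uy0, x0 - ux0 : x1 - ux0, None
            ]
            tex = _texture_image((y1 - y0, x1 - x0), spec.glom_texture, rng)
            img[y0:y1, x0:x1] = (1.0 - m) * img[y0:y1, x0:x1] + m * tex
    else:
        centers = np.empty((0, 2))
        radii = np.empty(0)

    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SyntheticSlide(image=image, centroids_xy=centers, radii=radii, spec=spec)


def make_training_patches(
    spec: SyntheticSlideSpec | None = None,
    n_pos: int = 200,
    n_neg: int = 400,
    patch_side: int = 576,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled patch sets for detector training.

    glom(+) patches are patch-sized views centered on a planted disk;
    glom(-) patches contain background only, so their center region overlaps
    no disk.  The default 1:2 class ratio follows the training-set guidance
    that negatives should outnumber positives at least two to one.  Patches
    are rendered directly (one planted disk per positive) rather than cropped
    from a large slide; the textures and geometry are identical.
    """
    spec = spec or SyntheticSlideSpec()
    rng = np.random.default_rng(spec.seed)
    r_lo, r_hi = spec.glom_radius_range
    if min(r_lo, r_hi) * 2 > patch_side:
        raise GlomLBPError("patch_side too small for the glomerulus radius range")

    shape = (patch_side, patch_side)
    pos = np.empty((n_pos, patch_side, patch_side, 3), dtype=np.uint8)
    for i in range(n_pos):
        img = _texture_image(shape, spec.background_texture, rng)
        r = float(rng.uniform(r_lo, min(r_hi, patch_side / 2.0)))
        m = _disk_blend_mask(patch_side, r)[:, :, None]
        tex = _texture_image(shape, spec.glom_texture, rng)
        img = (1.0 - m) * img + m * tex
        pos[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    neg = np.empty((n_neg, patch_side, patch_side, 3), dtype=np.uint8)
    for i in range(n_neg):
        img = _texture_image(shape, spec.background_texture, rng)
        neg[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    return pos, neg
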