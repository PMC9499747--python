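"""Preprocessing chain: weighted greyscale conversion, skull stripping, CLAHE.

The greyscale conversion takes fixed percentages of the three colour channels
(31% red, 57% green, 15% blue). Skull stripping removes non-brain anatomy by
intensity thresholding followed by morphological opening and retention of the
largest connected component. Contrast-limited adaptive histogram equalization
(CLAHE) equalises per-tile histograms after clipping them at a limit

    beta = (p' / L') * (1 + (alpha / 100) * (s_max - 1))

where p' is the tile pixel count, L' the number of grey levels, alpha the
clip factor in percent and s_max the maximum permitted mapping slope; the
clipped excess is redistributed evenly over all bins and pixels are mapped by
bilinear interpolation between the four nearest tile mappings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .image import ImageSlice, as_image

#: channel weights of the greyscale conversion (fractions of R, G, B)
DEFAULT_GREY_WEIGHTS = (0.31, 0.57, 0.15)


@dataclass
class GreyWeights:
    w_red: float = 0.31
    w_green: float = 0.57
    w_blue: float = 0.15

    def __post_init__(self):
        for w in (self.w_red, self.w_green, self.w_blue):
            if not 0.0 <= w <= 1.0:
                raise ValueError("greyscale weights must lie in [0, 1]")

    def as_tuple(self):
        return (self.w_red, self.w_green, self.w_blue)


@dataclass
class SkullStripConfig:
    """Threshold (numeric or 'auto' = Otsu on nonzero pixels) + morphology."""

    threshold: float | str = "auto"
    opening_radius: int = 3
    keep_largest_component: bool = True


@dataclass
class ClaheConfig:
    tile_grid: tuple = (8, 8)
    n_grey_levels: int = 256     # L'
    clip_factor: float = 50.0    # alpha, percent in [0, 100]
    s_max: float = 4.0           # maximum mapping slope
    p_prime: int | None = None   # pixels per tile; derived from the image

    def __post_init__(self):
        if not 0.0 <= self.clip_factor <= 100.0:
            raise ValueError("clip_factor must lie in [0, 100]")
        if self.s_max < 1.0:
            raise ValueError("s_max must be >= 1")
        if min(self.tile_grid) < 1:
            raise ValueError("tile counts must be >= 1")
        if self.n_grey_levels < 2:
            raise ValueError("n_grey_levels must be >= 2")


def rgb_to_grey(image, weights: GreyWeights | tuple = DEFAULT_GREY_WEIGHTS,
                value_range=(0.0, 255.0)) -> ImageSlice:
    """Weighted-channel greyscale conversion.

    ``grey = w_r*R + w_g*G + w_b*B`` per pixel, clipped into ``value_range``.
    A 2-D (already grey) input passes through unchanged.
    """
    if isinstance(weights, GreyWeights):
        weights = weights.as_tuple()
    arr = np.asarray(image.pixels if isinstance(image, ImageSlice) else image,
                     dtype=np.float64)
    if arr.ndim == 2:
        return as_image(arr, value_range).tagged("grey")
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(
            f"expected an (H, W, 3) colour image or an (H, W) grey image, "
            f"got shape {arr.shape}"
        )
    w_r, w_g, w_b = weights
    grey = w_r * arr[..., 0] + w_g * arr[..., 1] + w_b * arr[..., 2]
    grey = np.clip(grey, *value_range)
    return ImageSlice(grey, value_range, {"stage": "grey"})


def skull_strip(image, cfg: SkullStripConfig | None = None):
    """Threshold + morphology skull stripping.

    Pixels below the threshold T are removed from the candidate mask; the mask
    is then cleaned by morphological opening and, optionally, reduced to its
    largest connected component. Returns ``(brain_mask, stripped_image)`` with
    background set to 0.

    An empty post-stripping mask raises a warning (threshold too high) and is
    returned as-is rather than failing.
    """
    cfg = cfg or SkullStripConfig()
    img = as_image(image)
    px = img.pixels
    if cfg.threshold == "auto":
        nonzero = px[px > 0]
        if nonzero.size == 0 or np.ptp(nonzero) == 0:
            t = np.inf
        else:
            t = float(threshold_otsu(nonzero))
    else:
        t = float(cfg.threshold)

    candidate = px >= t
    mask = candidate
    if cfg.opening_radius > 0:
        mask = morphology.opening(
            mask, morphology.disk(cfg.opening_radius)
        ).astype(bool)
    mask &= candidate  # opening with a symmetric footprint cannot add pixels,
    # but keep the subset contract explicit
    if cfg.keep_largest_component and mask.any():
        labels = measure.label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()

    if not mask.any():
        warnings.warn(
            "skull stripping produced an empty brain mask; "
            "the threshold is likely set too high",
            stacklevel=2,
        )
    stripped = ImageSlice(
        np.where(mask, px, 0.0), img.value_range, {"stage": "skull_stripped"}
    )
    return mask, stripped


def clip_limit(cfg: ClaheConfig, p_prime: int | None = None) -> float:
    """Histogram clip limit beta = (p'/L') * (1 + (alpha/100)*(s_max - 1))."""
    p = p_prime if p_prime is not None else cfg.p_prime
    if p is None:
        raise ValueError("p_prime (pixels per tile) is required")
    if cfg.n_grey_levels == 0:
        raise ValueError("n_grey_levels must be nonzero")
    return (p / cfg.n_grey_levels) * (
        1.0 + (cfg.clip_factor / 100.0) * (cfg.s_max - 1.0)
    )


def clip_histogram(hist: np.ndarray, beta: float) -> np.ndarray:
    """Clip a histogram at ``beta`` and spread the excess evenly over all bins.

    Single-pass redistribution: bins may end up at ``beta + excess/len(hist)``
    but never higher.
    """
    hist = np.asarray(hist, dtype=np.float64)
    excess = np.maximum(hist - beta, 0.0).sum()
    clipped = np.minimum(hist, beta)
    return clipped + excess / hist.size


def _tile_edges(n: int, tiles: int) -> np.ndarray:
    return np.linspace(0, n, tiles + 1).astype(int)


def clahe(image, cfg: ClaheConfig | None = None) -> ImageSlice:
    """Contrast-limited adaptive histogram equalization.

    Per-tile histograms over L' grey levels are clipped at the configured
    limit, the excess is evenly redistributed, and each tile's mapping is the
    CDF scaled by (L'-1). Pixels are mapped by bilinear interpolation of the
    four nearest tile mappings; border pixels reuse the edge tile mappings.
    Output intensities lie in [0, L'-1].
    """
    cfg = cfg or ClaheConfig()
    img = as_image(image)
    h, w = img.pixels.shape
    rows, cols = cfg.tile_grid
    if rows > h or cols > w:
        warnings.warn(
            "tile grid exceeds the image size; shrinking the grid", stacklevel=2
        )
        rows, cols = min(rows, h), min(cols, w)

    big_l = cfg.n_grey_levels
    lo, hi = img.value_range
    # quantise intensities to bins 0 .. L'-1
    bins = np.clip(
        ((img.pixels - lo) / (hi - lo) * big_l).astype(int), 0, big_l - 1
    )

    ye = _tile_edges(h, rows)
    xe = _tile_edges(w, cols)
    mappings = np.empty((rows, cols, big_l), dtype=np.float64)
    for i in range(rows):
        for j in range(cols):
            tile = bins[ye[i]:ye[i + 1], xe[j]:xe[j + 1]]
            p_prime = tile.size
            hist = np.bincount(tile.ravel(), minlength=big_l).astype(np.float64)
            beta = clip_limit(cfg, p_prime=p_prime)
            hist = clip_histogram(hist, beta)
            cdf = np.cumsum(hist)
            mappings[i, j] = (big_l - 1) / p_prime * cdf

    # bilinear interpolation between tile-centre mappings
    yc = (ye[:-1] + ye[1:]) / 2.0 - 0.5
    xc = (xe[:-1] + xe[1:]) / 2.0 - 0.5
    fy = np.interp(np.arange(h), yc, np.arange(rows))
    fx = np.interp(np.arange(w), xc, np.arange(cols))
    y0 = np.floor(fy).astype(int)
    x0 = np.floor(fx).astype(int)
    y1 = np.minimum(y0 + 1, rows - 1)
    x1 = np.minimum(x0 + 1, cols - 1)
    wy = (fy - y0)[:, None]
    wx = (fx - x0)[None, :]

    Y0 = y0[:, None]
    Y1 = y1[:, None]
    X0 = x0[None, :]
    X1 = x1[None, :]
    out = (
        (1 - wy) * (1 - wx) * mappings[Y0, X0, bins]
        + (1 - wy) * wx * mappings[Y0, X1, bins]
        + wy * (1 - wx) * mappings[Y1, X0, bins]
        + wy * wx * mappings[Y1, X1, bins]
    )
    return ImageSlice(out, (0.0, float(big_l - 1)), {"stage": "clahe"})


def tile_mappings(image, cfg: ClaheConfig | None = None) -> np.ndarray:
    """Return the per-tile grey-level mappings CLAHE would apply.

    Shape ``(rows, cols, L')``; used to verify monotonicity and the slope
    bound without reaching into :func:`clahe` internals.
    """
    cfg = cfg or ClaheConfig()
    img = as_image(image)
    h, w = img.pixels.shape
    rows, cols = cfg.tile_grid
    rows, cols = min(rows, h), min(cols, w)
    big_l = cfg.n_grey_levels
    lo, hi = img.value_range
    bins = np.clip(((img.pixels - lo) / (hi - lo) * big_l).astype(int), 0, big_l - 1)
    ye, xe = _tile_edges(h, rows), _tile_edges(w, cols)
    out = np.empty((rows, cols, big_l))
    for i in range(rows):
        for j in range(cols):
            tile = bins[ye[i]:ye[i + 1], xe[j]:xe[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=big_l).astype(np.float64)
            hist = clip_histogram(hist, clip_limit(cfg, p_prime=tile.size))
            out[i, j] = (big_l - 1) / tile.size * np.cumsum(hist)
    return out
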