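"""Core 2-D image container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageSlice:
    """A single 2-D intensity grid with its representable range.

    Parameters
    ----------
    pixels : ndarray of shape (H, W)
        Intensity values, stored as float64 regardless of source dtype.
    value_range : tuple of (min, max)
        The representable intensity range (default 8-bit, ``(0, 255)``).
    metadata : dict
        Free-form provenance (source path, processing stage tag, ...).
    """

    pixels: np.ndarray
    value_range: tuple = (0.0, 255.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"ImageSlice expects a 2-D grid, got shape {self.pixels.shape}"
            )
        lo, hi = self.value_range
        if not lo < hi:
            raise ValueError("value_range must satisfy min < max")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.pixels.size

    def clipped(self) -> "ImageSlice":
        """Return a copy with intensities clipped into ``value_range``."""
        lo, hi = self.value_range
        return ImageSlice(
            np.clip(self.pixels, lo, hi), self.value_range, dict(self.metadata)
        )

    def to_uint8(self) -> np.ndarray:
        """Render to 8-bit, rescaling only if the range is not (0, 255)."""
        lo, hi = self.value_range
        px = np.clip(self.pixels, lo, hi)
        if (lo, hi) != (0.0, 255.0):
            px = (px - lo) / (hi - lo) * 255.0
        return np.rint(px).astype(np.uint8)

    def tagged(self, stage: str) -> "ImageSlice":
        meta = dict(self.metadata)
        meta["stage"] = stage
        return ImageSlice(self.pixels.copy(), self.value_range, meta)


def as_image(obj, value_range=(0.0, 255.0)) -> ImageSlice:
    """Coerce an array or ImageSlice to an ImageSlice."""
    if isinstance(obj, ImageSlice):
        return obj
    return ImageSlice(np.asarray(obj, dtype=np.float64), value_range)
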