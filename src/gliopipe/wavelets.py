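"""Separable 2-D discrete wavelet transform.

Implements the analysis filter bank d_{i,j} = sum_s p(s) h*(s - 2j) (and the
high-pass counterpart with g) as circular (periodized) convolution with
stride-2 downsampling, applied separably along rows and columns. One level
splits an image into four sub-bands — LL (approximation), LH (horizontal
detail), HL (vertical detail), HH (diagonal detail) — each of exactly half
the side; further levels recurse on LL.

Periodization keeps the transform exactly orthogonal for orthonormal filters
(Haar, Daubechies), so energy is conserved to machine precision and the
inverse reconstructs the input exactly; a 'symmetric' half-point extension is
also available for analysis only. Supported wavelets: 'haar' and 'db4' (the
4-tap Daubechies filter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SQRT2 = np.sqrt(2.0)
_SQRT3 = np.sqrt(3.0)

#: orthonormal low-pass (scaling) filters
_FILTERS = {
    "haar": np.array([1.0, 1.0]) / _SQRT2,
    "db4": np.array(
        [1.0 + _SQRT3, 3.0 + _SQRT3, 3.0 - _SQRT3, 1.0 - _SQRT3]
    ) / (4.0 * _SQRT2),
}

BAND_NAMES = ("LL", "LH", "HL", "HH")


def filters(wavelet: str):
    """Return (low-pass h, high-pass g) analysis filters, g the QMF of h."""
    if wavelet not in _FILTERS:
        raise ValueError(f"unknown wavelet {wavelet!r}; choose from {sorted(_FILTERS)}")
    h = _FILTERS[wavelet]
    g = (h[::-1] * (-1.0) ** np.arange(h.size))  # quadrature mirror
    return h, g


@dataclass
class SubbandSet:
    """DWT products per level: bands[level]['LL'|'LH'|'HL'|'HH'].

    Level keys run 1..levels; ``bands[L]['LL']`` for the deepest level L is
    the final approximation, while shallower LL bands are the intermediate
    approximations that were further decomposed.
    """

    bands: dict
    wavelet: str
    levels: int
    mode: str = "periodization"

    def band(self, name: str) -> np.ndarray:
        """Fetch a band by tag like 'LL1' or 'HL2'."""
        return self.bands[int(name[2:])][name[:2]]


def _analysis_1d(x: np.ndarray, filt: np.ndarray, mode: str, axis: int):
    """Stride-2 filtered decimation along ``axis``."""
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    taps = filt.size
    if mode == "periodization":
        if n % 2:
            raise ValueError("periodization requires an even length")
        idx = (2 * np.arange(n // 2)[:, None] + np.arange(taps)[None, :]) % n
        out = x[..., idx] @ filt
    elif mode == "symmetric":
        ext = np.concatenate(
            [x[..., taps - 1:: -1], x, x[..., : -taps - 1: -1]], axis=-1
        )
        full = np.apply_along_axis(
            lambda v: np.convolve(v, filt[::-1], mode="valid"), -1, ext
        )
        out = full[..., 1::2][..., : (n + taps - 1) // 2]
    else:
        raise ValueError(f"unknown extension mode {mode!r}")
    return np.moveaxis(out, -1, axis)


def _synthesis_1d(a: np.ndarray, d: np.ndarray, wavelet: str, axis: int):
    """Inverse of the periodized analysis step (transpose of an orthogonal map)."""
    h, g = filters(wavelet)
    a = np.moveaxis(a, axis, -1)
    d = np.moveaxis(d, axis, -1)
    n = 2 * a.shape[-1]
    taps = h.size
    x = np.zeros(a.shape[:-1] + (n,))
    for m in range(taps):
        pos = (2 * np.arange(a.shape[-1]) + m) % n
        np.add.at(x, (..., pos), a * h[m] + d * g[m])
    return np.moveaxis(x, -1, axis)


def dwt2_level(image: np.ndarray, wavelet: str = "haar",
               mode: str = "periodization"):
    """One analysis level: returns dict with LL, LH, HL, HH."""
    h, g = filters(wavelet)
    lo = _analysis_1d(image, h, mode, axis=1)   # filter along rows (x)
    hi = _analysis_1d(image, g, mode, axis=1)
    return {
        "LL": _analysis_1d(lo, h, mode, axis=0),
        "LH": _analysis_1d(hi, h, mode, axis=0),  # horizontal detail
        "HL": _analysis_1d(lo, g, mode, axis=0),  # vertical detail
        "HH": _analysis_1d(hi, g, mode, axis=0),
    }


def dwt2(image, wavelet: str = "haar", levels: int = 2,
         mode: str = "periodization") -> SubbandSet:
    """Multi-level separable 2-D DWT.

    Each level halves both sides; the input sides must be divisible by
    ``2**levels`` under periodization.
    """
    arr = np.asarray(getattr(image, "pixels", image), dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("dwt2 expects a 2-D image")
    if min(arr.shape) < 2**levels:
        raise ValueError(
            f"image sides {arr.shape} too small for {levels} levels "
            f"(need >= {2**levels})"
        )
    if mode == "periodization" and any(s % 2**levels for s in arr.shape):
        raise ValueError(
            f"image sides {arr.shape} must be divisible by 2**levels = {2**levels}"
        )
    bands = {}
    current = arr
    for lev in range(1, levels + 1):
        bands[lev] = dwt2_level(current, wavelet, mode)
        current = bands[lev]["LL"]
    return SubbandSet(bands, wavelet, levels, mode)


def idwt2_level(bands: dict, wavelet: str = "haar") -> np.ndarray:
    """Invert one periodized analysis level."""
    lo = _synthesis_1d(bands["LL"], bands["HL"], wavelet, axis=0)
    hi = _synthesis_1d(bands["LH"], bands["HH"], wavelet, axis=0)
    return _synthesis_1d(lo, hi, wavelet, axis=1)


def idwt2(subbands: SubbandSet) -> np.ndarray:
    """Reconstruct the input from an untouched periodized SubbandSet."""
    if subbands.mode != "periodization":
        raise NotImplementedError("inverse is implemented for periodization only")
    current = subbands.bands[subbands.levels]["LL"]
    for lev in range(subbands.levels, 0, -1):
        b = dict(subbands.bands[lev])
        b["LL"] = current
        current = idwt2_level(b, subbands.wavelet)
    return current
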