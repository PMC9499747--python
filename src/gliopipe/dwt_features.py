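"""Statistical texture features on DWT sub-bands.

A two-level DWT is applied to the (optionally tumor-masked) slice and six
statistics are computed on the LL and HL sub-bands of both levels — the
approximation plus the vertical-detail band, the combination found to carry
the most discriminative texture — giving a fixed 24-feature vector in the
order (LL1, HL1, LL2, HL2) x (mean, std, variance_mean, idm, rms, smoothness).

Feature definitions over an m x n coefficient grid f(x, y):

* ``mean``           sum of all values / (m*n)
* ``std``            population standard deviation about the mean
* ``variance_mean``  mean over rows of the per-row (sample) variance
* ``idm``            inverse difference moment,
                     sum_x sum_y f(x, y) / (1 + (x - y)^2) over grid
                     coordinates (not a co-occurrence statistic)
* ``rms``            sqrt(sum f^2 / (m*n))
* ``smoothness``     1 - 1/(1 + sum f)

``idm`` and ``smoothness`` keep these literal forms by default; with
``strict_formulas=False`` the conventional smoothness 1 - 1/(1 + sigma^2)
is substituted (co-occurrence-based homogeneity remains out of scope).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .image import as_image
from .wavelets import dwt2

FEATURE_NAMES = ("mean", "std", "variance_mean", "idm", "rms", "smoothness")
DEFAULT_BANDS = ("LL1", "HL1", "LL2", "HL2")


def subband_statistics(band, strict_formulas: bool = True) -> dict:
    """The six statistics of a single coefficient grid, as a named dict."""
    f = np.asarray(band, dtype=np.float64)
    if f.size == 0:
        raise ValueError("empty coefficient grid")
    if f.ndim != 2:
        raise ValueError("expected a 2-D coefficient grid")
    m, n = f.shape
    mn = m * n
    total = f.sum()
    mean = total / mn
    var = np.mean((f - mean) ** 2)
    std = np.sqrt(var)
    # per-row sample variance (rows of length 1 contribute 0)
    if n > 1:
        row_means = f.mean(axis=1, keepdims=True)
        row_vars = ((f - row_means) ** 2).sum(axis=1) / (n - 1)
    else:
        row_vars = np.zeros(m)
    variance_mean = row_vars.mean()
    x = np.arange(m)[:, None]
    y = np.arange(n)[None, :]
    idm = float((f / (1.0 + (x - y) ** 2)).sum())
    rms = np.sqrt((f**2).sum() / mn)
    if strict_formulas:
        smoothness = 1.0 - 1.0 / (1.0 + total)
    else:
        smoothness = 1.0 - 1.0 / (1.0 + var)
    return {
        "mean": float(mean),
        "std": float(std),
        "variance_mean": float(variance_mean),
        "idm": idm,
        "rms": float(rms),
        "smoothness": float(smoothness),
    }


def extract_feature_vector(image, wavelet: str = "haar", levels: int = 2,
                           bands=DEFAULT_BANDS, strict_formulas: bool = True,
                           mask=None) -> dict:
    """Concatenated sub-band features of one slice, as an ordered dict.

    With a ``mask``, intensities outside it are zeroed before the transform
    (the default pipeline passes the GA tumor mask).
    """
    img = as_image(image)
    px = img.pixels
    if mask is not None:
        px = np.where(np.asarray(mask, bool), px, 0.0)
    sb = dwt2(px, wavelet=wavelet, levels=levels)
    out = {}
    for tag in bands:
        stats = subband_statistics(sb.band(tag), strict_formulas=strict_formulas)
        for name in FEATURE_NAMES:
            out[f"{tag}_{name}"] = stats[name]
    return out


class DWTFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping a stack of slices to the 24-column feature matrix.

    ``X`` may be an array of shape ``(n_images, H, W)`` or a sequence of 2-D
    arrays/ImageSlices. Stateless: ``fit`` only records the feature names.
    """

    def __init__(self, wavelet="haar", levels=2, bands=DEFAULT_BANDS,
                 strict_formulas=True):
        self.wavelet = wavelet
        self.levels = levels
        self.bands = bands
        self.strict_formulas = strict_formulas

    def fit(self, X, y=None):
        self.feature_names_out_ = [
            f"{tag}_{name}" for tag in self.bands for name in FEATURE_NAMES
        ]
        return self

    def transform(self, X, masks=None):
        if not hasattr(self, "feature_names_out_"):
            self.fit(X)
        rows = []
        for i, img in enumerate(X):
            mask = None if masks is None else masks[i]
            feats = extract_feature_vector(
                img, wavelet=self.wavelet, levels=self.levels,
                bands=self.bands, strict_formulas=self.strict_formulas, mask=mask,
            )
            rows.append([feats[k] for k in self.feature_names_out_])
        return np.asarray(rows, dtype=np.float64)

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "feature_names_out_"):
            self.fit(None)
        return np.asarray(self.feature_names_out_, dtype=object)
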