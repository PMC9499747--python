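"""Seeded synthetic head-phantom generator.

Produces 2-D brain-MRI-like slices (head ellipse, bright skull ring, textured
brain tissue, class-dependent tumor blob) together with ground-truth brain and
tumor masks and a class label, so every downstream stage of the pipeline can be
exercised and scored without any clinical data.

Tumor classes carry invented but learnable image signatures:

* ``AST`` (astrocytoma)       — diffuse, low-contrast, Gaussian-tapered blob;
* ``OLI`` (oligodendroglioma) — medium-contrast, smooth-edged blob;
* ``GBM`` (glioblastoma)      — high-contrast blob with an irregular,
  ring-enhancing (bright-rim) boundary.

These signatures are stand-ins: real tumor appearance is far more variable and
depends on the MR sequence. They exist only so that segmentation overlap and
classification accuracy are meaningful quantities on synthetic data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import ImageSlice

TUMOR_CLASSES = ("AST", "GBM", "OLI")
NO_TUMOR_LABEL = "no tumor"
ALL_LABELS = TUMOR_CLASSES + (NO_TUMOR_LABEL,)

#: default class-dependent tumor intensity offset above the tissue mean
CLASS_OFFSETS = {"AST": 25.0, "OLI": 50.0, "GBM": 75.0}
#: default class-dependent boundary irregularity (harmonic amplitude)
CLASS_IRREGULARITY = {"AST": 0.06, "OLI": 0.08, "GBM": 0.25}

#: parameter ranges used by :func:`generate_dataset` when randomising specs
DEFAULT_SPEC_RANGES = {
    "radius_frac": (0.10, 0.18),
    "centre_max_offset": 0.40,
    "intensity_offset": {
        "AST": (20.0, 30.0),
        "OLI": (45.0, 55.0),
        "GBM": (70.0, 80.0),
    },
}


@dataclass
class SkullRingSpec:
    """Bright cranial ring, as fractions of the head's elliptical radius."""

    inner: float = 0.84
    outer: float = 0.95
    intensity: float = 220.0


@dataclass
class TissueSpec:
    """Brain interior: mean grey level, pixel texture noise, smooth bias field."""

    mean: float = 110.0
    texture_sd: float = 8.0
    bias_amplitude: float = 10.0


@dataclass
class TumorSpec:
    present: bool = True
    label: str = "GBM"
    #: centre offset from the head centre, in units of the head semi-axes
    centre: tuple = (-0.12, 0.18)
    #: blob radius as a fraction of the smaller head semi-axis
    radius_frac: float = 0.14
    #: added intensity above the tissue mean; None = class default
    intensity_offset: float | None = None
    #: boundary harmonic amplitude; None = class default
    irregularity: float | None = None


@dataclass
class PhantomSpec:
    image_side: int = 256
    skull_ring: SkullRingSpec = field(default_factory=SkullRingSpec)
    brain_tissue: TissueSpec = field(default_factory=TissueSpec)
    tumor: TumorSpec = field(default_factory=TumorSpec)
    noise_sd: float = 4.0
    seed: int = 0

    def validate(self):
        if self.image_side <= 0:
            raise ValueError("image_side must be positive")
        if not (0.0 < self.skull_ring.inner < self.skull_ring.outer < 1.0):
            raise ValueError("skull ring radii must satisfy 0 < inner < outer < 1")
        if self.tumor.present:
            if self.tumor.label not in TUMOR_CLASSES:
                raise ValueError(
                    f"tumor label must be one of {TUMOR_CLASSES}, "
                    f"got {self.tumor.label!r}"
                )
            if not (0.0 < self.tumor.radius_frac < 1.0):
                raise ValueError("tumor radius_frac must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PhantomSample:
    """A generated slice plus its ground truth."""

    image: ImageSlice
    brain_mask: np.ndarray
    tumor_mask: np.ndarray
    label: str
    spec: PhantomSpec


# inner edge of brain tissue, as a fraction of the head radius; the gap up to
# the skull ring stays near background so thresholding can separate the two
_BRAIN_FRAC = 0.78
_GAP_INTENSITY = 5.0


def _elliptical_rho(side: int):
    """Normalised elliptical radius field: 1.0 on the head outline."""
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    a = 0.46 * side  # vertical semi-axis
    b = 0.40 * side  # horizontal semi-axis
    return np.sqrt(((yy - c) / a) ** 2 + ((xx - c) / b) ** 2), (c, a, b)


def _smooth_field(rng: np.random.Generator, side: int) -> np.ndarray:
    """Low-frequency random field in [-1, 1], for the bias field."""
    coarse = rng.standard_normal((4, 4))
    fine = ndimage.zoom(coarse, side / 4.0, order=3, mode="nearest")
    fine = fine[:side, :side]
    span = np.abs(fine).max()
    return fine / span if span > 0 else fine


def _tumor_profile(spec: PhantomSpec, rho_geom, rng: np.random.Generator):
    """Additive tumor intensity field and binary tumor mask."""
    t = spec.tumor
    side = spec.image_side
    c, a, b = rho_geom
    cy = c + t.centre[0] * a
    cx = c + t.centre[1] * b
    r0 = t.radius_frac * min(a, b)

    yy, xx = np.mgrid[0:side, 0:side]
    dy, dx = yy - cy, xx - cx
    d = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    irr = t.irregularity if t.irregularity is not None else CLASS_IRREGULARITY[t.label]
    # irregular boundary: radius modulated by low-order harmonics
    boundary = np.full_like(d, r0)
    for k in range(2, 6):
        amp = irr * rng.uniform(0.3, 1.0) / (k - 1)
        phase = rng.uniform(0, 2 * math.pi)
        boundary = boundary + r0 * amp * np.cos(k * theta + phase)
    boundary = np.maximum(boundary, 0.3 * r0)

    mask = d <= boundary
    offset = t.intensity_offset if t.intensity_offset is not None else CLASS_OFFSETS[t.label]
    u = np.where(mask, d / np.maximum(boundary, 1e-9), 1.0)  # 0 centre -> 1 edge

    if t.label == "AST":
        # diffuse: Gaussian taper, never reaches full offset at the rim
        profile = offset * np.exp(-((u / 0.6) ** 2)) * mask
    elif t.label == "OLI":
        # smooth plateau with a soft shoulder
        shoulder = np.clip((1.0 - u) / 0.25, 0.0, 1.0)
        profile = offset * shoulder * (2 - shoulder) * mask  # smoothstep-ish
    else:  # GBM: enhancing rim over a dimmer core
        core = 0.55 * offset * (u < 0.65)
        rim = 1.5 * offset * ((u >= 0.65) & mask)
        profile = (core + rim) * mask
    return profile.astype(np.float64), mask


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom slice from its spec; bit-identical under seed.

    Raises
    ------
    ValueError
        If the spec is invalid or the tumor geometry does not fit inside
        the brain tissue region.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side
    rho, geom = _elliptical_rho(side)

    brain_mask = rho <= _BRAIN_FRAC
    ring = (rho >= spec.skull_ring.inner) & (rho <= spec.skull_ring.outer)
    gap = (rho > _BRAIN_FRAC) & (rho < spec.skull_ring.inner)

    tissue = spec.brain_tissue
    img = np.zeros((side, side), dtype=np.float64)
    img[brain_mask] = tissue.mean
    if tissue.texture_sd > 0:
        img[brain_mask] += rng.normal(0.0, tissue.texture_sd, brain_mask.sum())
    if tissue.bias_amplitude > 0:
        img[brain_mask] += (tissue.bias_amplitude * _smooth_field(rng, side))[brain_mask]
    img[gap] = _GAP_INTENSITY
    img[ring] = spec.skull_ring.intensity

    if spec.tumor.present:
        profile, tumor_mask = _tumor_profile(spec, geom, rng)
        if np.any(tumor_mask & ~brain_mask):
            raise ValueError(
                "tumor geometry extends outside the brain tissue region; "
                "reduce radius_frac or move centre closer to the head centre"
            )
        img += profile
        label = spec.tumor.label
    else:
        tumor_mask = np.zeros((side, side), dtype=bool)
        label = NO_TUMOR_LABEL

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 255.0)

    image = ImageSlice(img, (0.0, 255.0), {"stage": "phantom", "label": label})
    return PhantomSample(image, brain_mask, tumor_mask, label, spec)


def _flat_spec_fields(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    flat = {
        "image_side": d["image_side"],
        "noise_sd": d["noise_sd"],
        "seed": d["seed"],
        "tissue_mean": d["brain_tissue"]["mean"],
        "texture_sd": d["brain_tissue"]["texture_sd"],
        "bias_amplitude": d["brain_tissue"]["bias_amplitude"],
        "tumor_present": d["tumor"]["present"],
        "tumor_label": d["tumor"]["label"] if d["tumor"]["present"] else NO_TUMOR_LABEL,
        "tumor_centre_y": d["tumor"]["centre"][0],
        "tumor_centre_x": d["tumor"]["centre"][1],
        "tumor_radius_frac": d["tumor"]["radius_frac"],
        "tumor_intensity_offset": (
            d["tumor"]["intensity_offset"]
            if d["tumor"]["intensity_offset"] is not None
            else (CLASS_OFFSETS.get(d["tumor"]["label"], np.nan) if d["tumor"]["present"] else np.nan)
        ),
    }
    return flat


def generate_dataset(
    n_per_class: int,
    spec_ranges: dict | None = None,
    seed: int = 0,
    image_side: int = 256,
):
    """Generate a balanced labelled phantom set over AST/GBM/OLI/no-tumor.

    Parameters
    ----------
    n_per_class : int
        Samples per label (three tumor classes plus the no-tumor class, so
        the returned set has ``4 * n_per_class`` samples).
    spec_ranges : dict, optional
        Randomisation ranges; see :data:`DEFAULT_SPEC_RANGES`. Tumor radius
        and class-conditional intensity offsets are drawn uniformly from the
        stated intervals, centres uniformly in a disc.
    seed : int
        Master seed; per-sample seeds are spawned from it, so two calls with
        the same arguments return identical samples and manifests.
    image_side : int
        Side of the square phantom in pixels.

    Returns
    -------
    samples : list of PhantomSample
    manifest : pandas.DataFrame
        One row per sample recording label, seed and every spec field.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ranges = dict(DEFAULT_SPEC_RANGES)
    if spec_ranges:
        ranges.update(spec_ranges)

    master = np.random.default_rng(seed)
    samples, rows = [], []
    for label in ALL_LABELS:
        for i in range(n_per_class):
            sample_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sample_seed)
            if label == NO_TUMOR_LABEL:
                tumor = TumorSpec(present=False)
            else:
                r = rng.uniform(*ranges["radius_frac"])
                lo, hi = ranges["intensity_offset"][label]
                offset = rng.uniform(lo, hi)
                # centre uniform in a disc small enough that the blob fits
                max_c = min(ranges["centre_max_offset"], _BRAIN_FRAC - 1.3 * r / 0.40)
                max_c = max(max_c, 0.0)
                ang = rng.uniform(0, 2 * math.pi)
                rad = max_c * math.sqrt(rng.uniform(0, 1))
                tumor = TumorSpec(
                    present=True,
                    label=label,
                    centre=(rad * math.sin(ang), rad * math.cos(ang)),
                    radius_frac=r,
                    intensity_offset=offset,
                )
            spec = PhantomSpec(image_side=image_side, tumor=tumor, seed=sample_seed)
            sample = generate_phantom(spec)
            samples.append(sample)
            row = {"index": len(samples) - 1, "label": sample.label}
            row.update(_flat_spec_fields(spec))
            rows.append(row)
    manifest = pd.DataFrame(rows)
    return samples, manifest


def render_rgb(image: ImageSlice, weight_sum: float = 1.03) -> np.ndarray:
    """Render a greyscale slice to 3-channel 8-bit RGB.

    Channels are equal and pre-divided by the greyscale conversion weight sum
    so that converting back with the pipeline's channel weights (0.31, 0.57,
    0.15) recovers the source grey level to within one grey level.
    """
    g = image.to_uint8().astype(np.float64)
    ch = np.rint(np.clip(g / weight_sum, 0, 255)).astype(np.uint8)
    return np.stack([ch, ch, ch], axis=-1)
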