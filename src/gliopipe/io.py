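"""Reading and writing images for the pipeline stages.

PNG/TIFF go through imageio; single axial slices can be pulled out of NIfTI
volumes through nibabel. Everything becomes an :class:`ImageSlice` (2-D) or
an ``(H, W, 3)`` array for colour input.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .image import ImageSlice

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path, nifti_slice: int | None = None):
    """Read a 2-D slice (grey -> ImageSlice, colour -> (H, W, 3) array).

    For NIfTI volumes, ``nifti_slice`` selects the axial index (defaults to
    the middle slice); intensities are min-max rescaled to [0, 255].
    """
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
        if vol.ndim < 3:
            data = vol
        else:
            k = vol.shape[2] // 2 if nifti_slice is None else nifti_slice
            data = vol[:, :, k]
        span = np.ptp(data)
        if span > 0:
            data = (data - data.min()) / span * 255.0
        return ImageSlice(data, (0.0, 255.0), {"source": str(path)})
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if arr.shape[-1] == 4:
            arr = arr[..., :3]
        return arr.astype(np.float64)
    return ImageSlice(arr.astype(np.float64), (0.0, 255.0), {"source": str(path)})


def write_png(path, image) -> None:
    """Write an ImageSlice, 2-D array or boolean mask as an 8-bit PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(image, ImageSlice):
        arr = image.to_uint8()
    else:
        arr = np.asarray(image)
        if arr.dtype == bool:
            arr = arr.astype(np.uint8) * 255
        else:
            arr = np.clip(arr, 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)
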