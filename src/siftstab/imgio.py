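"""Reading 2D grayscale images: PNG/TIFF and single-frame DICOM.

All readers return a float array min-max normalized to [0, 1]; DICOM data
have the modality rescale (slope/intercept) applied first.
"""

from __future__ import annotations

import pathlib

import numpy as np


def normalize01(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        return (img - lo) / (hi - lo)
    return np.zeros_like(img)


def read_image(path) -> np.ndarray:
    """Read PNG/TIFF/DICOM as a [0, 1] grayscale raster."""
    path = pathlib.Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        return _read_dicom(path)
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    return normalize01(arr)


def _read_dicom(path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-frame 2D DICOM, got shape {arr.shape}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return normalize01(arr * slope + intercept)


def write_png(path, img: np.ndarray, bits: int = 16) -> None:
    import imageio.v3 as iio

    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    if bits == 16:
        iio.imwrite(path, (img * 65535).astype(np.uint16))
    elif bits == 8:
        iio.imwrite(path, (img * 255).astype(np.uint8))
    else:
        raise ValueError("bits must be 8 or 16")
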