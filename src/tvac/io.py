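"""Reading radiographs (DICOM / PNG / TIFF) and writing masks and tables."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom

__all__ = ["read_image", "write_image", "write_mask", "read_mask"]

_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}


def _read_dicom(path: Path) -> np.ndarray:
    ds = pydicom.dcmread(path)
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise ValueError(f"multi-frame DICOM is not supported: {path}")
    try:
        pixels = ds.pixel_array.astype(float)
    except Exception as exc:
        raise ValueError(f"cannot decode pixel data in {path}: {exc}") from exc
    if pixels.ndim != 2:
        raise ValueError(f"expected single-frame grayscale DICOM, got shape {pixels.shape}: {path}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = pixels * slope + intercept
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        pixels = pixels.max() - pixels  # stored inverted: low value = bright
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale radiograph as a [0, 1] float image.

    DICOM: rescale slope/intercept applied, MONOCHROME1 inverted so that
    0 = air-dark, then min-max scaled. PNG/TIFF: divided by the bit-depth
    maximum (255 or 65535).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() in _DICOM_SUFFIXES:
        return _read_dicom(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        raise ValueError(f"expected a grayscale image, got shape {arr.shape}: {path}")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    arr = arr.astype(float)
    return np.clip(arr, 0.0, 1.0)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] grayscale image as 8-bit PNG/TIFF."""
    arr = np.clip(np.asarray(img, dtype=float), 0, 1)
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground 255, background 0)."""
    arr = np.asarray(mask, dtype=bool)
    iio.imwrite(Path(path), (arr * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG; any nonzero pixel is foreground."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0
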