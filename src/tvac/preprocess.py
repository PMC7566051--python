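"""Intensity normalization and working-resolution resampling.

Radiographs arrive at wildly different resolutions and exposure settings.
All processing runs at a fixed working height of 512 rows (aspect ratio
preserved), and contrast is normalized with contrast-limited adaptive
histogram equalization (CLAHE) so that images from different scanners
occupy a comparable intensity range. CLAHE is applied after resampling so
its tile size is resolution-independent. Masks produced at working
resolution are mapped back to the original grid with nearest-neighbor
upsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.transform import resize

__all__ = ["WORKING_HEIGHT", "ResampleRecord", "apply_clahe", "to_working", "restore_mask"]

WORKING_HEIGHT = 512


@dataclass(frozen=True)
class ResampleRecord:
    original_size: tuple[int, int]
    working_size: tuple[int, int]
    scale: tuple[float, float]


def apply_clahe(
    img: np.ndarray, clip_limit: float = 0.01, tile_grid: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] image.

    ``clip_limit`` is the clipped fraction of each tile's histogram (0.01 ≈
    1% of the tile pixel count); ``tile_grid`` is the number of tiles along
    (rows, cols). Constant images are returned unchanged.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    if tile_grid[0] < 1 or tile_grid[1] < 1:
        raise ValueError("tile_grid dimensions must be >= 1")
    img = np.asarray(img, dtype=float)
    if np.ptp(img) == 0:
        return img.copy()
    kernel = (
        max(1, int(np.ceil(img.shape[0] / tile_grid[0]))),
        max(1, int(np.ceil(img.shape[1] / tile_grid[1]))),
    )
    out = equalize_adapthist(np.clip(img, 0, 1), kernel_size=kernel, clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0)


def to_working(img: np.ndarray) -> tuple[np.ndarray, ResampleRecord]:
    """Bilinearly resample to the 512-row working height, preserving aspect."""
    img = np.asarray(img, dtype=float)
    rows, cols = img.shape
    if rows < 32 or cols < 32:
        raise ValueError(f"image too small to process: {img.shape}")
    factor = WORKING_HEIGHT / rows
    new_cols = max(1, int(round(cols * factor)))
    rec = ResampleRecord(
        original_size=(rows, cols),
        working_size=(WORKING_HEIGHT, new_cols),
        scale=(factor, new_cols / cols),
    )
    if (rows, cols) == rec.working_size:
        return img.copy(), rec
    out = resize(
        img, rec.working_size, order=1, mode="edge", anti_aliasing=factor < 1, preserve_range=True
    )
    return np.clip(out, 0.0, 1.0), rec


def restore_mask(mask: np.ndarray, rec: ResampleRecord) -> np.ndarray:
    """Nearest-neighbor upsampling of a working-resolution mask to original size."""
    mask = np.asarray(mask)
    if mask.shape != rec.working_size:
        raise ValueError(f"mask shape {mask.shape} does not match working size {rec.working_size}")
    if rec.working_size == rec.original_size:
        return mask.astype(bool).copy()
    out = resize(
        mask.astype(float), rec.original_size, order=0, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    return out > 0.5
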