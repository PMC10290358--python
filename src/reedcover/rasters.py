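"""Thin raster I/O helpers: 8-bit PNG/TIFF images and float probability fields."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["read_image", "write_image", "write_probability", "write_mask"]


def read_image(path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF raster as a uint8 array (H x W or H x W x C)."""
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit raster, got dtype {arr.dtype}")
    return arr


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def write_probability(path, field: np.ndarray) -> None:
    """Write a [0, 1] probability field.

    ``.tif``/``.tiff`` targets get 32-bit float values as-is; ``.png``
    targets are scaled by 255 and rounded to 8 bits.
    """
    field = np.asarray(field, dtype=np.float32)
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, field)
    elif suffix == ".png":
        iio.imwrite(path, np.clip(np.rint(field * 255), 0, 255).astype(np.uint8))
    else:
        raise ValueError(f"unsupported probability format: {suffix}")


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG (reed = 255)."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
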