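"""Shared primitive types and raster conventions.

Rasters are plain ``numpy.ndarray``s with origin at the top-left corner,
row-major ``(y, x)`` indexing and y increasing downward — the coordinate
system of image files and of every published landmark definition this
package implements.

* grayscale image: 2-D ``uint8`` array, intensities in [0, 255]
* binary mask: 2-D ``bool`` array (persisted on disk as {0, 255} PNG)
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np


class Point(NamedTuple):
    """A pixel location: ``x`` is the column index, ``y`` the row index."""

    x: int
    y: int


def as_gray(image: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D uint8 grayscale raster."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale raster, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if not (np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255):
            raise ValueError("grayscale raster must hold integers in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_mask(mask: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D boolean mask.

    Accepts bool arrays, {0, 1} label arrays and {0, 255} persisted masks.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {arr.shape}")
    if arr.dtype == bool:
        return arr
    values = np.unique(arr)
    if not np.isin(values, (0, 1, 255)).all():
        raise ValueError(f"mask values must be binary, found {values[:10]}")
    return arr > 0


def mask_to_u8(mask: np.ndarray) -> np.ndarray:
    """Boolean mask -> {0, 255} uint8 raster for persistence."""
    return np.where(as_mask(mask), 255, 0).astype(np.uint8)
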