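"""Radiograph preprocessing: ROI crop, histogram equalization, median filter.

A lateral cephalogram is dominated by anatomy irrelevant to the sella
turcica, so the pipeline first crops a fixed pixel-coordinate region of
interest (the sella sits in a stable position on radiographs from a given
device), then enhances contrast with global histogram equalization and
removes impulse noise with a median filter.  The product is the fixed-size
(default 400 x 400) single-channel input of the segmentation network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .types import as_gray

#: Default region of interest for full-size (2884-wide) cephalograms,
#: as ``image[y0:y1, x0:x1]``.
DEFAULT_ROI = (500, 900, 1200, 1600)

# ITU-R BT.601 luma weights, the standard RGB->gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ROISpec:
    """Half-open crop window ``[y0, y1) x [x0, x1)``, origin top-left."""

    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        if not (0 <= self.y0 < self.y1 and 0 <= self.x0 < self.x1):
            raise ValueError(f"degenerate ROI {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y1 - self.y0, self.x1 - self.x0)


def load_grayscale(path: str | Path) -> np.ndarray:
    """Load a JPG/PNG/BMP image as a 2-D uint8 grayscale raster.

    Multi-channel images are reduced by standard luma weighting; an alpha
    channel, if present, is ignored.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize decoder errors
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = (arr.astype(np.float64) @ _LUMA).round()
    return np.clip(arr, 0, 255).astype(np.uint8)


def extract_roi(image: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Crop ``image[y0:y1, x0:x1]``; the ROI must lie inside the image."""
    image = as_gray(image)
    h, w = image.shape
    if roi.y1 > h or roi.x1 > w:
        raise ValueError(f"ROI {roi} exceeds image of size {w} x {h} (w x h)")
    return image[roi.y0 : roi.y1, roi.x0 : roi.x1].copy()


def equalize_histogram(image: np.ndarray) -> np.ndarray:
    """Global histogram equalization over 256 bins.

    Remaps intensity ``i`` to ``round(CDF(i) * 255)`` where ``CDF`` is the
    empirical cumulative distribution of the 256-bin histogram; the mapping
    is monotone, so intensity ordering is preserved.  A constant image is
    returned unchanged (no contrast to stretch).
    """
    image = as_gray(image)
    hist = np.bincount(image.ravel(), minlength=256)
    if np.count_nonzero(hist) <= 1:
        return image.copy()
    cdf = np.cumsum(hist) / image.size
    lut = np.clip(np.round(cdf * 255.0), 0, 255).astype(np.uint8)
    return lut[image]


def median_filter(image: np.ndarray, ksize: int = 5) -> np.ndarray:
    """Median filter with a ``ksize x ksize`` window and reflected borders."""
    if ksize < 3 or ksize % 2 == 0:
        raise ValueError(f"ksize must be an odd integer >= 3, got {ksize}")
    return ndimage.median_filter(as_gray(image), size=ksize, mode="reflect")


def preprocess(image: np.ndarray, roi: ROISpec | None = None, ksize: int = 5) -> np.ndarray:
    """Full preprocessing chain: crop ROI, equalize, median-filter."""
    if roi is None:
        roi = ROISpec(*DEFAULT_ROI)
    return median_filter(equalize_histogram(extract_roi(image, roi)), ksize=ksize)
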