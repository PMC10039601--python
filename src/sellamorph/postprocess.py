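"""Mask cleanup: keep only the largest connected foreground object.

The sella turcica is unique on a cephalogram, so any extra blobs in a
predicted mask are segmentation noise.  Objects are compared by the pixel
count of their *filled* outer boundary (holes count toward the area, as a
boundary-based criterion implies), and only the winner is preserved.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from .types import as_mask

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Return a mask holding only the largest 8-connected object.

    Area is the filled interior of each object's outer boundary, so an
    object's internal holes do not count against it.  Ties are broken
    deterministically: the object whose first pixel comes earliest in
    row-major scan order wins.  Raises ``ValueError`` on an empty mask,
    which signals segmentation failure upstream.
    """
    mask = as_mask(mask)
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        raise ValueError("no component found: mask has no foreground pixels")
    if n == 1:
        return mask.copy()
    # skimage labels components in row-major order of first encounter, so
    # the smallest label among maximal areas realizes the tie rule.
    best_label, best_area = 0, -1
    for lab in range(1, n + 1):
        area = int(ndimage.binary_fill_holes(labels == lab).sum())
        if area > best_area:
            best_label, best_area = lab, area
    return labels == best_label
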