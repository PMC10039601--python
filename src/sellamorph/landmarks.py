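"""Locate the four sella turcica landmarks on a postprocessed binary mask.

The four landmarks live on the contour of the segmented sella:

* **ADP** — the left-most contour point (the furthest point on the
  posterior inner wall, defining the anteroposterior diameter),
* **BPF** — the bottom-most contour point (the deepest point of the
  pituitary fossa floor),
* **TS / DS** — tuberculum and dorsum sellae, the two ends of the top
  chord.  They are corner points, so they are found with Shi-Tomasi
  minimum-eigenvalue corner detection on a Gaussian-smoothed rendering of
  the mask (smoothing suppresses spurious corners on the serrated binary
  edge).  Among the detected corners the two with the smallest ordinate
  (top-most; y grows downward) are kept, and the one with the larger
  abscissa is TS, the other DS.

Default corner-detector parameters (max corners 3, quality level 0.01,
minimum distance 40 px, block size 5) are tuned for 400 x 400 rasters;
scale ``min_distance`` with the raster when working at other sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import Point, as_mask

# clockwise 8-neighborhood offsets (dy, dx), starting North
_NEIGHBORS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


class LandmarkError(ValueError):
    """A landmark could not be located on the mask."""


@dataclass(frozen=True)
class CornerParams:
    """Shi-Tomasi detector settings (``goodFeaturesToTrack`` semantics)."""

    max_corners: int = 3
    quality_level: float = 0.01
    min_distance: float = 40.0
    block_size: int = 5

    def __post_init__(self) -> None:
        if self.max_corners < 2:
            raise ValueError("max_corners must be >= 2 (TS and DS are both needed)")
        if not 0 < self.quality_level <= 1:
            raise ValueError("quality_level must be in (0, 1]")
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError("block_size must be odd and >= 3")

    def scaled(self, factor: float) -> "CornerParams":
        """Rescale for a raster ``factor`` times the 400 px reference size.

        ``min_distance`` — the TS-DS suppression radius — scales linearly
        (at 128 px the default 40 px would suppress DS outright).  The
        block size stays put: shrinking the averaging window makes the
        response noisier on serrated predicted masks and buys nothing.
        """
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        return CornerParams(
            max_corners=self.max_corners,
            quality_level=self.quality_level,
            min_distance=self.min_distance * factor,
            block_size=self.block_size,
        )


@dataclass(frozen=True)
class SellaLandmarks:
    """The four named landmark pixels."""

    ts: Point
    ds: Point
    adp: Point
    bpf: Point

    def translated(self, dx: int, dy: int) -> "SellaLandmarks":
        return SellaLandmarks(
            *(Point(p.x + dx, p.y + dy) for p in (self.ts, self.ds, self.adp, self.bpf))
        )


def contour_points(mask: np.ndarray) -> list[Point]:
    """Ordered closed traversal of the outer boundary of the foreground.

    Moore-neighbor tracing, clockwise, starting from the first foreground
    pixel in row-major order.  Every returned point is a foreground pixel
    with at least one background (or out-of-image) neighbor.
    """
    mask = as_mask(mask)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise LandmarkError("contour of empty mask requested")
    padded = np.pad(mask, 1)
    start = (int(ys[0]) + 1, int(xs[0]) + 1)
    contour = [start]
    # came-from direction: we entered `start` from the West (background there)
    backtrack = (start[0], start[1] - 1)
    state0 = (start, backtrack)
    cur = start
    max_steps = 8 * ys.size + 16
    for _ in range(max_steps):
        dy, dx = backtrack[0] - cur[0], backtrack[1] - cur[1]
        k0 = _NEIGHBORS.index((dy, dx))
        nxt = None
        for j in range(1, 9):
            oy, ox = _NEIGHBORS[(k0 + j) % 8]
            cand = (cur[0] + oy, cur[1] + ox)
            if padded[cand]:
                nxt = cand
                prev_oy, prev_ox = _NEIGHBORS[(k0 + j - 1) % 8]
                backtrack = (cur[0] + prev_oy, cur[1] + prev_ox)
                break
        if nxt is None:  # isolated pixel
            break
        cur = nxt
        if (cur, backtrack) == state0:
            break
        contour.append(cur)
    return [Point(x - 1, y - 1) for (y, x) in contour]


def find_extrema(contour: list[Point]) -> tuple[Point, Point]:
    """(ADP, BPF): left-most and bottom-most contour points.

    Ties: left-most tie -> smallest y wins; bottom-most tie -> smallest x.
    """
    if not contour:
        raise LandmarkError("empty contour")
    xs = np.array([p.x for p in contour])
    ys = np.array([p.y for p in contour])
    adp = contour[int(np.lexsort((ys, xs))[0])]
    bpf = contour[int(np.lexsort((xs, -ys))[0])]
    return adp, bpf


def smooth_for_corners(mask: np.ndarray, sigma: float = 1.1) -> np.ndarray:
    """Gaussian-smooth a {0, 255} mask rendering for corner detection.

    Uses a 5 x 5 kernel at the default sigma (radius 2); returns a float
    image in [0, 255].  Smoothing is applied only for TS/DS detection —
    ADP/BPF are read off the raw mask contour.
    """
    img = np.where(as_mask(mask), 255.0, 0.0).astype(np.float32)
    radius = max(2, int(round(2 * sigma)))
    return ndimage.gaussian_filter(img, sigma=sigma, truncate=radius / sigma)


def _shi_tomasi_response(image: np.ndarray, block_size: int) -> np.ndarray:
    """Min-eigenvalue of the Sobel structure tensor, block-averaged."""
    img = np.asarray(image, dtype=np.float32)
    ix = ndimage.sobel(img, axis=1, mode="reflect")
    iy = ndimage.sobel(img, axis=0, mode="reflect")
    sxx = ndimage.uniform_filter(ix * ix, size=block_size, mode="reflect")
    syy = ndimage.uniform_filter(iy * iy, size=block_size, mode="reflect")
    sxy = ndimage.uniform_filter(ix * iy, size=block_size, mode="reflect")
    tr = sxx + syy
    det_root = np.sqrt((sxx - syy) ** 2 + 4.0 * sxy ** 2)
    return 0.5 * (tr - det_root)


def detect_corners(image: np.ndarray, params: CornerParams | None = None) -> list[Point]:
    """Shi-Tomasi corners, strongest first, at integer pixel precision.

    Candidates are 3x3 local maxima of the minimum-eigenvalue response at
    or above ``quality_level`` times the global maximum; they are accepted
    greedily in descending response subject to pairwise distance >=
    ``min_distance``, up to ``max_corners``.  Equal responses are broken
    in row-major order.
    """
    params = params or CornerParams()
    resp = _shi_tomasi_response(image, params.block_size)
    rmax = float(resp.max(initial=0.0))
    if rmax <= 0.0:
        raise LandmarkError("no corners found: flat corner response")
    local_max = resp >= ndimage.maximum_filter(resp, size=3, mode="reflect")
    cand = np.nonzero(local_max & (resp >= params.quality_level * rmax))
    cy, cx = cand
    order = np.lexsort((cx, cy, -resp[cand]))  # response desc, then row-major
    kept: list[Point] = []
    min_d2 = params.min_distance ** 2
    for i in order:
        p = Point(int(cx[i]), int(cy[i]))
        if all((p.x - q.x) ** 2 + (p.y - q.y) ** 2 >= min_d2 for q in kept):
            kept.append(p)
            if len(kept) == params.max_corners:
                break
    if not kept:
        raise LandmarkError("no corners found")
    return kept


def select_ts_ds(corners: list[Point]) -> tuple[Point, Point]:
    """Screen the two smallest-ordinate corners; larger abscissa is TS."""
    if len(corners) < 2:
        raise LandmarkError("landmarks not found: fewer than 2 corners detected")
    top_two = sorted(corners, key=lambda p: (p.y, p.x))[:2]
    ts, ds = sorted(top_two, key=lambda p: -p.x)
    return ts, ds


def locate_landmarks(mask: np.ndarray, params: CornerParams | None = None,
                     sigma: float = 1.1) -> SellaLandmarks:
    """Locate TS, DS, ADP and BPF on a single-component binary mask.

    ADP/BPF come from the raw contour extrema; TS/DS from corner detection
    on the Gaussian-smoothed mask.  A final sanity check requires
    ``TS.x > DS.x`` and both chord points above BPF; violations raise
    :class:`LandmarkError` rather than returning silent nonsense.
    """
    contour = contour_points(mask)
    adp, bpf = find_extrema(contour)
    try:
        corners = detect_corners(smooth_for_corners(mask, sigma=sigma), params)
        ts, ds = select_ts_ds(corners)
    except LandmarkError as exc:
        raise LandmarkError(f"TS/DS localization failed: {exc}") from exc
    if not (ts.x > ds.x and ts.y < bpf.y and ds.y < bpf.y):
        raise LandmarkError(
            f"landmarks not found: implausible geometry TS={ts} DS={ds} BPF={bpf}"
        )
    return SellaLandmarks(ts=ts, ds=ds, adp=adp, bpf=bpf)
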