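"""Synthetic sella-like shapes with exact raster ground truth.

Real cephalograms and their manual annotations are not redistributable,
so every pipeline stage is exercised on generated data instead.  The
generator draws a closed saddle ("nest") shape:

* a straight top chord from DS (left end) to TS (right end),
* a smooth wall descending from TS along the anterior side to BPF (the
  bottom-most point), along the floor to ADP (the left-most point, which
  bulges left of DS), and back up the posterior wall to DS.

The contour is a cubic spline through the landmark targets and three wall
waypoints; it is rasterized, filled, and the ground-truth landmarks are
then *recomputed from the raster* (exact left-most / bottom-most pixels,
nearest boundary pixels to the chord ends), so tests never argue with
sub-pixel rounding.  The radiograph renderer paints the wall as a bright
rim over a textured background with distractor arcs, then blurs and adds
noise — emulating the "nest bounded by a white line" appearance.

Geometry is sampled at a 400 px reference scale (TS-DS span 60-140 px,
depth 45-115 px, ADP bulge 5-25 px, rotation within ±5°) and
rejection-resampled until the implied Length lies in [4, 14] mm and
Diameter in [5, 16] mm at R = 0.1 — the range reported for human sellae.
Other canvas sizes scale the geometry proportionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import PchipInterpolator
from skimage import draw, measure as skmeasure

from .landmarks import SellaLandmarks, contour_points, find_extrema
from .measurement import LinearParameters, measure
from .types import Point, as_mask, mask_to_u8

REFERENCE_CANVAS = 400
LENGTH_RANGE_MM = (4.0, 14.0)
DIAMETER_RANGE_MM = (5.0, 16.0)


class GenerationError(RuntimeError):
    """A shape draw violated its landmark-role constraints."""


@dataclass(frozen=True)
class SellaShapeSpec:
    """Continuous control geometry of one synthetic sella (pixel units)."""

    canvas_size: int
    ts: tuple[float, float]
    ds: tuple[float, float]
    adp: tuple[float, float]
    bpf: tuple[float, float]
    waypoints: tuple[tuple[float, float], ...]  # anterior, floor, posterior
    rotation: float  # degrees, already applied to the stored points
    seed: int


@dataclass(frozen=True)
class SyntheticSample:
    """One generated (radiograph, mask, truth) triple."""

    image: np.ndarray
    mask: np.ndarray
    landmarks: SellaLandmarks
    true_params: LinearParameters


def _rotate(points: np.ndarray, center: np.ndarray, degrees: float) -> np.ndarray:
    t = math.radians(degrees)
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    return (points - center) @ rot.T + center


def sample_shape_spec(seed: int, canvas_size: int = REFERENCE_CANVAS) -> SellaShapeSpec:
    """Draw a random shape spec; deterministic in ``seed``.

    Rejection-resamples until the continuous control points imply a
    Length in [4, 14] mm and a Diameter in [5, 16] mm at the reference
    scale (R = 0.1 on a 400 px canvas).
    """
    rng = np.random.default_rng(seed)
    scale = canvas_size / REFERENCE_CANVAS
    for _ in range(200):
        span = rng.uniform(60, 140)
        depth = rng.uniform(45, 115)
        bulge = rng.uniform(5, 25)
        cx = rng.uniform(170, 230)
        cy = rng.uniform(100, 150)
        ts = np.array([cx + span / 2, cy + rng.uniform(-3, 3)])
        ds = np.array([cx - span / 2, cy + rng.uniform(-3, 3)])
        bpf = np.array([cx + rng.uniform(-0.15, 0.15) * span, cy + depth])
        adp = np.array([ds[0] - bulge, cy + rng.uniform(0.35, 0.55) * depth])
        w_anterior = np.array(
            [ts[0] + rng.uniform(-2, 8), cy + rng.uniform(0.45, 0.60) * depth]
        )
        w_floor = np.array(
            [
                adp[0] + rng.uniform(0.25, 0.40) * (bpf[0] - adp[0]),
                adp[1] + rng.uniform(0.75, 0.90) * (bpf[1] - adp[1]),
            ]
        )
        w_posterior = np.array(
            [ds[0] - rng.uniform(0.35, 0.60) * bulge, cy + rng.uniform(0.18, 0.30) * depth]
        )
        rotation = rng.uniform(-5, 5)
        pts = np.vstack([ts, ds, adp, bpf, w_anterior, w_floor, w_posterior])
        center = np.array([cx, cy + depth / 2])
        pts = _rotate(pts, center, rotation)
        ts, ds, adp, bpf, w_anterior, w_floor, w_posterior = pts

        length_mm = math.dist(ts, ds) * 0.1
        diameter_mm = math.dist(ts, adp) * 0.1
        ok = (
            LENGTH_RANGE_MM[0] <= length_mm <= LENGTH_RANGE_MM[1]
            and DIAMETER_RANGE_MM[0] <= diameter_mm <= DIAMETER_RANGE_MM[1]
            # landmark roles must hold with margin on the control points
            and adp[0] < min(p[0] for p in (ts, ds, bpf, w_anterior, w_floor, w_posterior)) - 2
            and bpf[1] > max(p[1] for p in (ts, ds, adp, w_anterior, w_floor, w_posterior)) + 2
            and max(ts[1], ds[1]) < min(p[1] for p in (adp, bpf, w_anterior, w_floor, w_posterior)) - 4
            and ds[0] < ts[0]
        )
        if ok:
            pts *= scale
            return SellaShapeSpec(
                canvas_size=canvas_size,
                ts=tuple(pts[0]),
                ds=tuple(pts[1]),
                adp=tuple(pts[2]),
                bpf=tuple(pts[3]),
                waypoints=(tuple(pts[4]), tuple(pts[5]), tuple(pts[6])),
                rotation=rotation,
                seed=seed,
            )
    raise GenerationError(f"could not sample a valid shape spec from seed {seed}")


def _wall_samples(spec: SellaShapeSpec, n: int = 600) -> np.ndarray:
    """Dense (n, 2) polyline TS -> anterior -> BPF -> floor -> ADP -> DS."""
    w_ant, w_floor, w_post = spec.waypoints
    knots = np.array([spec.ts, w_ant, spec.bpf, w_floor, spec.adp, w_post, spec.ds])
    seg = np.linalg.norm(np.diff(knots, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    # shape-preserving interpolant: per-coordinate extremes stay at knots,
    # so BPF really is bottom-most and ADP left-most on the curve
    spl = PchipInterpolator(t, knots, axis=0)
    return spl(np.linspace(0.0, t[-1], n))


def render_mask(spec: SellaShapeSpec) -> tuple[np.ndarray, SellaLandmarks]:
    """Rasterize the closed contour and return (mask, raster landmarks).

    The returned landmarks are recomputed from the raster: ADP is the
    left-most boundary pixel (tie: smallest y), BPF the bottom-most (tie:
    smallest x), TS/DS the boundary pixels nearest the continuous chord
    ends.  Raises :class:`GenerationError` if the raster violates the
    landmark roles.
    """
    n = spec.canvas_size
    wall = _wall_samples(spec)
    poly = np.vstack([wall, [spec.ts]])  # close chord DS -> TS
    rr, cc = draw.polygon(poly[:, 1], poly[:, 0], shape=(n, n))
    mask = np.zeros((n, n), dtype=bool)
    mask[rr, cc] = True
    # make sure the contour line itself is foreground
    wi = np.round(wall).astype(int)
    keep = (wi[:, 0] >= 0) & (wi[:, 0] < n) & (wi[:, 1] >= 0) & (wi[:, 1] < n)
    mask[wi[keep, 1], wi[keep, 0]] = True
    rr, cc = draw.line(*np.round([spec.ds[1], spec.ds[0], spec.ts[1], spec.ts[0]]).astype(int))
    mask[np.clip(rr, 0, n - 1), np.clip(cc, 0, n - 1)] = True
    mask = ndimage.binary_fill_holes(mask)

    if skmeasure.label(mask, connectivity=2).max() != 1:
        raise GenerationError("rasterized shape is not a single component")
    contour = contour_points(mask)
    adp, bpf = find_extrema(contour)
    pts = np.array([(p.x, p.y) for p in contour], dtype=float)
    ts = Point(*map(int, pts[np.linalg.norm(pts - spec.ts, axis=1).argmin()]))
    ds = Point(*map(int, pts[np.linalg.norm(pts - spec.ds, axis=1).argmin()]))
    # A near-flat floor or wall lets the raster extremum slide a few px
    # along the contour; ground truth is raster-defined, so this check only
    # guards against gross geometry violations.
    tol = max(4.0, 10.0 * spec.canvas_size / REFERENCE_CANVAS)
    if (
        math.dist(adp, spec.adp) > tol
        or math.dist(bpf, spec.bpf) > tol
        or math.dist(ts, spec.ts) > tol
        or math.dist(ds, spec.ds) > tol
    ):
        raise GenerationError("raster extrema drifted from their targets")
    if not (ts.x > ds.x and max(ts.y, ds.y) < bpf.y and adp.x < min(ts.x, ds.x)):
        raise GenerationError("raster landmarks violate their role constraints")
    return mask, SellaLandmarks(ts=ts, ds=ds, adp=adp, bpf=bpf)


def render_radiograph(
    spec: SellaShapeSpec,
    mask: np.ndarray,
    landmarks: SellaLandmarks,
    seed: int,
) -> np.ndarray:
    """Render a radiograph-like uint8 image for (mask, landmarks).

    Bright rim along the open wall (not the chord), darker fossa interior,
    low-frequency textured background with distractor arcs away from the
    sella, Gaussian blur, additive Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    n = spec.canvas_size
    mask = as_mask(mask)
    scale = n / REFERENCE_CANVAS

    # background: base level plus a smooth random field
    g = max(4, n // 32)
    field = ndimage.zoom(rng.normal(size=(g, g)), n / g, order=3)[:n, :n]
    img = rng.uniform(110, 150) + field * rng.uniform(8, 20)

    # distractor arcs outside the sella's (dilated) bounding box
    ys, xs = np.nonzero(mask)
    pad = int(10 * scale) + 2
    y0, y1 = ys.min() - pad, ys.max() + pad
    x0, x1 = xs.min() - pad, xs.max() + pad
    for _ in range(int(rng.integers(2, 5))):
        cy, cx = rng.uniform(0, n, size=2)
        radius = rng.uniform(20, 80) * scale
        rr, cc = draw.circle_perimeter(
            int(cy), int(cx), max(2, int(radius)), shape=(n, n)
        )
        outside = ~((rr >= y0) & (rr <= y1) & (cc >= x0) & (cc <= x1))
        img[rr[outside], cc[outside]] = rng.uniform(150, 220)

    # fossa interior darker than background
    img[mask] = rng.uniform(60, 90) + field[mask] * 5.0

    # bright rim along the open wall
    rim = np.zeros((n, n), dtype=bool)
    wi = np.round(_wall_samples(spec, n=1200)).astype(int)
    keep = (wi[:, 0] >= 0) & (wi[:, 0] < n) & (wi[:, 1] >= 0) & (wi[:, 1] < n)
    rim[wi[keep, 1], wi[keep, 0]] = True
    thickness = int(rng.integers(2, 5))
    rim = ndimage.binary_dilation(rim, iterations=max(1, round(thickness * scale / 2)))
    img[rim] = rng.uniform(190, 250)

    img = ndimage.gaussian_filter(img, sigma=rng.uniform(0.8, 1.4))
    img += rng.normal(0.0, rng.uniform(5, 15), size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def add_noise_spots(
    mask: np.ndarray,
    k: int,
    max_area: int = 20,
    seed: int = 0,
    min_gap: int = 5,
) -> np.ndarray:
    """Add ``k`` small disjoint foreground spots (area <= max_area each).

    Spots keep at least ``min_gap`` px of clearance from the main
    component and from each other, so connected-component analysis sees
    exactly ``k`` extra objects.  Raises :class:`GenerationError` if the
    spots cannot be placed.
    """
    mask = as_mask(mask)
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return mask.copy()
    rng = np.random.default_rng(seed)
    out = mask.copy()
    n_rows, n_cols = out.shape
    max_radius = max(1, int(math.sqrt(max_area / math.pi)))
    for _ in range(k):
        dist = ndimage.distance_transform_edt(~out)
        for attempt in range(300):
            r = int(rng.integers(1, max_radius + 1))
            cy = int(rng.integers(r + 1, n_rows - r - 1))
            cx = int(rng.integers(r + 1, n_cols - r - 1))
            rr, cc = draw.disk((cy, cx), r, shape=out.shape)
            if rr.size == 0 or rr.size > max_area:
                continue
            if dist[rr, cc].min() > min_gap + r:
                out[rr, cc] = True
                break
        else:
            raise GenerationError(f"could not place {k} disjoint noise spots")
    return out


def make_sample(
    seed: int,
    canvas_size: int = REFERENCE_CANVAS,
    r: float = 0.1,
    max_retries: int = 20,
) -> SyntheticSample:
    """Generate one sample, retrying fresh seeds on rasterization failure."""
    for attempt in range(max_retries):
        sub = np.random.default_rng([seed, attempt])
        spec_seed = int(sub.integers(0, 2**31))
        try:
            spec = sample_shape_spec(spec_seed, canvas_size=canvas_size)
            mask, lm = render_mask(spec)
        except GenerationError:
            continue
        image = render_radiograph(spec, mask, lm, seed=int(sub.integers(0, 2**31)))
        return SyntheticSample(image=image, mask=mask, landmarks=lm,
                               true_params=measure(lm, r))
    raise GenerationError(f"no valid sample from seed {seed} after {max_retries} tries")


MANIFEST_COLUMNS = [
    "image", "mask",
    "TS_x", "TS_y", "DS_x", "DS_y", "ADP_x", "ADP_y", "BPF_x", "BPF_y",
    "length_mm", "diameter_mm", "depth_mm",
]


def generate_dataset(
    n: int,
    seed: int,
    out_dir: str | Path,
    canvas_size: int = REFERENCE_CANVAS,
    r: float = 0.1,
) -> pd.DataFrame:
    """Write ``n`` (image, mask) PNG pairs plus a manifest CSV.

    Fully reproducible from ``seed``; returns the manifest frame whose
    ``length_mm``/``diameter_mm``/``depth_mm`` columns hold the exact
    measurements of the raster ground-truth landmarks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sample_seeds = rng.integers(0, 2**31, size=n)
    rows = []
    for i, s in enumerate(sample_seeds):
        sample = make_sample(int(s), canvas_size=canvas_size, r=r)
        image_name = f"image_{i:04d}.png"
        mask_name = f"mask_{i:04d}.png"
        iio.imwrite(out_dir / image_name, sample.image)
        iio.imwrite(out_dir / mask_name, mask_to_u8(sample.mask))
        lm = sample.landmarks
        rows.append(
            [image_name, mask_name,
             lm.ts.x, lm.ts.y, lm.ds.x, lm.ds.y,
             lm.adp.x, lm.adp.y, lm.bpf.x, lm.bpf.y,
             sample.true_params.length_mm,
             sample.true_params.diameter_mm,
             sample.true_params.depth_mm]
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
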