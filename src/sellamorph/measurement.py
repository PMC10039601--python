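"""Linear sella turcica parameters from the four landmarks.

With landmark pixel coordinates TS(x1, y1), DS(x2, y2), ADP(x3, y3),
BPF(x4, y4) and the image scale R (mm per pixel, 0.1 for standard
cephalograms digitized at 0.1 mm pixel pitch):

* Length   = |TS - DS| * R                    (top chord)
* Diameter = |TS - ADP| * R                   (anteroposterior diameter)
* Depth    = distance from BPF to the TS-DS line, * R

All three are non-negative millimetre quantities; full precision is kept
internally and values are conventionally reported to 2 decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .landmarks import SellaLandmarks
from .types import Point


@dataclass(frozen=True)
class LinearParameters:
    """Length, Diameter and Depth in millimetres, plus the scale used."""

    length_mm: float
    diameter_mm: float
    depth_mm: float
    scale_r: float

    def __post_init__(self) -> None:
        for v in (self.length_mm, self.diameter_mm, self.depth_mm):
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"linear parameters must be finite and >= 0, got {v}")

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(Length, Diameter, Depth) at reporting precision."""
        return (
            round(self.length_mm, ndigits),
            round(self.diameter_mm, ndigits),
            round(self.depth_mm, ndigits),
        )


def _check_scale(r: float) -> None:
    if not (math.isfinite(r) and r > 0):
        raise ValueError(f"scale R must be a positive mm/px factor, got {r}")


def compute_length(ts: Point, ds: Point, r: float = 0.1) -> float:
    """Length: Euclidean TS-DS distance in mm."""
    _check_scale(r)
    return math.hypot(ds.x - ts.x, ds.y - ts.y) * r


def compute_diameter(ts: Point, adp: Point, r: float = 0.1) -> float:
    """Anteroposterior diameter: Euclidean TS-ADP distance in mm."""
    _check_scale(r)
    return math.hypot(adp.x - ts.x, adp.y - ts.y) * r


def compute_depth(ts: Point, ds: Point, bpf: Point, r: float = 0.1) -> float:
    """Depth: perpendicular distance from BPF to the TS-DS line, in mm.

    Uses the standard point-to-line form
    ``|(y1-y2)x4 + (x2-x1)y4 + x1*y2 - y1*x2| / |TS - DS|``.
    """
    _check_scale(r)
    x1, y1 = ts
    x2, y2 = ds
    x4, y4 = bpf
    denom = math.hypot(x2 - x1, y2 - y1)
    if denom == 0:
        raise ValueError("TS and DS coincide: the chord line is degenerate")
    num = abs((y1 - y2) * x4 + (x2 - x1) * y4 + x1 * y2 - y1 * x2)
    return num / denom * r


def measure(lm: SellaLandmarks, r: float = 0.1) -> LinearParameters:
    """Bundle Length, Diameter and Depth for one landmark set."""
    return LinearParameters(
        length_mm=compute_length(lm.ts, lm.ds, r),
        diameter_mm=compute_diameter(lm.ts, lm.adp, r),
        depth_mm=compute_depth(lm.ts, lm.ds, lm.bpf, r),
        scale_r=r,
    )
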