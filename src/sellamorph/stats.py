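"""Agreement statistics between two measurement series.

For method comparison (manual vs automatic morphometry) the package
reports:

* the intraclass correlation coefficient, model ICC(2,1) — two-way
  random effects, absolute agreement, single measurement — computed from
  the two-rater mean-squares decomposition.  This is the standard choice
  when both the subjects and the two "raters" (measurement methods) are
  regarded as random samples and systematic offsets between methods
  should count against agreement;
* the interpretation bands: moderate (0.41, 0.60], substantial
  (0.60, 0.80], excellent (0.80, 1.00], below-moderate otherwise;
* Bland-Altman bias and 95% limits of agreement
  ``mean(d) ± 1.96 * SD(d)`` with ``d = b - a`` (new method minus
  reference) and the sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AgreementStats:
    """ICC with its interpretation band, plus Bland-Altman quantities."""

    icc: float
    icc_band: str
    bias: float
    loa_low: float
    loa_high: float
    within_loa: float  # fraction of differences inside [loa_low, loa_high]
    n: int


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise ValueError(f"need two equal-length 1-D series, got {a.shape} and {b.shape}")
    if a.size < 2:
        raise ValueError("at least 2 paired measurements are required")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("series contain non-finite values")
    return a, b


def icc(a, b) -> float:
    """ICC(2,1) between two equal-length measurement series.

    Mean squares come from the two-way layout with n subjects (rows) and
    k = 2 raters (columns):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))
    """
    a, b = _paired(a, b)
    x = np.column_stack([a, b])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom <= 0 or ss_total == 0:
        raise ValueError("ICC undefined: no variance in the paired data")
    # clamp float round-off (e.g. 1 + 2e-16 for perfectly equal series)
    return float(np.clip((msr - mse) / denom, -1.0, 1.0))


def interpret_icc(value: float) -> str:
    """Map an ICC value onto its agreement band."""
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"ICC must lie in [-1, 1], got {value}")
    if 0.80 < value <= 1.00:
        return "excellent"
    if 0.60 < value <= 0.80:
        return "substantial"
    if 0.41 < value <= 0.60:
        return "moderate"
    return "below-moderate"


def bland_altman(a, b) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high) of the differences ``b - a``."""
    a, b = _paired(a, b)
    d = b - a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def agreement_report(a, b) -> AgreementStats:
    """Full agreement bundle between reference series a and test series b."""
    a, b = _paired(a, b)
    value = icc(a, b)
    bias, lo, hi = bland_altman(a, b)
    d = b - a
    within = float(np.mean((d >= lo) & (d <= hi)))
    return AgreementStats(
        icc=value,
        icc_band=interpret_icc(value),
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        within_loa=within,
        n=int(a.size),
    )
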