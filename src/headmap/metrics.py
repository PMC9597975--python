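"""Validation metrics for mapping models.

The headline metrics are mean squared error and mean absolute error of
predicted against observed utilities, the proportions of predictions
deviating from observed values by less than 0.10 and 0.25 (strict
inequality by default), a summary of the prediction distribution, and
an error breakdown across bands of the observed utility range — the
latter exposes the systematic bias mappers show at the tails of the
utility distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = ["PerformanceReport", "RangeBin", "compute_metrics", "errors_by_range",
           "EQ5D_BINS", "SF6D_BINS"]

# Range bands keyed by observed utility. Bands are left-closed,
# right-open; the outermost bands absorb anything beyond their edge so
# the bands always partition the sample (the SF-6D floor 0.345 falls in
# the band labelled "0.35 - 0.5").
EQ5D_BINS: List[Tuple[str, float, float]] = (
    [("< 0", -np.inf, 0.0)]
    + [(f"{i / 10:g} - {(i + 1) / 10:g}", i / 10, (i + 1) / 10) for i in range(9)]
    + [("0.9 - 1.0", 0.9, np.inf)]
)
SF6D_BINS: List[Tuple[str, float, float]] = (
    [("0.35 - 0.5", -np.inf, 0.5)]
    + [(f"{i / 10:g} - {(i + 1) / 10:g}", i / 10, (i + 1) / 10) for i in range(5, 9)]
    + [("0.9 - 1.0", 0.9, np.inf)]
)


@dataclass
class RangeBin:
    label: str
    n: int
    mse: Optional[float]
    mae: Optional[float]


@dataclass
class PerformanceReport:
    n: int
    mean: float
    sd: float
    min: float
    p25: float
    median: float
    p75: float
    max: float
    mse: float
    mae: float
    pct_within_010: float
    pct_within_025: float
    by_range: List[RangeBin] = field(default_factory=list)


def _check_pair(observed, predicted) -> Tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: observed {o.shape}, predicted {p.shape}")
    if o.size == 0:
        raise ValueError("need at least one observation")
    return o, p


def compute_metrics(observed, predicted, strict: bool = True) -> PerformanceReport:
    """MSE, MAE, threshold proportions and a prediction summary.

    ``strict=True`` counts |error| strictly below each threshold, so an
    absolute error of exactly 0.10 does NOT count as within 0.10;
    ``strict=False`` switches to ≤ for sensitivity analyses.
    """
    o, p = _check_pair(observed, predicted)
    err = p - o
    abs_err = np.abs(err)
    # an |error| within float noise of the threshold counts as exactly equal,
    # so the strict rule excludes it and the lenient rule includes it
    at_thr = {t: np.isclose(abs_err, t, rtol=0.0, atol=1e-12) for t in (0.10, 0.25)}
    if strict:
        cmp = lambda a, t: (a < t) & ~at_thr[t]
    else:
        cmp = lambda a, t: (a <= t) | at_thr[t]
    return PerformanceReport(
        n=o.size,
        mean=float(p.mean()),
        sd=float(p.std(ddof=1)) if p.size > 1 else 0.0,
        min=float(p.min()),
        p25=float(np.percentile(p, 25)),
        median=float(np.median(p)),
        p75=float(np.percentile(p, 75)),
        max=float(p.max()),
        mse=float(np.mean(err ** 2)),
        mae=float(abs_err.mean()),
        pct_within_010=float(100.0 * cmp(abs_err, 0.10).mean()),
        pct_within_025=float(100.0 * cmp(abs_err, 0.25).mean()),
    )


def errors_by_range(observed, predicted, target: str = "eq5d") -> List[RangeBin]:
    """Per-band MSE/MAE, each observation assigned by its observed value.

    Bands are left-closed, right-open (an observed 0.6 falls in
    "0.6 - 0.7"); empty bands are reported with n = 0.
    """
    o, p = _check_pair(observed, predicted)
    bins = EQ5D_BINS if target == "eq5d" else SF6D_BINS
    out: List[RangeBin] = []
    for label, lo, hi in bins:
        mask = (o >= lo) & (o < hi)
        if not mask.any():
            out.append(RangeBin(label=label, n=0, mse=None, mae=None))
            continue
        err = p[mask] - o[mask]
        out.append(RangeBin(
            label=label,
            n=int(mask.sum()),
            mse=float(np.mean(err ** 2)),
            mae=float(np.mean(np.abs(err))),
        ))
    return out
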