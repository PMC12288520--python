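"""Lowess-detrended age gaps, z-scores, and the Global ensemble gap.

The "age gap" is the residual of clock-predicted age around a locally
weighted scatterplot smooth of predicted age on chronological age. The
smooth absorbs both the mean offset and any non-linearity of the clock's
calibration, so the gap is (by construction) approximately uncorrelated
with chronological age and is read as years of biological age deviation.
Gaps are z-scored per clock before being used as exposures, making effect
sizes comparable across clocks with different gap variances.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "lowess_smooth",
    "lowess_detrend",
    "zscore_gaps",
    "global_gap",
    "per_year_effect",
]

DEFAULT_FRACTION = 2.0 / 3.0


def lowess_smooth(x: np.ndarray, y: np.ndarray, fraction: float = DEFAULT_FRACTION) -> np.ndarray:
    """Locally weighted linear smoother (tricube kernel, 0 robust iterations).

    Classic first-pass lowess: for each point the ``int(fraction * n)``
    nearest neighbours (a contiguous window in sorted x) are tricube-weighted
    by distance scaled to the window half-width, and a weighted linear fit is
    evaluated at the point. Returns fitted values in the input order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    k = min(max(int(fraction * n), 2), n)
    xrange = xs[-1] - xs[0]
    fitted = np.empty(n)
    left = 0
    for i in range(n):
        xi = xs[i]
        # slide the nearest-neighbour window rightwards
        while left + k - 1 < n - 1 and xi - xs[left] > xs[left + k] - xi:
            left += 1
        win = slice(left, left + k)
        xw, yw = xs[win], ys[win]
        h = max(xi - xw[0], xw[-1] - xi)
        d = np.abs(xw - xi)
        if h > 0:
            w = np.where(d <= 0.999 * h, (1.0 - (d / h) ** 3) ** 3, 0.0)
            w[d <= 0.001 * h] = 1.0
        else:
            w = np.ones(k)
        w = w / w.sum()
        xbar = np.dot(w, xw)
        var = np.dot(w, (xw - xbar) ** 2)
        if h > 0 and math.sqrt(var) > 1e-3 * xrange:
            w = w * (1.0 + (xi - xbar) * (xw - xbar) / var)
        fitted[i] = np.dot(w, yw)
    out = np.empty(n)
    out[order] = fitted
    return out


def lowess_detrend(
    predicted: pd.Series, chronological: pd.Series, fraction: float = DEFAULT_FRACTION
) -> pd.Series:
    """Age gap = predicted age minus the lowess smooth at each subject's age."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if set(predicted.index) != set(chronological.index):
        raise ValueError("predicted and chronological must share the same subjects")
    if len(predicted) < 10:
        raise ValueError("lowess detrending requires at least 10 subjects")
    chronological = chronological.reindex(predicted.index)
    smooth = lowess_smooth(
        chronological.to_numpy(dtype=float), predicted.to_numpy(dtype=float), fraction
    )
    gap = predicted.to_numpy(dtype=float) - smooth
    return pd.Series(gap, index=predicted.index, name=getattr(predicted, "name", "gap"))


def zscore_gaps(gaps: pd.Series, population=None) -> pd.Series:
    """Z-score gaps using mean/SD (ddof=1) of the scoring population.

    ``population`` restricts the subjects over which the mean and SD are
    computed (e.g. the subcohort); the transform is applied to all subjects.
    """
    ref = gaps if population is None else gaps.loc[list(population)]
    if len(ref) < 2:
        raise ValueError("scoring population must contain at least 2 subjects")
    mu = float(ref.mean())
    sd = float(ref.std(ddof=1))
    if not sd > 0:
        raise ValueError("scoring population gap SD must be > 0")
    return (gaps - mu) / sd


def global_gap(
    gaps_by_clock: dict[str, pd.Series], population=None
) -> tuple[pd.Series, pd.Series]:
    """Unweighted mean of per-clock gaps, plus its z-score.

    All clocks must cover exactly the same subjects; subjects missing from
    any clock abort rather than silently averaging over available clocks.
    """
    if len(gaps_by_clock) < 2:
        raise ValueError("a Global gap needs at least 2 clocks")
    clocks = list(gaps_by_clock)
    base = set(gaps_by_clock[clocks[0]].index)
    for c in clocks[1:]:
        if set(gaps_by_clock[c].index) != base:
            raise ValueError(f"clock {c!r} does not cover the common subject set")
    frame = pd.DataFrame(
        {c: gaps_by_clock[c].reindex(gaps_by_clock[clocks[0]].index) for c in clocks}
    )
    gap = frame.mean(axis=1)
    gap.name = "Global"
    return gap, zscore_gaps(gap, population)


def per_year_effect(loghr_per_z: float, gap_sd: float) -> float:
    """Convert a per-z-score log hazard into a per-year hazard ratio."""
    if not (np.isfinite(loghr_per_z) and np.isfinite(gap_sd)):
        raise ValueError("inputs must be finite")
    if not gap_sd > 0:
        raise ValueError("gap_sd must be > 0")
    return float(np.exp(loghr_per_z / gap_sd))
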