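"""Age-relatedness of disease endpoints via Gompertz-Makeham incidence fits.

A disease whose incidence rises steeply with age has a large Gompertz slope
b in the hazard ``h(t) = c + a * exp(b*t)``. Fitting this to banded
incidence data (events and person-years per age band, Poisson likelihood at
the band midpoint) gives a per-endpoint age-relatedness coefficient, which
is then rank-correlated (Spearman) with the per-endpoint age-gap log hazard
ratios. Complete-linkage clustering orders clock x endpoint association
matrices for heatmap export.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = [
    "tabulate_incidence",
    "GompertzFit",
    "fit_gompertz_makeham",
    "correlate_age_relatedness",
    "cluster_associations",
]


def tabulate_incidence(
    events: pd.DataFrame, band_width: float = 5.0, origin: float = 0.0
) -> pd.DataFrame:
    """Events and person-years per age band from an event table.

    Each subject contributes person-time to every band overlapped by their
    (entry_age, exit_age] interval; events fall in the band containing the
    exit age.
    """
    entry = events["entry_age"].to_numpy(dtype=float)
    exit_ = events["exit_age"].to_numpy(dtype=float)
    ev = events["event"].to_numpy(dtype=bool)
    lo = origin + band_width * math.floor((entry.min() - origin) / band_width)
    hi = origin + band_width * math.ceil((exit_.max() - origin) / band_width)
    edges = np.arange(lo, hi + band_width / 2, band_width)
    rows = []
    endpoint = events["endpoint"].iloc[0] if "endpoint" in events.columns else ""
    for a, b in zip(edges[:-1], edges[1:]):
        py = np.clip(np.minimum(exit_, b) - np.maximum(entry, a), 0.0, None).sum()
        n_ev = int(np.sum(ev & (exit_ > a) & (exit_ <= b)))
        if py > 0:
            rows.append(
                {
                    "endpoint": endpoint,
                    "age_lower": a,
                    "age_upper": b,
                    "events": n_ev,
                    "person_years": py,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GompertzFit:
    makeham_c: float
    scale_a: float
    rate_b: float
    se_b: float
    loglik: float
    boundary_c: bool = False


def _gm_negll(params, mid, events, py):
    c, log_a, b = params
    mu = py * (c + np.exp(log_a) * np.exp(b * mid))
    if np.any(mu <= 0):
        return 1e30
    return float(np.sum(mu - events * np.log(mu)))


def fit_gompertz_makeham(series: pd.DataFrame) -> GompertzFit:
    """Poisson MLE of (c, a, b) from banded incidence, multi-start over b.

    The hazard is evaluated at each band midpoint; the likelihood is
    ``events_k ~ Poisson(person_years_k * (c + a*exp(b*mid_k)))`` with
    c >= 0 and a > 0. Starts span 20 log-spaced b values in [1e-3, 0.3]/yr.
    A solution on the c = 0 boundary is flagged, not rejected; the SE of b
    comes from the observed information at the optimum.
    """
    n_bands_with_events = int((series["events"] > 0).sum())
    if n_bands_with_events == 0:
        raise ValueError("all-zero event counts; nothing to fit")
    if n_bands_with_events < 4:
        raise ValueError("need >= 4 age bands with events")
    mid = ((series["age_lower"] + series["age_upper"]) / 2).to_numpy(dtype=float)
    events = series["events"].to_numpy(dtype=float)
    py = series["person_years"].to_numpy(dtype=float)
    if np.any(py <= 0):
        raise ValueError("person_years must be > 0")
    crude = events.sum() / py.sum()
    best = None
    for b0 in np.geomspace(1e-3, 0.3, 20):
        # moment-matched start for a at this b
        a0 = max(crude / max(np.mean(np.exp(b0 * mid)), 1e-12), 1e-12)
        x0 = [crude / 2, math.log(a0), b0]
        res = optimize.minimize(
            _gm_negll,
            x0,
            args=(mid, events, py),
            method="L-BFGS-B",
            bounds=[(0.0, None), (-40.0, 10.0), (1e-6, 2.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    c, log_a, b = best.x
    boundary = c <= 1e-12
    # observed information by central finite differences
    h = np.array([max(1e-7, abs(c) * 1e-4), 1e-5, max(1e-7, abs(b) * 1e-4)])
    k = 3
    H = np.zeros((k, k))
    f0 = _gm_negll(best.x, mid, events, py)
    for i in range(k):
        for j in range(i, k):
            xpp = best.x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = best.x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = best.x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = best.x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            if i == j:
                H[i, i] = (
                    _gm_negll(xpp, mid, events, py)
                    - 2 * f0
                    + _gm_negll(xmm, mid, events, py)
                ) / (4 * h[i] ** 2)
            else:
                H[i, j] = H[j, i] = (
                    _gm_negll(xpp, mid, events, py)
                    - _gm_negll(xpm, mid, events, py)
                    - _gm_negll(xmp, mid, events, py)
                    + _gm_negll(xmm, mid, events, py)
                ) / (4 * h[i] * h[j])
    idx = [1, 2] if boundary else [0, 1, 2]  # drop the boundary row for c = 0
    try:
        cov = np.linalg.inv(H[np.ix_(idx, idx)])
        se_b = float(np.sqrt(max(cov[-1, -1], 0.0)))
    except np.linalg.LinAlgError:
        se_b = float("nan")
    return GompertzFit(
        makeham_c=float(c),
        scale_a=float(math.exp(log_a)),
        rate_b=float(b),
        se_b=se_b,
        loglik=-f0,
        boundary_c=bool(boundary),
    )


def _exact_spearman_p(x_rank: np.ndarray, y_rank: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    n = x_rank.size
    count = 0
    total = 0
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean()
    denom = math.sqrt(float(np.sum(xc**2) * np.sum(yc**2)))
    for perm in itertools.permutations(range(n)):
        rho = float(np.sum(xc[list(perm)] * yc)) / denom
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def correlate_age_relatedness(
    loghrs: dict[str, float], betas: dict[str, float]
) -> tuple[float, float]:
    """Spearman correlation between per-endpoint log hazards and Gompertz b.

    Pairs are matched by endpoint label; at least 5 shared endpoints are
    required. For n <= 10 the p-value is an exact permutation p; otherwise
    scipy's large-sample approximation is used.
    """
    shared = sorted(set(loghrs) & set(betas))
    if len(shared) < 5:
        raise ValueError(
            f"only {len(shared)} shared endpoints; need >= 5 for a rank correlation"
        )
    x = np.array([loghrs[e] for e in shared], dtype=float)
    y = np.array([betas[e] for e in shared], dtype=float)
    rho, p = stats.spearmanr(x, y)
    if len(shared) <= 10:
        p = _exact_spearman_p(stats.rankdata(x), stats.rankdata(y), rho)
    return float(rho), float(p)


def cluster_associations(matrix: pd.DataFrame) -> tuple[list, list]:
    """Row and column leaf orders from complete-linkage clustering.

    Euclidean distances, rows and columns clustered independently. A single
    row or column yields the identity order; missing cells abort.
    """
    if matrix.isna().any().any():
        raise ValueError("association matrix contains missing cells")

    def order(frame: pd.DataFrame) -> list:
        if len(frame) < 2:
            return list(frame.index)
        Z = linkage(frame.to_numpy(dtype=float), method="complete", metric="euclidean")
        return [frame.index[i] for i in leaves_list(Z)]

    return order(matrix), order(matrix.T)
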