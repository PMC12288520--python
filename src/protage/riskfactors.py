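"""Cross-sectional models of age-gap z-scores on lifestyle, and the HLI.

The healthy lifestyle index (HLI) scores five behaviours (BMI, smoking,
alcohol, diet, physical activity) from 0 (least healthy) to 4, summing to a
0-20 scale. Gap-on-factor models are ordinary least squares of the gap
z-score on a categorical factor (contrasts against the least healthy
reference) or on mutually adjusted continuous/binary factors, always
adjusted for age, sex and center.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

__all__ = [
    "load_default_hli_cutpoints",
    "compute_hli",
    "hli_quintiles",
    "gap_on_factor",
    "gap_on_factors_mutual",
]


def smoking_class(cohort: pd.DataFrame, heavy_cigs: float = 16.0) -> pd.Series:
    """Five-level smoking category for HLI scoring and contrasts.

    never / former_light / former_heavy / current_light / current_heavy,
    with the light-heavy split at ``heavy_cigs`` cigarettes per day.
    Former smokers without recorded intensity count as former_light.
    """
    status = cohort["smoking_status"].to_numpy()
    cigs = cohort["cigarettes_per_day"].to_numpy(dtype=float)
    out = np.where(
        status == "never",
        "never",
        np.where(
            status == "former",
            np.where(cigs >= heavy_cigs, "former_heavy", "former_light"),
            np.where(cigs >= heavy_cigs, "current_heavy", "current_light"),
        ),
    )
    return pd.Series(out, index=cohort.index, name="smoking_class")


def load_default_hli_cutpoints() -> dict:
    """Packaged default HLI cutpoint configuration (editable data, not code)."""
    text = resources.files("protage").joinpath("data/hli_default.yaml").read_text()
    return yaml.safe_load(text)


def _score_numeric(values: np.ndarray, spec: dict, factor: str) -> np.ndarray:
    edges = list(spec["edges"])
    if len(edges) != 4 or sorted(edges) != edges or len(set(edges)) != 4:
        raise ValueError(
            f"HLI factor {factor!r}: edges must be 4 strictly increasing values "
            "(overlapping or unordered bins rejected)"
        )
    raw = np.searchsorted(np.asarray(edges, dtype=float), values, side="right")
    if spec.get("direction", "higher_better") == "lower_better":
        raw = 4 - raw
    return raw.astype(int)


def _score_categorical(values: np.ndarray, spec: dict, factor: str) -> np.ndarray:
    scores = spec["scores"]
    bad = sorted(set(values) - set(scores))
    if bad:
        raise ValueError(f"HLI factor {factor!r}: no score for categories {bad}")
    vals = sorted(scores.values())
    if any(not 0 <= v <= 4 for v in vals):
        raise ValueError(f"HLI factor {factor!r}: scores must lie in 0..4")
    return np.array([scores[v] for v in values], dtype=int)


def compute_hli(profiles: pd.DataFrame, cutpoints: dict | None = None) -> pd.DataFrame:
    """Per-factor 0-4 scores and the 0-20 total for each subject.

    ``cutpoints`` maps each factor to either ``{type: numeric, edges: [e1..e4],
    direction}`` (bins by ``searchsorted``; ``lower_better`` reverses the
    score) or ``{type: categorical, scores: {category: points}}``. The
    packaged defaults cover bmi, smoking, alcohol, diet and activity.
    """
    if cutpoints is None:
        cutpoints = load_default_hli_cutpoints()
    out = pd.DataFrame(index=profiles.index)
    for factor, spec in cutpoints.items():
        col = spec.get("column", factor)
        if col not in profiles.columns:
            raise ValueError(f"HLI factor {factor!r}: column {col!r} not in profiles")
        values = profiles[col].to_numpy()
        if spec.get("type", "numeric") == "numeric":
            out[f"hli_{factor}"] = _score_numeric(values.astype(float), spec, factor)
        else:
            out[f"hli_{factor}"] = _score_categorical(values, spec, factor)
    out["hli_total"] = out.sum(axis=1)
    return out


def hli_quintiles(totals: pd.Series) -> pd.Series:
    """Quintile (1..5) of the HLI total on the scoring population.

    Cutpoints are the sample 20/40/60/80 percentiles; ties on a cutpoint go
    to the lower quintile.
    """
    qs = np.percentile(totals.to_numpy(dtype=float), [20, 40, 60, 80])
    ranks = np.searchsorted(qs, totals.to_numpy(dtype=float), side="left") + 1
    return pd.Series(ranks, index=totals.index, name="hli_quintile")


def _adjust_matrix(adjust: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code non-numeric adjustment columns (sex, center)."""
    parts = []
    for col in adjust.columns:
        if pd.api.types.is_numeric_dtype(adjust[col]):
            parts.append(adjust[[col]].astype(float))
        else:
            parts.append(pd.get_dummies(adjust[col], prefix=col, drop_first=True).astype(float))
    return pd.concat(parts, axis=1)


def gap_on_factor(
    gaps_z: pd.Series,
    factor: pd.Series,
    adjust: pd.DataFrame,
    reference: str,
) -> pd.DataFrame:
    """OLS contrasts of a gap z-score across factor categories vs reference.

    Returns one row per non-reference category with the estimate (in gap SD
    units), SE, 95% CI and p-value. Empty categories are dropped with a
    warning; the reference must have at least two observations.
    """
    factor = factor.reindex(gaps_z.index)
    adjust = adjust.reindex(gaps_z.index)
    counts = factor.value_counts()
    if reference not in counts or counts[reference] < 2:
        raise ValueError(f"reference category {reference!r} needs >= 2 observations")
    empty = [c for c in counts.index if counts[c] == 0]
    if empty:
        warnings.warn(f"dropping empty categories: {empty}")
    levels = [reference] + [c for c in counts.index if c != reference and counts[c] > 0]
    dummies = pd.DataFrame(
        {f"{factor.name or 'factor'}[{lev}]": (factor == lev).astype(float) for lev in levels[1:]},
        index=gaps_z.index,
    )
    X = sm.add_constant(pd.concat([dummies, _adjust_matrix(adjust)], axis=1))
    res = sm.OLS(gaps_z.to_numpy(dtype=float), X.to_numpy(dtype=float)).fit()
    names = list(X.columns)
    rows = []
    for lev, col in zip(levels[1:], dummies.columns):
        j = names.index(col)
        est, se = res.params[j], res.bse[j]
        rows.append(
            {
                "category": lev,
                "estimate": est,
                "se": se,
                "ci_low": est - 1.96 * se,
                "ci_high": est + 1.96 * se,
                "p": res.pvalues[j],
                "n": int(counts[lev]),
            }
        )
    return pd.DataFrame(rows)


def gap_on_factors_mutual(
    gaps_by_clock: dict[str, pd.Series],
    factors: pd.DataFrame,
    adjust: pd.DataFrame,
    scale_continuous: bool = True,
) -> dict[str, pd.DataFrame]:
    """One mutually adjusted OLS per clock; clock x factor coefficient matrices.

    Continuous factor columns are standardized (when ``scale_continuous``)
    so coefficients are per-SD; binary indicator columns are left as is.
    Returns ``{"coef": ..., "se": ..., "p": ...}`` DataFrames indexed by
    clock with one column per factor.
    """
    factors = factors.copy()
    for col in factors.columns:
        vals = factors[col].to_numpy(dtype=float)
        uniq = np.unique(vals)
        if scale_continuous and uniq.size > 2:
            sd = vals.std(ddof=1)
            if sd == 0:
                raise ValueError(f"factor {col!r} is constant")
            factors[col] = (vals - vals.mean()) / sd
    first = next(iter(gaps_by_clock.values()))
    adjust_mat = _adjust_matrix(adjust.reindex(first.index))
    X = sm.add_constant(
        pd.concat([factors.reindex(first.index), adjust_mat], axis=1).astype(float)
    )
    xmat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(xmat)
    if rank < xmat.shape[1]:
        xc = xmat - xmat.mean(axis=0)
        sd = xc.std(axis=0)
        z = xc / np.where(sd == 0, 1.0, sd)
        corr = (z.T @ z) / max(len(xmat) - 1, 1)
        names = list(X.columns)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                if sd[a] > 0 and sd[b] > 0 and abs(corr[a, b]) > 1 - 1e-10:
                    raise ValueError(f"aliased design columns: {names[a]!r} and {names[b]!r}")
        raise ValueError("rank-deficient design matrix")
    coef, se, pv = {}, {}, {}
    names = list(X.columns)
    idx = [names.index(c) for c in factors.columns]
    for clock, gaps in gaps_by_clock.items():
        res = sm.OLS(gaps.reindex(first.index).to_numpy(dtype=float), xmat).fit()
        coef[clock] = res.params[idx]
        se[clock] = res.bse[idx]
        pv[clock] = res.pvalues[idx]
    cols = list(factors.columns)
    return {
        "coef": pd.DataFrame(coef, index=cols).T,
        "se": pd.DataFrame(se, index=cols).T,
        "p": pd.DataFrame(pv, index=cols).T,
    }
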