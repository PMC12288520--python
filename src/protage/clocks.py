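"""Linear proteomic age clocks: representation, application, training, QC.

A clock is an affine predictor of chronological age from protein
intensities, ``age_hat = intercept + sum_j w_j * f_j(x_j)`` where ``f_j``
is a declared per-analyte preprocessing step (identity, log10, or z-score
with stored training mean/SD). Clocks are stored as JSON so externally
published weight sets can be dropped in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.neighbors import LocalOutlierFactor

__all__ = [
    "ClockSpec",
    "lift_intensities",
    "qc_outliers",
    "apply_clock",
    "train_clock",
    "select_organ_proteins",
]

_PREPROCESS_KINDS = {"identity", "log10", "zscore"}


@dataclass
class ClockSpec:
    """A named linear age predictor with its preprocessing declaration."""

    name: str
    organ: str  # an organ label, "conventional" or "organismal"
    intercept: float
    weights: dict[str, float]
    preprocess: dict[str, dict] = field(default_factory=dict)
    training_meta: str = ""

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("ClockSpec.weights must be non-empty")
        for aid in self.weights:
            entry = self.preprocess.get(aid)
            if entry is None:
                raise ValueError(f"no preprocess entry for analyte {aid!r}")
            kind = entry.get("kind")
            if kind not in _PREPROCESS_KINDS:
                raise ValueError(f"unknown preprocess kind {kind!r} for {aid!r}")
            if kind == "zscore":
                if "mean" not in entry or "sd" not in entry:
                    raise ValueError(f"zscore preprocess for {aid!r} needs mean and sd")
                if not entry["sd"] > 0:
                    raise ValueError(f"zscore sd for {aid!r} must be > 0")

    def to_json(self, path=None) -> str:
        payload = {
            "name": self.name,
            "organ": self.organ,
            "intercept": self.intercept,
            "weights": self.weights,
            "preprocess": self.preprocess,
            "training_meta": self.training_meta,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ClockSpec":
        """Load from a JSON string or file path; schema is validated strictly."""
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        required = {"name", "organ", "intercept", "weights", "preprocess", "training_meta"}
        extra = set(payload) - required
        missing = required - set(payload)
        if extra or missing:
            raise ValueError(
                f"clock JSON schema mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        return cls(
            name=payload["name"],
            organ=payload["organ"],
            intercept=float(payload["intercept"]),
            weights={k: float(v) for k, v in payload["weights"].items()},
            preprocess=payload["preprocess"],
            training_meta=payload["training_meta"],
        )


def lift_intensities(
    matrix: pd.DataFrame, scale_factors: dict[str, float]
) -> pd.DataFrame:
    """Rescale each analyte column by its assay-version lifting factor."""
    missing = [c for c in matrix.columns if c not in scale_factors]
    if missing:
        raise ValueError(f"no scale factor for analytes: {missing[:10]}")
    factors = np.array([scale_factors[c] for c in matrix.columns], dtype=float)
    if np.any(factors <= 0) or not np.all(np.isfinite(factors)):
        bad = [c for c, f in zip(matrix.columns, factors) if not f > 0]
        raise ValueError(f"scale factors must be positive and finite: {bad[:10]}")
    return matrix * factors


def qc_outliers(
    matrix: pd.DataFrame,
    n_components: int = 10,
    n_neighbors: int = 20,
    tukey_k: float = 1.5,
) -> set[str]:
    """Multivariate outlier subjects by PCA projection + local outlier factor.

    The log10-transformed, column-standardized matrix is projected onto the
    top principal components; a local-outlier-factor score is computed per
    subject on that projection and subjects whose score exceeds
    ``Q3 + tukey_k * IQR`` of the score distribution are flagged.
    """
    n, p = matrix.shape
    if n_components >= min(n, p):
        raise ValueError("n_components must be < min(n_subjects, n_analytes)")
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be < n_subjects")
    x = np.log10(np.maximum(matrix.to_numpy(dtype=float), 1e-12))
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    proj = PCA(n_components=n_components, svd_solver="full").fit_transform(x)
    lof = LocalOutlierFactor(n_neighbors=n_neighbors)
    lof.fit(proj)
    score = -lof.negative_outlier_factor_
    q1, q3 = np.percentile(score, [25, 75])
    thresh = q3 + tukey_k * (q3 - q1)
    flagged = score > thresh
    return set(np.asarray(matrix.index)[flagged])


def _preprocess_column(x: np.ndarray, entry: dict, analyte: str) -> np.ndarray:
    kind = entry["kind"]
    if kind == "identity":
        return x
    if kind == "log10":
        if np.any(x <= 0):
            raise ValueError(f"log10 preprocess needs positive intensities ({analyte})")
        return np.log10(x)
    if kind == "zscore":
        return (x - entry["mean"]) / entry["sd"]
    raise ValueError(f"unknown preprocess kind {kind!r}")


def apply_clock(matrix: pd.DataFrame, spec: ClockSpec) -> pd.Series:
    """Predicted age per subject; missing analytes abort (no imputation)."""
    missing = [a for a in spec.weights if a not in matrix.columns]
    if missing:
        raise ValueError(
            f"clock {spec.name!r}: analytes missing from matrix: {missing[:20]}"
        )
    pred = np.full(len(matrix), float(spec.intercept))
    for aid, w in spec.weights.items():
        col = _preprocess_column(
            matrix[aid].to_numpy(dtype=float), spec.preprocess[aid], aid
        )
        pred = pred + w * col
    return pd.Series(pred, index=matrix.index, name=spec.name)


def train_clock(
    matrix: pd.DataFrame,
    ages: pd.Series,
    alpha: float = 0.5,
    n_folds: int = 5,
    seed: int = 0,
    name: str = "clock",
    organ: str = "conventional",
) -> ClockSpec:
    """Cross-validated elastic-net regression of age on standardized intensities.

    ``alpha`` is the L1/L2 mixing parameter; the penalty strength is chosen
    at the ``n_folds``-fold cross-validation minimum. Zero-variance analytes
    are dropped before standardization. The returned spec stores the
    training means/SDs as z-score preprocessing, so applying it to the
    training matrix reproduces the model's fitted values.
    """
    ages = ages.reindex(matrix.index)
    if ages.isna().any() or not np.all(np.isfinite(ages.to_numpy(dtype=float))):
        raise ValueError("ages must be finite for every subject in the matrix")
    if len(matrix) < 50:
        raise ValueError("training requires at least 50 subjects")
    y = ages.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("age vector is constant; cannot train a clock")
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    cols = np.asarray(matrix.columns)[keep]
    z = (x[:, keep] - mu[keep]) / sd[keep]
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # harmless convergence chatter at tiny lambda
        model = ElasticNetCV(
            l1_ratio=alpha, cv=cv, alphas=60, random_state=seed, max_iter=5000
        )
        model.fit(z, y)
    nz = np.flatnonzero(model.coef_)
    if nz.size == 0:  # fully shrunk: keep the single strongest analyte at coef 0
        nz = np.array([0])
    weights = {cols[j]: float(model.coef_[j]) for j in nz}
    preprocess = {
        cols[j]: {"kind": "zscore", "mean": float(mu[keep][j]), "sd": float(sd[keep][j])}
        for j in nz
    }
    lo, hi = float(np.min(y)), float(np.max(y))
    return ClockSpec(
        name=name,
        organ=organ,
        intercept=float(model.intercept_),
        weights=weights,
        preprocess=preprocess,
        training_meta=f"n={len(matrix)}, age range {lo:.1f}-{hi:.1f}, "
        f"elastic-net l1_ratio={alpha}, {n_folds}-fold CV",
    )


def select_organ_proteins(
    annotation: pd.DataFrame, organ: str, fold_threshold: float = 4.0
) -> set[str]:
    """Analytes enriched for one organ, or the 'organismal' remainder.

    An analyte belongs to ``organ`` when its enrichment (fold-change of
    organ expression over the maximum of other organs) is at least
    ``fold_threshold`` (inclusive boundary). ``organ="organismal"`` returns
    the analytes below threshold for every annotated organ.
    """
    organs = set(annotation["organ"])
    if organ != "organismal" and organ not in organs:
        raise ValueError(f"unknown organ {organ!r}; annotated organs: {sorted(organs)}")
    enr = annotation["enrichment"].to_numpy(dtype=float)
    if organ == "organismal":
        above = set(annotation.loc[enr >= fold_threshold, "analyte_id"])
        return set(annotation["analyte_id"]) - above
    mask = (annotation["organ"] == organ).to_numpy() & (enr >= fold_threshold)
    return set(annotation.loc[mask, "analyte_id"])
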