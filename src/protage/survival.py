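"""Case-cohort survival inference.

The engine is a stratified Cox partial likelihood with attained age as the
timescale (delayed entry at recruitment age), Breslow tie handling, row
weights, and a robust (sandwich, grouped-by-subject) variance. Case-cohort
data are handled by Prentice weighting: subcohort members are at risk over
their whole observed interval, while cases outside the subcohort enter the
risk set only just before their own failure, so they contribute their own
event but no other risk sets.

Also here: Benjamini-Hochberg FDR, Harrell's concordance index under left
truncation, lasso-penalized Cox selection over a cross-validated lambda
path, concordance comparison across model specifications, and event-lag
sensitivity refits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PRENTICE_EPS",
    "AssociationResult",
    "CoxFit",
    "impute_covariates",
    "make_stratum",
    "prentice_weights",
    "fit_cox",
    "fit_stratified_cox",
    "bh_fdr",
    "harrell_c",
    "lasso_cox_select",
    "compare_models_concordance",
    "lag_sensitivity",
]

logger = logging.getLogger("protage")

#: non-subcohort cases enter the risk set this many years before their event
PRENTICE_EPS = 1e-6


def impute_covariates(
    records: pd.DataFrame, columns: list[str], method: str = "simple"
) -> pd.DataFrame:
    """Fill missing covariate values before model fitting.

    ``method="simple"`` imputes column means (numeric) or modes
    (categorical) and logs how many cells were filled; ``method="none"``
    rejects any missingness outright.
    """
    out = records.copy()
    n_filled = 0
    for col in columns:
        miss = out[col].isna()
        if not miss.any():
            continue
        if method == "none":
            raise ValueError(f"missing values in {col!r} with imputation disabled")
        if method != "simple":
            raise ValueError(f"unknown imputation method {method!r}")
        if pd.api.types.is_numeric_dtype(out[col]):
            out.loc[miss, col] = out[col].mean()
        else:
            out.loc[miss, col] = out[col].mode().iloc[0]
        n_filled += int(miss.sum())
    if n_filled:
        logger.info("imputed %d missing covariate cells", n_filled)
    return out


def make_stratum(
    sex, center, entry_age, band_width: float = 5.0, origin: float = 0.0
) -> pd.Series:
    """Composite stratum key: sex x center x age band (default 5-year bands
    aligned to multiples of 5)."""
    entry_age = np.asarray(entry_age, dtype=float)
    band = origin + band_width * np.floor((entry_age - origin) / band_width)
    return pd.Series(
        [f"{s}|{c}|{b:g}" for s, c, b in zip(np.asarray(sex), np.asarray(center), band)]
    )


def prentice_weights(records: pd.DataFrame, eps: float = PRENTICE_EPS) -> pd.DataFrame:
    """Apply the Prentice risk-set entry rule to a case-cohort record table.

    Subcohort members keep their observed (entry, exit) interval with weight
    one. Cases outside the subcohort have their entry moved to
    ``exit_age - eps`` so they appear only in their own risk set. A
    non-subcohort non-case violates the design and aborts.
    """
    if "in_subcohort" not in records.columns:
        raise ValueError("records must carry an in_subcohort column")
    out = records.copy()
    insub = out["in_subcohort"].to_numpy(dtype=bool)
    event = out["event"].to_numpy(dtype=bool)
    bad = ~insub & ~event
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} non-subcohort non-case rows present; "
            "a case-cohort sample contains only the subcohort plus cases"
        )
    entry = out["entry_age"].to_numpy(dtype=float).copy()
    late = ~insub & event
    entry[late] = out.loc[late, "exit_age"].to_numpy(dtype=float) - eps
    out["entry_age"] = entry
    if "weight" not in out.columns:
        out["weight"] = 1.0
    return out


# ---------------------------------------------------------------------------
# Cox partial likelihood engine
# ---------------------------------------------------------------------------


class _Stratum:
    """Per-stratum precomputed sort structure for the partial likelihood."""

    def __init__(self, X, entry, exit_, event, w):
        self.X, self.entry, self.exit, self.event, self.w = X, entry, exit_, event, w
        self.exit_order = np.argsort(exit_, kind="stable")
        self.entry_order = np.argsort(entry, kind="stable")
        ev_times = exit_[event]
        self.ut, inv = np.unique(ev_times, return_inverse=True)
        self.dw = np.bincount(inv, weights=w[event])
        self.sX = np.zeros((self.ut.size, X.shape[1]))
        np.add.at(self.sX, inv, w[event, None] * X[event])
        exit_sorted = exit_[self.exit_order]
        entry_sorted = entry[self.entry_order]
        self.idx_exit = np.searchsorted(exit_sorted, self.ut, side="left")
        self.idx_entry = np.searchsorted(entry_sorted, self.ut, side="left")
        self.sum_w_eta_base = None  # filled per eval

    @staticmethod
    def _suffix(v):
        """Suffix sums along axis 0 with a trailing zero row."""
        out = np.concatenate([np.cumsum(v[::-1], axis=0)[::-1], np.zeros((1,) + v.shape[1:])])
        return out

    def s_moments(self, eta, order):
        """S0(t), S1(t), S2(t) over risk sets at the stratum's event times."""
        m = float(np.max(eta))
        r = self.w * np.exp(eta - m)
        rx = r[self.exit_order]
        rn = r[self.entry_order]
        S0 = self._suffix(rx)[self.idx_exit] - self._suffix(rn)[self.idx_entry]
        S1 = S2 = None
        if order >= 1:
            vX = r[:, None] * self.X
            S1 = (
                self._suffix(vX[self.exit_order])[self.idx_exit]
                - self._suffix(vX[self.entry_order])[self.idx_entry]
            )
        if order >= 2:
            vXX = r[:, None, None] * (self.X[:, :, None] * self.X[:, None, :])
            S2 = (
                self._suffix(vXX[self.exit_order])[self.idx_exit]
                - self._suffix(vXX[self.entry_order])[self.idx_entry]
            )
        return m, S0, S1, S2

    def eval(self, beta, order=2):
        eta = self.X @ beta
        m, S0, S1, S2 = self.s_moments(eta, order)
        S0 = np.maximum(S0, 1e-300)
        ll = float(np.sum(self.w[self.event] * eta[self.event])) - float(
            np.sum(self.dw * (np.log(S0) + m))
        )
        grad = info = None
        if order >= 1:
            xbar = S1 / S0[:, None]
            grad = self.sX.sum(axis=0) - (self.dw[:, None] * xbar).sum(axis=0)
        if order >= 2:
            v = S2 / S0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]
            info = (self.dw[:, None, None] * v).sum(axis=0)
        return ll, grad, info

    def score_residuals(self, beta):
        """Per-row score residuals (for the grouped sandwich variance)."""
        eta = self.X @ beta
        m, S0, S1, _ = self.s_moments(eta, order=1)
        S0 = np.maximum(S0, 1e-300)
        xbar = S1 / S0[:, None]
        # prefix sums over event times of dw/S0 and dw*xbar/S0
        A = np.concatenate([[0.0], np.cumsum(self.dw / S0)])
        B = np.concatenate(
            [np.zeros((1, self.X.shape[1])), np.cumsum(self.dw[:, None] * xbar / S0[:, None], axis=0)]
        )
        lo = np.searchsorted(self.ut, self.entry, side="right")
        hi = np.searchsorted(self.ut, self.exit, side="right")
        r = self.w * np.exp(eta - m)
        U = -(r[:, None] * (self.X * (A[hi] - A[lo])[:, None] - (B[hi] - B[lo])))
        if self.event.any():
            pos = np.searchsorted(self.ut, self.exit[self.event])
            U[self.event] += self.w[self.event, None] * (
                self.X[self.event] - xbar[pos]
            )
        return U


class _CoxData:
    def __init__(self, X, entry, exit_, event, weight, strata, subject_ids):
        if np.any(entry >= exit_):
            raise ValueError("every record must have entry_age < exit_age")
        self.p = X.shape[1]
        codes, _ = pd.factorize(strata)
        self.strata = []
        self.row_index = []
        dropped = 0
        for s in range(codes.max() + 1):
            rows = np.flatnonzero(codes == s)
            if not event[rows].any():
                dropped += 1
                continue
            self.strata.append(
                _Stratum(X[rows], entry[rows], exit_[rows], event[rows], weight[rows])
            )
            self.row_index.append(rows)
        self.n_strata_dropped = dropped
        if not self.strata:
            raise ValueError("no events in any stratum")
        if dropped:
            logger.info("dropped %d eventless strata", dropped)
        self.n = sum(len(r) for r in self.row_index)
        self.n_events = int(event.sum())
        self.subject_ids = subject_ids

    def eval(self, beta, order=2):
        ll, grad, info = 0.0, np.zeros(self.p), np.zeros((self.p, self.p))
        for st in self.strata:
            l, g, i = st.eval(beta, order)
            ll += l
            if order >= 1:
                grad += g
            if order >= 2:
                info += i
        return ll, (grad if order >= 1 else None), (info if order >= 2 else None)

    def robust_cov(self, beta, info):
        """Sandwich covariance with score residuals grouped by subject."""
        groups = {}
        meat = np.zeros((self.p, self.p))
        for st, rows in zip(self.strata, self.row_index):
            U = st.score_residuals(beta)
            for k, row in enumerate(rows):
                sid = self.subject_ids[row]
                if sid in groups:
                    groups[sid] = groups[sid] + U[k]
                else:
                    groups[sid] = U[k]
        M = np.array(list(groups.values()))
        meat = M.T @ M
        bread = np.linalg.inv(info)
        return bread @ meat @ bread


def _check_collinearity(X: np.ndarray, names: list[str]) -> None:
    xc = X - X.mean(axis=0)
    sd = xc.std(axis=0)
    if np.any(sd == 0) and X.shape[1] > 1:
        const = [names[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant covariate column(s): {const}")
    if X.shape[1] < 2:
        return
    rank = np.linalg.matrix_rank(xc)
    if rank < X.shape[1]:
        z = xc / np.where(sd == 0, 1.0, sd)
        corr = (z.T @ z) / max(len(X) - 1, 1)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                if abs(corr[a, b]) > 1 - 1e-10:
                    raise ValueError(
                        f"collinear covariates: {names[a]!r} and {names[b]!r}"
                    )
        raise ValueError(f"design matrix is rank deficient among {names}")


def _prepare(records: pd.DataFrame, covariates: list[str]) -> _CoxData:
    for col in ("entry_age", "exit_age", "event"):
        if col not in records.columns:
            raise ValueError(f"records must have a {col!r} column")
    X = records[list(covariates)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values in records")
    _check_collinearity(X, list(covariates))
    strata = (
        records["stratum"].to_numpy()
        if "stratum" in records.columns
        else np.zeros(len(records), dtype=int)
    )
    weight = (
        records["weight"].to_numpy(dtype=float)
        if "weight" in records.columns
        else np.ones(len(records))
    )
    sids = (
        records["subject_id"].to_numpy()
        if "subject_id" in records.columns
        else np.arange(len(records))
    )
    return _CoxData(
        X,
        records["entry_age"].to_numpy(dtype=float),
        records["exit_age"].to_numpy(dtype=float),
        records["event"].to_numpy(dtype=bool),
        weight,
        strata,
        sids,
    )


@dataclass
class CoxFit:
    params: pd.Series
    se: pd.Series
    robust_se: pd.Series
    cov: pd.DataFrame
    loglik: float
    n: int
    n_events: int
    n_strata_dropped: int
    iterations: int


def _newton(data: _CoxData, tol=1e-9, max_iter=50, beta0=None):
    beta = np.zeros(data.p) if beta0 is None else beta0.copy()
    ll, grad, info = data.eval(beta)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            return beta, ll, info, it
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix at iteration {it}") from exc
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = data.eval(cand)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
    if np.max(np.abs(grad)) < 1e-5:  # converged loosely; accept with a warning
        warnings.warn(f"Cox fit: loose convergence, |grad|={np.max(np.abs(grad)):.2e}")
        return beta, ll, info, max_iter
    raise ValueError(
        f"Cox fit did not converge in {max_iter} iterations "
        f"(gradient norm {np.max(np.abs(grad)):.3e})"
    )


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str],
    robust: bool = True,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Maximize the stratified, left-truncated, weighted Cox partial
    likelihood (Breslow ties) by Newton iteration."""
    data = _prepare(records, covariates)
    beta, ll, info, it = _newton(data, tol=tol, max_iter=max_iter)
    cov_model = np.linalg.inv(info)
    cov = data.robust_cov(beta, info) if robust else cov_model
    names = list(covariates)
    return CoxFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(np.sqrt(np.diag(cov_model)), index=names),
        robust_se=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=ll,
        n=data.n,
        n_events=data.n_events,
        n_strata_dropped=data.n_strata_dropped,
        iterations=it,
    )


@dataclass
class AssociationResult:
    clock: str
    endpoint: str
    model: str
    loghr: float
    se: float
    p: float
    n: int
    n_events: int
    q: float = float("nan")

    @property
    def hr(self) -> float:
        return float(np.exp(self.loghr))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.loghr - 1.96 * self.se)),
            float(np.exp(self.loghr + 1.96 * self.se)),
        )

    def as_row(self) -> dict:
        lo, hi = self.ci95
        return {
            "clock": self.clock,
            "endpoint": self.endpoint,
            "model": self.model,
            "loghr": self.loghr,
            "se": self.se,
            "hr": self.hr,
            "ci_low": lo,
            "ci_high": hi,
            "p": self.p,
            "q": self.q,
            "n": self.n,
            "n_events": self.n_events,
        }


def fit_stratified_cox(
    records: pd.DataFrame,
    exposure: str,
    adjust: list[str] = (),
    clock: str = "",
    endpoint: str = "",
    model: str = "base",
    robust: bool = True,
) -> AssociationResult:
    """Association of one exposure with one endpoint, optionally adjusted.

    Records are expected to already carry Prentice entry times (see
    :func:`prentice_weights`) when they come from a case-cohort sample.
    """
    fit = fit_cox(records, [exposure, *adjust], robust=robust)
    se = float((fit.robust_se if robust else fit.se)[exposure])
    b = float(fit.params[exposure])
    p = 2 * stats.norm.sf(abs(b) / se) if se > 0 else float("nan")
    res = AssociationResult(
        clock=clock or exposure,
        endpoint=endpoint,
        model=model,
        loghr=b,
        se=se,
        p=float(p),
        n=fit.n,
        n_events=fit.n_events,
    )
    res.fit = fit
    return res


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def harrell_c(records: pd.DataFrame, risk_score: pd.Series) -> float:
    """Harrell's concordance index under left truncation.

    A pair is usable when one member has an event at time T and the other
    is under observation at T (entered before, exits after). The index is
    the proportion of usable pairs in which the failing member has the
    higher risk score; score ties count one half.
    """
    score = risk_score.reindex(records["subject_id"]).to_numpy(dtype=float)
    if np.any(~np.isfinite(score)):
        raise ValueError("risk score missing or non-finite for some subjects")
    entry = records["entry_age"].to_numpy(dtype=float)
    exit_ = records["exit_age"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=bool)
    if not event.any():
        raise ValueError("no events; concordance undefined")
    conc = 0.0
    usable = 0
    for i in np.flatnonzero(event):
        t = exit_[i]
        at_risk = (entry < t) & (exit_ > t)
        k = int(at_risk.sum())
        if k == 0:
            continue
        usable += k
        s = score[at_risk]
        conc += float(np.sum(score[i] > s)) + 0.5 * float(np.sum(score[i] == s))
    if usable == 0:
        raise ValueError("no usable pairs; concordance undefined")
    return conc / usable


# ---------------------------------------------------------------------------
# Lasso-penalized Cox selection
# ---------------------------------------------------------------------------


def _soft(z, g):
    return np.sign(z) * np.maximum(np.abs(z) - g, 0.0)


def _penalized_quadratic_cd(beta, g, H, lam, pen_mask, n_iter=200, tol=1e-10):
    """Coordinate descent on g'd + d'Hd/2 + lam*||beta+d||_1 (penalized coords)."""
    b = beta.copy()
    p = b.size
    hd = np.diag(H).copy()
    hd[hd <= 0] = 1e-12
    grad = g - H @ beta  # gradient of quadratic at b (excluding penalty), as fn of b
    # maintain q(b) gradient: g + H(b - beta)
    for _ in range(n_iter):
        max_delta = 0.0
        for j in range(p):
            gj = g[j] + H[j] @ (b - beta)
            z = hd[j] * b[j] - gj
            new = _soft(z, lam) / hd[j] if pen_mask[j] else z / hd[j]
            delta = new - b[j]
            if delta != 0.0:
                b[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return b


def _fit_penalized(data, lam, pen_mask, scale, beta0, W, max_outer=50, tol=1e-8):
    """Prox-Newton for the L1-penalized (on pen_mask coords) Cox objective
    f(beta) = -ll(beta*scale)/W + lam * sum_j |beta_j| over penalized coords.

    ``beta`` lives on the standardized scale; ``scale`` maps it back.
    """
    beta = beta0.copy()

    def objective(b):
        ll, _, _ = data.eval(b * scale, order=0)
        return -ll / W + lam * np.sum(np.abs(b[pen_mask]))

    f = objective(beta)
    for _ in range(max_outer):
        ll, grad, info = data.eval(beta * scale)
        g = -(grad * scale) / W
        H = (info * np.outer(scale, scale)) / W
        H = H + 1e-10 * np.eye(H.shape[0])
        new = _penalized_quadratic_cd(beta, g, H, lam, pen_mask)
        step = new - beta
        if np.max(np.abs(step)) < tol:
            return beta
        t = 1.0
        for _ in range(25):
            cand = beta + t * step
            f_new = objective(cand)
            if f_new <= f + 1e-14:
                break
            t *= 0.5
        if f_new > f:
            return beta
        beta, f = cand, f_new
    return beta


def _lasso_path(data, lam_path, pen_mask, scale, W):
    betas = []
    beta = np.zeros(data.p)
    for lam in lam_path:
        beta = _fit_penalized(data, lam, pen_mask, scale, beta, W)
        betas.append(beta.copy())
    return np.array(betas)


def lasso_cox_select(
    records: pd.DataFrame,
    candidate_exposures: list[str],
    adjust: list[str] = (),
    n_folds: int = 5,
    seed: int = 0,
    n_lambda: int = 30,
    lambda_min_ratio: float = 1e-3,
    robust: bool = True,
    rule: str = "min",
):
    """Select exposures by L1-penalized Cox regression with CV-tuned lambda.

    Candidate exposure coefficients are penalized (on a standardized scale);
    adjustment covariates stay unpenalized. Lambda is tuned on the
    cross-validated partial-likelihood deviance (Verweij-van Houwelingen)
    over ``n_lambda`` log-spaced values: ``rule="min"`` takes the deviance
    minimum (best prediction; tends to carry small-coefficient extras),
    ``rule="1se"`` the sparsest lambda within one standard error of it (the
    usual convention when the goal is support recovery). Selected exposures
    are refit jointly, unpenalized, with the adjustment covariates.

    Returns ``(selected, results, info)`` where ``results`` is a list of
    :class:`AssociationResult` for each selected exposure from the joint
    refit and ``info`` holds the lambda path and CV deviances.
    """
    if len(candidate_exposures) < 2:
        raise ValueError("need at least 2 candidate exposures")
    cols = list(candidate_exposures) + list(adjust)
    data = _prepare(records, cols)
    p = len(cols)
    pen_mask = np.zeros(p, dtype=bool)
    pen_mask[: len(candidate_exposures)] = True
    sds = records[cols].to_numpy(dtype=float).std(axis=0, ddof=1)
    scale = np.where(pen_mask, np.where(sds > 0, sds, 1.0), 1.0)
    W = float(data.n_events)

    # lambda_max: smallest lambda with all penalized coords at zero, given the
    # unpenalized coords fitted alone
    beta_init = np.zeros(p)
    if adjust:
        sub = _prepare(records, list(adjust))
        b_adj, *_ = _newton(sub)
        beta_init[len(candidate_exposures):] = b_adj
    _, grad, _ = data.eval(beta_init * scale)
    g = -(grad * scale) / W
    lam_max = float(np.max(np.abs(g[pen_mask]))) * 1.0001
    lam_path = lam_max * np.logspace(0, np.log10(lambda_min_ratio), n_lambda)

    betas_full = _lasso_path(data, lam_path, pen_mask, scale, W)

    # cross-validated deviance
    rng = np.random.default_rng(seed)
    subjects = records["subject_id"].to_numpy()
    uniq = pd.unique(subjects)
    fold_of = dict(zip(uniq, rng.integers(0, n_folds, size=uniq.size)))
    folds = np.array([fold_of[s] for s in subjects])
    fold_dev = np.zeros((n_folds, n_lambda))
    fold_events = np.zeros(n_folds)
    for f in range(n_folds):
        train = records.loc[folds != f]
        d_train = _prepare(train, cols)
        fold_events[f] = data.n_events - d_train.n_events
        W_tr = float(d_train.n_events)
        betas_tr = _lasso_path(d_train, lam_path, pen_mask, scale, W_tr)
        for k in range(n_lambda):
            b = betas_tr[k] * scale
            ll_all, _, _ = data.eval(b, order=0)
            ll_tr, _, _ = d_train.eval(b, order=0)
            fold_dev[f, k] = -2.0 * (ll_all - ll_tr)
    # per-held-out-event deviance, weighted by fold event counts (the
    # cv.glmnet convention, which keeps fold composition out of the SE)
    wf = np.maximum(fold_events, 1.0)
    cvraw = fold_dev / wf[:, None]
    cvm = (wf[:, None] * cvraw).sum(axis=0) / wf.sum()
    cvsd = np.sqrt(
        ((wf[:, None] * (cvraw - cvm) ** 2).sum(axis=0) / wf.sum()) / (n_folds - 1)
    )
    k_min = int(np.argmin(cvm))
    if rule == "min":
        best = k_min
    elif rule == "1se":
        within = np.flatnonzero(cvm <= cvm[k_min] + cvsd[k_min])
        best = int(within[0])  # lambdas are decreasing: first = sparsest
    else:
        raise ValueError(f"unknown lambda rule {rule!r}")
    beta_best = betas_full[best]
    selected = [
        candidate_exposures[j]
        for j in range(len(candidate_exposures))
        if abs(beta_best[j]) > 1e-10
    ]
    info = {
        "lambda_path": lam_path,
        "cv_deviance": cvm,
        "cv_deviance_se": cvsd,
        "lambda_best": lam_path[best],
        "path_coefs": betas_full,  # standardized-scale coefficients
    }
    if not selected:
        warnings.warn("lasso selection: all candidate coefficients zero at CV minimum")
        return [], [], info
    fit = fit_cox(records, selected + list(adjust), robust=robust)
    results = []
    for name in selected:
        se = float((fit.robust_se if robust else fit.se)[name])
        b = float(fit.params[name])
        res = AssociationResult(
            clock=name,
            endpoint=str(records["endpoint"].iloc[0]) if "endpoint" in records else "",
            model="lasso-refit",
            loghr=b,
            se=se,
            p=float(2 * stats.norm.sf(abs(b) / se)) if se > 0 else float("nan"),
            n=fit.n,
            n_events=fit.n_events,
        )
        res.fit = fit
        results.append(res)
    return selected, results, info


def compare_models_concordance(
    records: pd.DataFrame,
    model_specs: dict[str, list[str]],
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Harrell's C with subject-level bootstrap CIs for several model specs.

    Each spec (name -> covariate list) is fit on the shared record set; its
    linear predictor is the risk score. Bootstrap resamples subjects with
    replacement and recomputes C with the fitted scores held fixed.
    """
    rng = np.random.default_rng(seed)
    uniq = pd.unique(records["subject_id"])
    boot_draws = [rng.choice(uniq, size=uniq.size, replace=True) for _ in range(n_boot)]
    rows = []
    by_subject = records.set_index("subject_id", drop=False)
    for name, cols in model_specs.items():
        fit = fit_cox(records, cols, robust=False)
        score = pd.Series(
            records[cols].to_numpy(dtype=float) @ fit.params.to_numpy(),
            index=records["subject_id"].to_numpy(),
        )
        c = harrell_c(records, score)
        boots = []
        for draw in boot_draws:
            sample = by_subject.loc[draw]
            try:
                boots.append(harrell_c(sample, score))
            except ValueError:
                continue
        lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
        rows.append(
            {"model": name, "c_index": c, "ci_low": lo, "ci_high": hi,
             "n": fit.n, "n_events": fit.n_events}
        )
    return pd.DataFrame(rows)


def lag_sensitivity(
    records_raw: pd.DataFrame,
    lag_years,
    exposure: str,
    adjust: list[str] = (),
    clock: str = "",
    endpoint: str = "",
    model: str = "adjusted",
) -> dict[float, AssociationResult]:
    """Refit the association excluding events within a lag of recruitment.

    ``records_raw`` must hold the true (pre-Prentice) entry ages. Events
    occurring within ``lag`` years of entry are recoded as censored at the
    event age; the resulting non-subcohort non-cases are dropped (they no
    longer belong to a Prentice case-cohort sample), and the model is refit.
    """
    out = {}
    for lag in lag_years:
        if lag < 0:
            raise ValueError("lag must be >= 0")
        rec = records_raw.copy()
        early = rec["event"].to_numpy(dtype=bool) & (
            rec["exit_age"].to_numpy(dtype=float)
            - rec["entry_age"].to_numpy(dtype=float)
            <= lag
        )
        rec.loc[early, "event"] = False
        drop = ~rec["in_subcohort"].to_numpy(dtype=bool) & ~rec["event"].to_numpy(dtype=bool)
        if drop.any():
            logger.info("lag %.1f: dropped %d early non-subcohort cases", lag, drop.sum())
        rec = rec.loc[~drop]
        if not rec["event"].any():
            raise ValueError(f"no events remain at lag {lag}")
        rec = prentice_weights(rec)
        out[lag] = fit_stratified_cox(
            rec, exposure, adjust, clock=clock, endpoint=endpoint, model=f"{model}-lag{lag:g}"
        )
    return out
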