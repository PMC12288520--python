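"""Synthetic cohort generation for proteomic-aging analyses.

Generates cohorts with the statistical structure the downstream pipeline
assumes: a latent "biological age acceleration" per subject (with
organ-specific components), age-linked plasma protein signatures, lifestyle
factors that shift the acceleration, Gompertz-Makeham survival whose hazard
depends on the acceleration, and case-cohort sampling (a random subcohort
plus all cases).

The latent acceleration is in years: a subject with ``accel_global = +3``
has the protein profile of someone three years older than their
chronological age, and a mortality hazard multiplied by ``exp(3 * gamma)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GompertzParams",
    "SimConfig",
    "simulate_cohort",
    "simulate_survival",
    "sample_case_cohort",
]

# Continuous lifestyle factors are centred at these population values before
# the acceleration effect is applied, so that the default cohort has a
# near-zero mean lifestyle contribution. Indicator factors are not centred.
LIFESTYLE_CENTERS = {
    "alcohol_gday": 10.0,
    "bmi": 25.0,
    "diet_score": 7.0,
    "activity_met": 40.0,
    "education_level": 3.0,
    "cigarettes_per_day": 0.0,
    "current_smoker": 0.0,
    "former_smoker": 0.0,
}

#: years of acceleration per unit of each (centred) factor
DEFAULT_LIFESTYLE_EFFECTS = {
    "current_smoker": 1.0,
    "cigarettes_per_day": 0.05,
    "alcohol_gday": 0.02,
    "bmi": 0.08,
    "diet_score": -0.15,
    "activity_met": -0.01,
    "education_level": -0.2,
}

EDUCATION_LEVELS = 5
SMOKING_STATES = ("never", "former", "current")


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz-Makeham hazard h(t) = c + a * exp(b*t + gamma*accel).

    ``makeham_c`` is the age-independent (extrinsic) hazard, ``scale_a`` and
    ``rate_b`` the Gompertz scale and slope, and ``gamma`` the log-hazard
    increase per year of latent acceleration.
    """

    makeham_c: float = 2e-4
    scale_a: float = 2e-5
    rate_b: float = 0.10
    gamma: float = math.log(1.4) / 3.0

    def validate(self) -> None:
        for name in ("makeham_c", "scale_a", "rate_b", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"gompertz.{name} must be finite, got {v!r}")
        if self.makeham_c < 0:
            raise ValueError("gompertz.makeham_c must be >= 0")
        if self.scale_a <= 0:
            raise ValueError("gompertz.scale_a must be > 0")
        if self.rate_b <= 0:
            raise ValueError("gompertz.rate_b must be > 0")


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int = 4000
    n_proteins: int = 300
    n_organs: int = 3
    age_range: tuple[float, float] = (40.0, 70.0)
    frac_age_proteins: float = 0.5
    organ_block_size: int = 20
    sigma_accel: float = 3.0
    sigma_organ: float = 2.0
    sigma_noise: float = 1.0
    lifestyle_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIFESTYLE_EFFECTS)
    )
    gompertz: GompertzParams = field(default_factory=GompertzParams)
    admin_censor_age: float = 75.0
    subcohort_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        scalars = {
            "n_subjects": self.n_subjects,
            "n_proteins": self.n_proteins,
            "n_organs": self.n_organs,
            "frac_age_proteins": self.frac_age_proteins,
            "organ_block_size": self.organ_block_size,
            "sigma_accel": self.sigma_accel,
            "sigma_organ": self.sigma_organ,
            "sigma_noise": self.sigma_noise,
            "admin_censor_age": self.admin_censor_age,
            "subcohort_fraction": self.subcohort_fraction,
        }
        for name, v in scalars.items():
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        for name, v in self.lifestyle_effects.items():
            if not np.isfinite(v):
                raise ValueError(f"lifestyle_effects[{name!r}] must be finite")
            if name not in LIFESTYLE_CENTERS:
                raise ValueError(f"unknown lifestyle effect key {name!r}")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        lo, hi = self.age_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("age_range must satisfy min < max with finite bounds")
        for name in ("sigma_accel", "sigma_organ", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.subcohort_fraction <= 1:
            raise ValueError("subcohort_fraction must be in (0, 1]")
        n_age = int(round(self.frac_age_proteins * self.n_proteins))
        if self.n_organs * self.organ_block_size > n_age:
            raise ValueError(
                "n_organs * organ_block_size exceeds the number of age-linked proteins"
            )
        self.gompertz.validate()

    def organs(self) -> list[str]:
        return [f"organ{k + 1}" for k in range(self.n_organs)]


def _subject_ids(n: int) -> np.ndarray:
    width = max(5, len(str(n)))
    return np.array([f"S{i:0{width}d}" for i in range(1, n + 1)])


def _draw_lifestyle(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Marginal lifestyle distributions; the joint is independent by design."""
    smoking = rng.choice(SMOKING_STATES, size=n, p=[0.45, 0.30, 0.25])
    cigs = np.where(
        smoking == "current", np.round(rng.gamma(shape=3.0, scale=4.0, size=n)), 0.0
    )
    return pd.DataFrame(
        {
            "sex": rng.choice(["F", "M"], size=n),
            "center": rng.choice([f"C{j}" for j in range(1, 5)], size=n),
            "smoking_status": smoking,
            "cigarettes_per_day": cigs,
            "alcohol_gday": np.round(rng.lognormal(mean=1.8, sigma=1.0, size=n), 1),
            "bmi": np.round(np.clip(rng.normal(26.0, 4.0, size=n), 16.0, None), 1),
            "diet_score": np.round(np.clip(rng.normal(7.0, 2.0, size=n), 0.0, 14.0), 1),
            "activity_met": np.round(rng.gamma(shape=4.0, scale=10.0, size=n), 1),
            "education_level": rng.choice(
                np.arange(1, EDUCATION_LEVELS + 1), size=n, p=[0.15, 0.25, 0.25, 0.2, 0.15]
            ),
        }
    )


def lifestyle_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric columns on which lifestyle acceleration effects operate."""
    return pd.DataFrame(
        {
            "current_smoker": (cohort["smoking_status"] == "current").astype(float),
            "former_smoker": (cohort["smoking_status"] == "former").astype(float),
            "cigarettes_per_day": cohort["cigarettes_per_day"].astype(float),
            "alcohol_gday": cohort["alcohol_gday"].astype(float),
            "bmi": cohort["bmi"].astype(float),
            "diet_score": cohort["diet_score"].astype(float),
            "activity_met": cohort["activity_met"].astype(float),
            "education_level": cohort["education_level"].astype(float),
        },
        index=cohort.index,
    )


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a cohort table, a protein intensity matrix and the latent state.

    Returns
    -------
    cohort : DataFrame
        One row per subject: ``subject_id``, ``age``, sex/center and
        lifestyle columns.
    proteins : DataFrame
        Wide intensity matrix, subjects in rows (index = subject_id),
        analyte IDs in columns. Age-linked analytes satisfy
        ``x = a_j + b_j * (age + accel) + noise`` where ``accel`` is the
        organ-specific acceleration for organ-annotated analytes and the
        global acceleration otherwise.
    latent : DataFrame
        ``subject_id``, ``accel_global`` and one ``accel_<organ>`` column
        per organ. ``accel_global`` includes the lifestyle contribution.

    The generator also attaches the organ annotation table (analyte_id,
    organ, enrichment) as ``proteins.attrs["annotation"]`` and the true
    protein coefficients as ``proteins.attrs["protein_truth"]``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    sid = _subject_ids(n)

    lo, hi = config.age_range
    age = np.round(rng.uniform(lo, hi, size=n), 2)  # recruitment age, 0.01 yr
    cohort = _draw_lifestyle(n, rng)
    cohort.insert(0, "age", age)
    cohort.insert(0, "subject_id", sid)

    design = lifestyle_design(cohort)
    lifestyle_contrib = np.zeros(n)
    for key, effect in config.lifestyle_effects.items():
        lifestyle_contrib += effect * (design[key].to_numpy() - LIFESTYLE_CENTERS[key])

    accel_global = rng.normal(0.0, config.sigma_accel, size=n) + lifestyle_contrib
    organs = config.organs()
    accel_organ = {
        org: accel_global + rng.normal(0.0, config.sigma_organ, size=n)
        for org in organs
    }
    latent = pd.DataFrame({"subject_id": sid, "accel_global": accel_global})
    for org in organs:
        latent[f"accel_{org}"] = accel_organ[org]

    # protein truth: which analytes are age-linked, their organ, slope, intercept
    p = config.n_proteins
    n_age = int(round(config.frac_age_proteins * p))
    analyte_ids = np.array([f"A{j:05d}" for j in range(1, p + 1)])
    a_j = rng.uniform(10.0, 20.0, size=p)
    slope_mag = rng.uniform(0.02, 0.06, size=p)
    slope_sign = rng.choice([-1.0, 1.0], size=p)
    b_j = np.where(np.arange(p) < n_age, slope_mag * slope_sign, 0.0)

    organ_of = np.array(["none"] * p, dtype=object)
    pos = 0
    for org in organs:
        organ_of[pos : pos + config.organ_block_size] = org
        pos += config.organ_block_size
    organ_of[pos:n_age] = "organismal"

    effective_age = np.empty((n, p))
    for j in range(p):
        if b_j[j] == 0.0:
            effective_age[:, j] = 0.0
        elif organ_of[j] in accel_organ:
            effective_age[:, j] = age + accel_organ[organ_of[j]]
        else:
            effective_age[:, j] = age + accel_global
    intensities = a_j + b_j * effective_age
    if config.sigma_noise > 0:
        intensities = intensities + rng.normal(0.0, config.sigma_noise, size=(n, p))
    intensities = np.maximum(intensities, 1e-6)  # RFU intensities are positive

    proteins = pd.DataFrame(intensities, index=pd.Index(sid, name="subject_id"),
                            columns=analyte_ids)

    # organ annotation with enrichment fold-changes: organ-block analytes are
    # strongly enriched (>= 4-fold); all others fall below any such threshold
    ann_organ = np.where(
        np.isin(organ_of, organs), organ_of, rng.choice(organs, size=p)
    )
    enrichment = np.where(
        np.isin(organ_of, organs),
        rng.uniform(4.0, 10.0, size=p),
        rng.uniform(1.0, 3.0, size=p),
    )
    annotation = pd.DataFrame(
        {"analyte_id": analyte_ids, "organ": ann_organ, "enrichment": np.round(enrichment, 3)}
    )
    truth = pd.DataFrame(
        {"analyte_id": analyte_ids, "intercept": a_j, "slope": b_j, "organ": organ_of}
    )
    proteins.attrs["annotation"] = annotation
    proteins.attrs["protein_truth"] = truth
    return cohort, proteins, latent


def _invert_gm_grid(
    entry: np.ndarray,
    accel: np.ndarray,
    gp: GompertzParams,
    censor: float,
    unif: np.ndarray,
    step: float = 0.01,
) -> np.ndarray:
    """Event ages by inverse transform of the cumulative hazard.

    Solves ``H(t) - H(entry) = -log(u)`` on a fixed age grid (``step``
    years) with linear interpolation; returns inf where the target exceeds
    the cumulative hazard at the censoring age.
    """
    n = entry.size
    target = -np.log(unif)
    c, a, b, g = gp.makeham_c, gp.scale_a, gp.rate_b, gp.gamma
    k = (a / b) * np.exp(g * accel)
    # F(t) = c*t + k*exp(b*t) is the "raw" cumulative hazard primitive
    rhs = target + c * entry + k * np.exp(b * entry)
    t0 = math.floor(float(entry.min()))
    grid = np.arange(t0, censor + step, step)
    grid_exp = np.exp(b * grid)
    out = np.full(n, np.inf)
    chunk = max(1, int(2e7 // max(grid.size, 1)))
    for s in range(0, n, chunk):
        e = min(n, s + chunk)
        F = c * grid[None, :] + k[s:e, None] * grid_exp[None, :]
        idx = np.sum(F < rhs[s:e, None], axis=1)
        solved = idx < grid.size
        ii = np.where(solved)[0]
        if ii.size:
            hi = idx[ii]
            lo = np.maximum(hi - 1, 0)
            f_lo = F[ii, lo]
            f_hi = F[ii, hi]
            frac = np.where(f_hi > f_lo, (rhs[s:e][ii] - f_lo) / (f_hi - f_lo), 0.0)
            t = grid[lo] + np.clip(frac, 0.0, 1.0) * step
            out[s + ii] = np.maximum(t, entry[s + ii])
    return out


def simulate_survival(
    cohort: pd.DataFrame,
    latent: pd.DataFrame,
    config: SimConfig,
    endpoint: str = "mortality",
    gompertz: GompertzParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one survival record per subject for one endpoint.

    The hazard is ``h(t) = c + a * exp(b*t + gamma*accel_global)`` with
    delayed entry at the recruitment age and administrative censoring at
    ``config.admin_censor_age``. ``gompertz`` overrides the config's hazard
    (used for disease endpoints); ``seed`` overrides the config seed.
    """
    gp = gompertz if gompertz is not None else config.gompertz
    gp.validate()
    if len(cohort) != len(latent):
        raise ValueError("cohort and latent must have one row per subject")
    if not np.array_equal(
        cohort["subject_id"].to_numpy(), latent["subject_id"].to_numpy()
    ):
        raise ValueError("cohort and latent subject_id columns must match")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    entry = cohort["age"].to_numpy(dtype=float)
    accel = latent["accel_global"].to_numpy(dtype=float)
    censor = float(config.admin_censor_age)
    unif = rng.uniform(size=len(cohort))
    if censor <= entry.min():
        event_age = np.full(len(cohort), np.inf)
    else:
        event_age = _invert_gm_grid(entry, accel, gp, censor, unif)
    exit_age = np.minimum(event_age, np.maximum(censor, entry))
    event = event_age <= censor
    return pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "endpoint": endpoint,
            "entry_age": entry,
            "exit_age": exit_age,
            "event": event,
            "in_subcohort": True,
        }
    )


def draw_subcohort(
    subject_ids: np.ndarray | pd.Series, fraction: float, seed: int
) -> set[str]:
    """Independent Bernoulli(fraction) subcohort membership draw."""
    if not 0 < fraction <= 1:
        raise ValueError("subcohort fraction must be in (0, 1]")
    ids = np.asarray(subject_ids)
    rng = np.random.default_rng(seed)
    keep = rng.uniform(size=ids.size) < fraction
    return set(ids[keep])


def sample_case_cohort(
    events: pd.DataFrame,
    subcohort_fraction: float,
    seed: int,
    subcohort_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Reduce a full-cohort event table to a case-cohort sample.

    A random subcohort of the stated fraction is retained together with all
    cases (whether in the subcohort or not); non-subcohort non-cases are
    dropped. ``subcohort_ids`` pins the subcohort (so several endpoints can
    share one subcohort); otherwise a fresh Bernoulli draw over the unique
    subjects is made.
    """
    if not 0 < subcohort_fraction <= 1:
        raise ValueError("subcohort_fraction must be in (0, 1]")
    if subcohort_ids is None:
        subcohort_ids = draw_subcohort(
            events["subject_id"].unique(), subcohort_fraction, seed
        )
    in_sub = events["subject_id"].isin(subcohort_ids).to_numpy()
    keep = in_sub | events["event"].to_numpy()
    out = events.loc[keep].copy()
    out["in_subcohort"] = in_sub[keep]
    return out.reset_index(drop=True)
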