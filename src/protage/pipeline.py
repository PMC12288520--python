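"""Configuration-driven orchestration of the full analysis.

``run_analysis`` ties every stage together: simulate (or ingest) a cohort,
QC, clock training and application, lowess age gaps, Prentice-weighted
case-cohort associations (base and risk-factor-adjusted, conventional and
organ clocks plus the Global ensemble), FDR control, risk-factor linear
models, Gompertz-Makeham age-relatedness, lasso clock selection and
concordance comparison. All outputs are TSV/JSON in a run directory, with
a machine-readable manifest (seed, versions, subject counts at each
filter step) and a log.

One top-level seed governs every stochastic stage: per-stage seeds are
derived as ``SeedSequence([seed, crc32(stage_name)])``, so adding or
removing a stage never perturbs the others.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agegap import global_gap, lowess_detrend, zscore_gaps
from .age_relatedness import (
    cluster_associations,
    correlate_age_relatedness,
    fit_gompertz_makeham,
    tabulate_incidence,
)
from .clocks import apply_clock, qc_outliers, select_organ_proteins, train_clock
from .riskfactors import (
    compute_hli,
    gap_on_factor,
    gap_on_factors_mutual,
    hli_quintiles,
    smoking_class,
)
from .simcohort import (
    GompertzParams,
    SimConfig,
    draw_subcohort,
    lifestyle_design,
    sample_case_cohort,
    simulate_cohort,
    simulate_survival,
)
from .survival import (
    bh_fdr,
    compare_models_concordance,
    fit_stratified_cox,
    lag_sensitivity,
    lasso_cox_select,
    make_stratum,
    prentice_weights,
)

__all__ = ["DEFAULT_ENDPOINTS", "RISK_FACTOR_COLUMNS", "load_config", "run_analysis"]

logger = logging.getLogger("protage")

#: per-endpoint Gompertz-Makeham hazards (c /yr, a /yr, b /yr, gamma /yr-accel)
DEFAULT_ENDPOINTS: dict[str, dict] = {
    "mortality": dict(makeham_c=2e-4, scale_a=2e-5, rate_b=0.100, gamma=0.112),
    "chd": dict(makeham_c=1e-4, scale_a=8e-6, rate_b=0.095, gamma=0.090),
    "stroke": dict(makeham_c=8e-5, scale_a=4e-6, rate_b=0.100, gamma=0.100),
    "lung_cancer": dict(makeham_c=5e-5, scale_a=6e-6, rate_b=0.085, gamma=0.110),
    "dementia": dict(makeham_c=1e-5, scale_a=5e-7, rate_b=0.140, gamma=0.120),
    "diabetes": dict(makeham_c=3e-4, scale_a=1e-5, rate_b=0.060, gamma=0.070),
    "kidney_cancer": dict(makeham_c=5e-5, scale_a=2e-6, rate_b=0.075, gamma=0.050),
    "fracture": dict(makeham_c=1e-3, scale_a=1e-6, rate_b=0.050, gamma=0.010),
}

#: covariates of the risk-factor-adjusted Cox model
RISK_FACTOR_COLUMNS = [
    "current_smoker",
    "former_smoker",
    "alcohol_gday",
    "bmi",
    "diet_score",
    "activity_met",
    "education_level",
]

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "protage_run",
    "simulate": {},  # SimConfig field overrides
    "n_train": 1500,
    "clocks": {"n_conventional": 5, "protein_fraction": 0.6, "alpha": 0.5, "n_folds": 5},
    "organ_clocks": True,
    "fold_threshold": 4.0,
    "qc": {"enabled": True, "n_components": 10, "n_neighbors": 20, "tukey_k": 1.5},
    "endpoints": None,  # None -> DEFAULT_ENDPOINTS
    "analysis": {
        "subcohort_fraction": 0.3,
        "fdr": 0.05,
        "lags": [2.0, 5.0],
        "lowess_fraction": 2.0 / 3.0,
        "concordance": True,
        "lasso": True,
        "n_boot": 200,
        # endpoint -> Gompertz rate b from an external registry (as published
        # age-relatedness coefficients); None correlates against the rates
        # fitted from this cohort's own incidence
        "external_betas": None,
    },
}


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _merge(base: dict, override: dict, path="") -> dict:
    out = dict(base)
    for k, v in override.items():
        if k not in base:
            raise ValueError(f"unknown config key {path + k!r}")
        if isinstance(base[k], dict) and isinstance(v, dict) and base[k]:
            out[k] = _merge(base[k], v, path + k + ".")
        else:
            out[k] = v
    return out


def load_config(source) -> dict:
    """Load and validate a run configuration (YAML path, YAML text or dict).

    Unknown keys are rejected; missing keys take documented defaults.
    """
    if isinstance(source, dict):
        raw = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        raw = yaml.safe_load(text) or {}
    cfg = _merge(DEFAULT_CONFIG, raw)
    if not 0 < cfg["analysis"]["fdr"] < 1:
        raise ValueError("analysis.fdr must be in (0, 1)")
    if not 0 < cfg["analysis"]["subcohort_fraction"] <= 1:
        raise ValueError("analysis.subcohort_fraction must be in (0, 1]")
    return cfg


def _sim_config(cfg: dict) -> SimConfig:
    over = dict(cfg["simulate"])
    gp = over.pop("gompertz", None)
    kwargs = dict(over)
    if gp is not None:
        kwargs["gompertz"] = GompertzParams(**gp)
    if "age_range" in kwargs:
        kwargs["age_range"] = tuple(kwargs["age_range"])
    return SimConfig(**kwargs)


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", **kw)


def _endpoint_params(cfg: dict) -> dict[str, GompertzParams]:
    raw = cfg["endpoints"] if cfg["endpoints"] is not None else DEFAULT_ENDPOINTS
    return {name: GompertzParams(**p) for name, p in raw.items()}


def run_analysis(config, outdir=None) -> Path:
    """Execute the full pipeline; returns the run directory."""
    cfg = load_config(config)
    seed = int(cfg["seed"])
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "protage_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config": cfg,
        "counts": {},
        "stages": [],
    }
    counts = manifest["counts"]
    stage = "init"
    try:
        # ------------------------------------------------------------------
        stage = "simulate"
        sim = _sim_config(cfg)
        n_train = int(cfg["n_train"])
        sim_all = SimConfig(
            **{
                **{f: getattr(sim, f) for f in sim.__dataclass_fields__},
                "n_subjects": sim.n_subjects + n_train,
                "seed": _stage_seed(seed, "simulate"),
            }
        )
        cohort_all, proteins_all, latent_all = simulate_cohort(sim_all)
        annotation = proteins_all.attrs["annotation"]
        # one draw, split into a clock-training part and the analysis cohort,
        # so published-style clocks are external to the analysis sample
        train_ids = cohort_all["subject_id"].iloc[:n_train]
        cohort = cohort_all.iloc[n_train:].reset_index(drop=True)
        latent = latent_all.iloc[n_train:].reset_index(drop=True)
        proteins_train = proteins_all.loc[train_ids]
        proteins = proteins_all.loc[cohort["subject_id"]]
        counts["n_train"] = n_train
        counts["n_analysis_initial"] = len(cohort)
        _write(cohort, out / "cohort.tsv")
        _write(latent, out / "latent.tsv")
        _write(annotation, out / "organ_annotation.tsv")
        proteins.to_csv(out / "proteins.csv", float_format="%.6g")
        manifest["stages"].append(stage)

        # ------------------------------------------------------------------
        stage = "qc"
        if cfg["qc"]["enabled"]:
            flagged = qc_outliers(
                proteins,
                n_components=cfg["qc"]["n_components"],
                n_neighbors=cfg["qc"]["n_neighbors"],
                tukey_k=cfg["qc"]["tukey_k"],
            )
        else:
            flagged = set()
        counts["n_qc_flagged"] = len(flagged)
        keep = ~cohort["subject_id"].isin(flagged)
        cohort = cohort.loc[keep].reset_index(drop=True)
        latent = latent.loc[keep.to_numpy()].reset_index(drop=True)
        proteins = proteins.loc[cohort["subject_id"]]
        counts["n_analysis"] = len(cohort)
        logger.info("QC flagged %d subjects; %d remain", len(flagged), len(cohort))
        manifest["stages"].append(stage)

        # ------------------------------------------------------------------
        stage = "clocks"
        ck = cfg["clocks"]
        train_ages = pd.Series(
            cohort_all["age"].iloc[:n_train].to_numpy(), index=proteins_train.index
        )
        specs = []
        rng_clocks = np.random.default_rng(_stage_seed(seed, "clocks"))
        for k in range(int(ck["n_conventional"])):
            cols = rng_clocks.choice(
                proteins_train.columns,
                size=max(2, int(ck["protein_fraction"] * proteins_train.shape[1])),
                replace=False,
            )
            specs.append(
                train_clock(
                    proteins_train[cols],
                    train_ages,
                    alpha=ck["alpha"],
                    n_folds=ck["n_folds"],
                    seed=_stage_seed(seed, f"clock{k}"),
                    name=f"conv{k + 1}",
                    organ="conventional",
                )
            )
        organ_names = []
        if cfg["organ_clocks"]:
            organs = sorted(set(annotation["organ"])) + ["organismal"]
            for org in organs:
                cols = sorted(
                    select_organ_proteins(annotation, org, cfg["fold_threshold"])
                )
                if len(cols) < 2:
                    logger.info("organ %s: too few proteins, skipped", org)
                    continue
                specs.append(
                    train_clock(
                        proteins_train[cols],
                        train_ages,
                        alpha=ck["alpha"],
                        n_folds=ck["n_folds"],
                        seed=_stage_seed(seed, f"organ-{org}"),
                        name=org,
                        organ=org,
                    )
                )
                organ_names.append(org)
        clock_dir = out / "clocks"
        clock_dir.mkdir(exist_ok=True)
        for spec in specs:
            spec.to_json(clock_dir / f"{spec.name}.json")
        counts["n_clocks"] = len(specs)
        manifest["stages"].append(stage)

        # ------------------------------------------------------------------
        stage = "agegap"
        ages = pd.Series(cohort["age"].to_numpy(), index=proteins.index)
        frac = cfg["analysis"]["lowess_fraction"]
        predicted, gaps, gap_z = {}, {}, {}
        for spec in specs:
            pred = apply_clock(proteins, spec)
            predicted[spec.name] = pred
            gaps[spec.name] = lowess_detrend(pred, ages, frac)
            gap_z[spec.name] = zscore_gaps(gaps[spec.name])
        conv_names = [s.name for s in specs if s.organ == "conventional"]
        gap_global, gap_global_z = global_gap({c: gaps[c] for c in conv_names})
        pred_global = pd.concat([predicted[c] for c in conv_names], axis=1).mean(axis=1)
        predicted["Global"] = pred_global
        gaps["Global"] = gap_global
        gap_z["Global"] = gap_global_z
        rows = []
        for name in predicted:
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": predicted[name].index,
                        "clock": name,
                        "predicted_age": predicted[name].to_numpy(),
                        "gap": gaps[name].to_numpy(),
                        "gap_z": gap_z[name].to_numpy(),
                    }
                )
            )
        agegap_table = pd.concat(rows, ignore_index=True)
        _write(agegap_table, out / "agegaps.tsv")
        counts["gap_sd_years"] = {n: float(gaps[n].std(ddof=1)) for n in gaps}
        manifest["stages"].append(stage)

        # ------------------------------------------------------------------
        stage = "survival"
        params = _endpoint_params(cfg)
        subcohort = draw_subcohort(
            cohort["subject_id"].to_numpy(),
            cfg["analysis"]["subcohort_fraction"],
            _stage_seed(seed, "subcohort"),
        )
        design = lifestyle_design(cohort)
        design.index = cohort["subject_id"].to_numpy()
        strata = make_stratum(cohort["sex"], cohort["center"], cohort["age"])
        strata.index = cohort["subject_id"].to_numpy()
        conv_and_global = conv_names + ["Global"]
        results = []
        raw_records = {}
        events_full = {}
        for endpoint, gp in params.items():
            ev = simulate_survival(
                cohort, latent, sim, endpoint=endpoint, gompertz=gp,
                seed=_stage_seed(seed, f"survival-{endpoint}"),
            )
            events_full[endpoint] = ev
            cc = sample_case_cohort(
                ev, cfg["analysis"]["subcohort_fraction"], seed, subcohort_ids=subcohort
            )
            cc = cc.merge(design, left_on="subject_id", right_index=True)
            cc["stratum"] = strata.loc[cc["subject_id"]].to_numpy()
            for name in conv_and_global + organ_names:
                cc[f"gapz_{name}"] = gap_z[name].loc[cc["subject_id"]].to_numpy()
            raw_records[endpoint] = cc
            rec = prentice_weights(cc)
            for name in conv_and_global + organ_names:
                family = "organ" if name in organ_names else "conventional"
                for model, adjust in (
                    ("base", []),
                    ("adjusted", RISK_FACTOR_COLUMNS),
                ):
                    res = fit_stratified_cox(
                        rec, f"gapz_{name}", adjust,
                        clock=name, endpoint=endpoint, model=model,
                    )
                    res.family = family
                    results.append(res)
            counts.setdefault("n_cases", {})[endpoint] = int(ev["event"].sum())
        # FDR within each family x model table
        for family in ("conventional", "organ"):
            for model in ("base", "adjusted"):
                block = [
                    r for r in results if r.family == family and r.model == model
                ]
                if block:
                    qs = bh_fdr([r.p for r in block])
                    for r, q in zip(block, qs):
                        r.q = float(q)
        assoc = pd.DataFrame([r.as_row() | {"family": r.family} for r in results])
        _write(assoc[assoc["family"] == "conventional"], out / "associations_conventional.tsv")
        if organ_names:
            _write(assoc[assoc["family"] == "organ"], out / "associations_organ.tsv")
        manifest["stages"].append(stage)

        # ------------------------------------------------------------------
        stage = "heatmap"
        conv_adj = assoc[(assoc["family"] == "conventional") & (assoc["model"] == "adjusted")]
        heat = conv_adj.pivot(index="clock", columns="endpoint", values="loghr")
        row_order, col_order = cluster_associations(heat)
        heat.loc[row_order, col_order].to_csv(out / "heatmap_conventional.tsv", sep="\t")
        manifest["stages"].append(stage)

        # ------------------------------------------------------------------
        stage = "riskfactors"
        sub_ids = [s for s in cohort["subject_id"] if s in subcohort]
        sub_cohort = cohort.set_index("subject_id").loc[sub_ids]
        profiles = sub_cohort.copy()
        profiles["smoking_class"] = smoking_class(sub_cohort)
        hli = compute_hli(profiles)
        hli["hli_quintile"] = hli_quintiles(hli["hli_total"])
        adjust = pd.DataFrame(
            {"age": sub_cohort["age"], "sex": sub_cohort["sex"], "center": sub_cohort["center"]}
        )
        gz_sub = gap_z["Global"].loc[sub_ids]
        contrast_tables = []
        for fac_name, series, ref in (
            ("smoking", profiles["smoking_class"].rename("smoking"), "current_heavy"),
            ("hli_quintile", hli["hli_quintile"].astype(str).rename("hli_quintile"), "1"),
        ):
            tab = gap_on_factor(gz_sub, series, adjust, reference=ref)
            tab.insert(0, "factor", fac_name)
            contrast_tables.append(tab)
        _write(pd.concat(contrast_tables, ignore_index=True), out / "risk_factor_contrasts.tsv")
        factors = pd.DataFrame(
            {
                "current_smoker": (sub_cohort["smoking_status"] == "current").astype(float),
                "alcohol_gday": sub_cohort["alcohol_gday"],
                "bmi": sub_cohort["bmi"],
                "diet_score": sub_cohort["diet_score"],
                "activity_met": sub_cohort["activity_met"],
                "high_education": (sub_cohort["education_level"] >= 4).astype(float),
            }
        )
        mutual = gap_on_factors_mutual(
            {n: gap_z[n].loc[sub_ids] for n in conv_and_global}, factors, adjust
        )
        mutual["coef"].to_csv(out / "risk_factor_matrix.tsv", sep="\t")
        manifest["stages"].append(stage)

        # ------------------------------------------------------------------
        stage = "age_relatedness"
        inc_rows, gm_rows, betas = [], [], {}
        for endpoint, ev in events_full.items():
            inc = tabulate_incidence(ev)
            inc_rows.append(inc)
            try:
                fit = fit_gompertz_makeham(inc)
            except ValueError as exc:
                logger.info("gompertz fit skipped for %s: %s", endpoint, exc)
                continue
            betas[endpoint] = fit.rate_b
            gm_rows.append(
                {
                    "endpoint": endpoint,
                    "makeham_c": fit.makeham_c,
                    "scale_a": fit.scale_a,
                    "rate_b": fit.rate_b,
                    "se_b": fit.se_b,
                    "boundary_c": fit.boundary_c,
                }
            )
        _write(pd.concat(inc_rows, ignore_index=True), out / "incidence.tsv")
        _write(pd.DataFrame(gm_rows), out / "gompertz_fits.tsv")
        loghrs = {
            r.endpoint: r.loghr
            for r in results
            if r.clock == "Global" and r.model == "adjusted"
        }
        if cfg["analysis"]["external_betas"] is not None:
            betas = dict(cfg["analysis"]["external_betas"])
        if len(set(loghrs) & set(betas)) >= 5:
            rho, p = correlate_age_relatedness(loghrs, betas)
            _write(
                pd.DataFrame([{"rho": rho, "p": p, "n_endpoints": len(set(loghrs) & set(betas))}]),
                out / "age_relatedness.tsv",
            )
            manifest["age_relatedness_rho"] = rho
        else:
            logger.info("age-relatedness correlation skipped: fewer than 5 endpoints")
        manifest["stages"].append(stage)

        # ------------------------------------------------------------------
        stage = "concordance"
        if cfg["analysis"]["lasso"] or cfg["analysis"]["concordance"]:
            rec_mort = prentice_weights(raw_records["mortality"])
        if cfg["analysis"]["lasso"] and organ_names:
            selected, lasso_results, _ = lasso_cox_select(
                rec_mort,
                [f"gapz_{n}" for n in organ_names],
                RISK_FACTOR_COLUMNS,
                seed=_stage_seed(seed, "lasso"),
            )
            _write(
                pd.DataFrame(
                    [r.as_row() for r in lasso_results]
                    or [{"clock": "(none selected)"}]
                ),
                out / "lasso_selection.tsv",
            )
            manifest["lasso_selected"] = [s.replace("gapz_", "") for s in selected]
        if cfg["analysis"]["concordance"]:
            model_specs = {
                "risk_factors": list(RISK_FACTOR_COLUMNS),
                "global_gap": ["gapz_Global"],
                "combined": ["gapz_Global", *RISK_FACTOR_COLUMNS],
            }
            if organ_names:
                model_specs["organ_gaps_plus_risk"] = [
                    f"gapz_{n}" for n in organ_names
                ] + list(RISK_FACTOR_COLUMNS)
            conc = compare_models_concordance(
                rec_mort,
                model_specs,
                n_boot=int(cfg["analysis"]["n_boot"]),
                seed=_stage_seed(seed, "bootstrap"),
            )
            _write(conc, out / "concordance.tsv")
        manifest["stages"].append(stage)

        # ------------------------------------------------------------------
        stage = "lag_sensitivity"
        lags = cfg["analysis"]["lags"]
        if lags:
            lag_res = lag_sensitivity(
                raw_records["mortality"],
                lags,
                "gapz_Global",
                RISK_FACTOR_COLUMNS,
                clock="Global",
                endpoint="mortality",
            )
            _write(
                pd.DataFrame(
                    [{"lag": lag} | r.as_row() for lag, r in lag_res.items()]
                ),
                out / "lag_sensitivity.tsv",
            )
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        logger.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    logger.removeHandler(handler)
    handler.close()
    return out
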