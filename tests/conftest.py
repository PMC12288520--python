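import numpy as np
import pandas as pd
import pytest

from protage import (
    GompertzParams,
    SimConfig,
    prentice_weights,
    sample_case_cohort,
    simulate_cohort,
    simulate_survival,
)


@pytest.fixture(scope="session")
def small_sim():
    """A modest cohort shared across read-only tests."""
    config = SimConfig(
        n_subjects=800,
        n_proteins=80,
        n_organs=2,
        organ_block_size=10,
        sigma_noise=0.8,
        seed=11,
    )
    cohort, proteins, latent = simulate_cohort(config)
    return config, cohort, proteins, latent


def make_case_cohort_records(
    n=2000,
    seed=0,
    gamma=np.log(1.4) / 3.0,
    subcohort_fraction=0.3,
    exposure_from_latent=True,
):
    """Case-cohort survival records with the latent acceleration z-score as
    the exposure (true log HR per exposure SD = 3 * gamma)."""
    config = SimConfig(
        n_subjects=n,
        n_proteins=4,
        n_organs=1,
        organ_block_size=1,
        frac_age_proteins=0.5,
        lifestyle_effects={},
        gompertz=GompertzParams(gamma=gamma),
        seed=seed,
    )
    cohort, _, latent = simulate_cohort(config)
    events = simulate_survival(cohort, latent, config, seed=seed + 1)
    cc = sample_case_cohort(events, subcohort_fraction, seed=seed + 2)
    if exposure_from_latent:
        accel = latent.set_index("subject_id")["accel_global"]
        cc["accel_z"] = (accel.loc[cc["subject_id"]] / config.sigma_accel).to_numpy()
    return config, cohort, latent, cc


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two identical small pipeline runs (for determinism and integrity)."""
    from protage import run_analysis

    cfg = {
        "seed": 5,
        "simulate": {
            "n_subjects": 900,
            "n_proteins": 90,
            "n_organs": 2,
            "organ_block_size": 10,
        },
        "n_train": 600,
        "analysis": {"n_boot": 30},
        "endpoints": {
            "mortality": dict(makeham_c=2e-4, scale_a=2e-5, rate_b=0.10, gamma=0.112),
            "chd": dict(makeham_c=1e-4, scale_a=8e-6, rate_b=0.095, gamma=0.09),
            "stroke": dict(makeham_c=8e-5, scale_a=4e-6, rate_b=0.10, gamma=0.10),
            "lung_cancer": dict(makeham_c=5e-5, scale_a=6e-6, rate_b=0.085, gamma=0.11),
            "dementia": dict(makeham_c=1e-5, scale_a=5e-7, rate_b=0.14, gamma=0.12),
        },
    }
    base = tmp_path_factory.mktemp("pipeline")
    out1 = run_analysis(cfg, outdir=base / "run1")
    out2 = run_analysis(cfg, outdir=base / "run2")
    return cfg, out1, out2
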