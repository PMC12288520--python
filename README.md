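# protage

Proteomic age clocks and case-cohort survival analysis, with a synthetic
cohort generator that makes every stage testable end to end.

## The problem

Plasma proteomes drift with age in a way that is partly decoupled from the
calendar. A *proteomic age clock* is a linear predictor of chronological age
from protein intensities,

    age_hat_i = b0 + sum_j w_j * f_j(x_ij),

where `f_j` is a declared per-analyte transform (identity, log10, or
z-score with stored training mean/SD). The interesting quantity is not the
prediction but its residual structure: the **age gap**

    gap_i = age_hat_i - s(age_i),

where `s` is a lowess smooth (tricube local-linear, span 2/3) of predicted
on chronological age. The gap is read as years of biological age above or
below one's chronological age, and is z-scored per clock so clocks with
different variances are comparable. Averaging several clocks' gaps gives a
**Global** gap that suppresses clock-specific noise.

Cohort studies measure proteomes in a random *subcohort* plus everyone who
later develops disease (the case-cohort design). Associations between gap
z-scores and incident disease are estimated with a Cox model on the age
timescale (delayed entry at recruitment), stratified by sex, center and
5-year age band, with **Prentice weighting**: cases outside the subcohort
enter the risk set only just before their own failure. The package also
scores each endpoint's *age-relatedness* (the slope b of a Gompertz-Makeham
hazard `h(t) = c + a*exp(b*t)` fitted to banded incidence) and asks, via
Spearman correlation, whether age-gap effects concentrate in the most
age-related diseases; selects organ-specific clocks by lasso-penalized Cox
regression with cross-validated lambda; and compares model discrimination
with Harrell's concordance index under left truncation.

Because cohort proteomics data cannot be redistributed, the package ships a
generator (`protage.simcohort`) producing cohorts with the assumed
structure: a latent global acceleration (years), organ-specific components,
age-linked protein blocks, lifestyle effects that shift the acceleration,
and Gompertz-Makeham survival whose hazard multiplies by `exp(gamma)` per
year of acceleration. Every statistical claim in the test suite is checked
against this known truth or an independent oracle.

## Worked example

```python
import numpy as np, pandas as pd
from protage import (SimConfig, simulate_cohort, simulate_survival,
                     sample_case_cohort, train_clock, apply_clock,
                     lowess_detrend, zscore_gaps, prentice_weights,
                     fit_stratified_cox, make_stratum, per_year_effect)

config = SimConfig(n_subjects=3000, n_proteins=150, n_organs=2,
                   organ_block_size=15, seed=42)
cohort, proteins, latent = simulate_cohort(config)
ages = pd.Series(cohort["age"].to_numpy(), index=proteins.index)

train_ids, score_ids = proteins.index[:1000], proteins.index[1000:]
clock = train_clock(proteins.loc[train_ids], ages.loc[train_ids], seed=0)
pred = apply_clock(proteins.loc[score_ids], clock)

gap = lowess_detrend(pred, ages.loc[score_ids])
gap_z = zscore_gaps(gap)

events = simulate_survival(cohort, latent, config, seed=1)
events = events[events["subject_id"].isin(score_ids)]
cc = sample_case_cohort(events, 0.3, seed=2)
sub = cohort.set_index("subject_id").loc[cc["subject_id"]]
cc["stratum"] = make_stratum(sub["sex"], sub["center"], cc["entry_age"]).to_numpy()
cc["gap_z"] = gap_z.loc[cc["subject_id"]].to_numpy()
res = fit_stratified_cox(prentice_weights(cc), "gap_z", endpoint="mortality")
```

This prints, with the formatting of the example script:

```
clock uses 101 analytes; r(predicted, chronological) = 0.895
age gap SD = 3.40 years; r(gap, age) = +0.0016
mortality HR per gap z-score = 1.30 (95% CI 1.15-1.47), 526 events in 982 records
per year of age gap: 8.0% excess hazard
```

Reading it: the elastic-net clock tracks chronological age (r = 0.90); the
lowess-detrended gap is uncorrelated with age by construction, with an SD
of 3.4 years; one SD of gap carries a 30% higher mortality hazard in the
Prentice-weighted case-cohort fit, i.e. about 8% per year of biological
age — consistent with the generating hazard, which couples mortality to the
latent acceleration at hazard ratio 1.4 per 3-year SD.

The full pipeline (QC, five conventional clocks, organ clocks, Global
ensemble, base and risk-factor-adjusted models for every endpoint, FDR,
risk-factor models, age-relatedness, lasso selection, concordance) runs
from a YAML config:

```sh
protage run --config run.yaml
protage simulate --out simdir --seed 3      # just the synthetic data
```

Outputs are TSV tables plus a `manifest.json` recording the seed, versions
and subject counts at every exclusion step; identical config and seed give
byte-identical outputs.

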