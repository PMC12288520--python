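# Methods

This note records the statistical model behind `protage`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Latent-acceleration model of the synthetic cohort

Each subject carries a latent global acceleration `A_i` (years), drawn
`N(0, sigma_accel^2)` plus a lifestyle contribution, and organ-specific
accelerations `A_ik = A_i + N(0, sigma_organ^2)`. Age-linked proteins obey

    x_ij = a_j + b_j * (age_i + A_i*) + e_ij,   e ~ N(0, sigma_noise^2),

where `A_i*` is the organ acceleration for organ-annotated analytes and the
global one otherwise; intensities are floored at a tiny positive value so
relative-fluorescence positivity holds. Protein intercepts are uniform on
[10, 20] and slope magnitudes on [0.02, 0.06] with random sign; a fraction
`frac_age_proteins` (default 0.5) of analytes carries age signal at all.
Organ-enriched analytes form disjoint blocks of `organ_block_size` per
organ with enrichment fold-changes uniform on [4, 10]; all other analytes
sit below 4, so a fold-4 threshold recovers the blocks exactly and the
remaining age-linked analytes are "organismal".

Lifestyle factors (smoking status and intensity, alcohol g/day, BMI, diet
score, activity METs, education) have independent marginals chosen to look
like a middle-aged European cohort; their joint distribution is a
convention, not an estimate. They act on biology *only* through
`accel_global`, additively in years (default effects: +1 yr for current
smoking, +0.05 yr per cigarette/day, +0.02 per alcohol g/day, +0.08 per
BMI unit, -0.15 per diet point, -0.01 per MET, -0.2 per education level;
continuous factors centred at documented population values). This single
pathway is what makes "risk-factor adjustment attenuates the association"
a testable statement with known truth.

Survival follows a Gompertz-Makeham hazard with proportional frailty on
the acceleration,

    h_i(t) = c + a * exp(b*t + gamma * A_i),

with delayed entry at the recruitment age (uniform on `age_range`) and
administrative censoring at `admin_censor_age` (default 75). Defaults
c = 2e-4/yr, a = 2e-5/yr, b = 0.10/yr give life-table-like adult mortality;
gamma defaults to ln(1.4)/3 so that one SD (3 yr) of acceleration carries a
hazard ratio of 1.4, the scale of the strongest clock-mortality
associations reported for ensemble clocks. Event ages are drawn by inverse
transform of the cumulative hazard on a fixed 0.01-year grid with linear
interpolation (the Gompertz-Makeham CDF has no closed-form inverse);
the pure-Gompertz limit is tested against the closed-form inversion.

Case-cohort sampling marks an independent Bernoulli subcohort (fraction
default 0.3) and retains all cases; one subcohort draw is shared across
endpoints, as in a real multi-endpoint case-cohort study.

## Clocks and age gaps

Clocks are trained by cross-validated elastic net (mixing 0.5, lambda at
the 5-fold CV minimum) on column-standardized intensities; zero-variance
columns are dropped. The returned spec stores training means/SDs as
z-score preprocessing, so application elsewhere reproduces the fitted
model exactly. Published-style clocks are emulated by training each
"conventional" clock on a random 60% of analytes, on a training split
disjoint from the analysis cohort (the real clocks were trained in other
populations; in-sample gaps would be optimistically small). Organ clocks
restrict to fold-4-enriched analytes per organ; the organismal clock uses
the below-threshold remainder. Missing analytes abort rather than impute:
silently imputing changes a published clock's meaning.

QC flags multivariate outliers by projecting the log10, column-standardized
matrix onto the top principal components (default 10), scoring each subject
with a local outlier factor (default 20 neighbours) and applying Tukey's
rule (Q3 + 1.5 IQR) to the scores. On a finite Gaussian cloud the LOF score
distribution has a heavy right tail, so the default fence flags a small
percentage of unremarkable subjects along with any true outlier; the
multiplier is configurable and the far-out fence (k = 5) isolates gross
outliers only.

The age gap is the residual of predicted age around a tricube local-linear
smoother of predicted on chronological age, span 2/3, zero robustifying
iterations (the iteration count is the simplest choice and is
configurable), evaluated at each observed age. The smoother follows the
classic first-pass lowess algorithm (nearest-neighbour window,
`int(frac*n)` points, cutoffs at 0.999/0.001 of the half-width, variance
guard on the slope); an independent reference implementation reproduces it
to 1e-6. Note the smoother absorbs any affine calibration error of a
clock — a clock that over-predicts everyone by five years has zero gaps.
Gaps are z-scored with the n-1 SD convention over the full analysis
sample by default (a subcohort-only scoring population is an option; which
one a given study used is rarely stated). The Global gap is the unweighted
mean of the five conventional clocks' gaps (organ clocks excluded),
z-scored the same way. Per-year effects divide the per-z log hazard by the
gap SD in years.

## Case-cohort inference

The Cox engine maximizes the stratified, left-truncated, weighted partial
likelihood by Newton iteration with step-halving (gradient tolerance
1e-9, 50 iterations, collinear designs rejected naming the aliased pair).
Risk sets use (entry, exit] intervals; Breslow tie handling, because the
Prentice risk-set algebra stays clean under weights and simulated
continuous ages make ties measure-zero (a rounded-ages test covers the
tied case against a brute-force likelihood). Prentice weighting moves a
non-subcohort case's entry to its exit minus epsilon = 1e-6 yr; estimates
are invariant to epsilon over 1e-4 to 1e-8 except when another event time
falls inside the window (probability of order epsilon). Variances default
to the robust sandwich with score residuals grouped by subject — the
appropriate choice under case-cohort weighting — with the model-based
inverse information available by flag. Strata are sex x center x 5-year
age band aligned to multiples of five. Missing covariates in ingested data
get single mean/mode imputation with a logged count via
`impute_covariates` (a multiply-imputed alternative is out of scope;
`method="none"` rejects missingness instead).

Benjamini-Hochberg q-values are computed per analysis family (conventional
clocks and organ clocks separately, per model). Harrell's C counts a pair
usable when one member fails at t and the other is under observation at t
(entered before, exits after), with score ties at one half; this respects
left truncation, which off-the-shelf concordance routines do not.
Concordance CIs are subject-level bootstrap percentiles (200 resamples)
with the fitted linear predictor held fixed.

Lasso selection penalizes the candidate gap coefficients (standardized
scale) while adjustment covariates stay unpenalized, solved by prox-Newton
with an inner coordinate descent over a 30-point log-spaced lambda path
(warm starts, lambda_min = 1e-3 lambda_max). Cross-validation uses the
Verweij-van Houwelingen partial-likelihood deviance, normalized per
held-out event and averaged with event-count weights — the cv.glmnet
convention, which keeps fold composition out of the SE. Two lambda rules
are offered: the CV minimum (default; best prediction, but it carries
small-coefficient extras — the known behaviour of CV-tuned lasso) and the
one-SE rule (sparsest lambda within one SE of the minimum), which is the
convention when the goal is support recovery and is what the recovery
experiments use. The selected set is refit unpenalized with the risk
factors. The path was cross-checked against an independent penalized-Cox
implementation at a fixed lambda.

Lag sensitivity recodes events within 2 or 5 years of recruitment as
censored, drops the resulting non-subcohort non-cases (they no longer
belong to a Prentice sample), and refits.

## Age-relatedness

Incidence is tabulated in 5-year bands (person-years by interval overlap,
events by exit age); the Gompertz-Makeham Poisson likelihood is evaluated
at band midpoints and maximized by L-BFGS-B from 20 log-spaced starts of b
in [1e-3, 0.3]/yr, with c >= 0 (a boundary solution is flagged, not
rejected) and the SE of b from a finite-difference observed information.
Spearman correlation between per-endpoint log hazards and b uses an exact
permutation p-value for n <= 10 and the large-sample approximation above.
When external registry coefficients are supplied
(`analysis.external_betas`), they replace the cohort-fitted slopes in the
correlation — the published coefficients the design imitates come from
millions of records and carry negligible sampling error, whereas slopes
fitted to a few hundred cases per endpoint do not; the acceptance script
uses registry-scale expected-count fits for exactly this reason.
Association heatmaps are ordered by complete-linkage clustering of
Euclidean distances, rows and columns independently.

## Pipeline and reproducibility

`run_analysis` executes simulate -> QC -> clock training (on a disjoint
training split of the same simulated world, so protein structure is
shared) -> gaps -> associations (base and adjusted; FDR per family) ->
risk factors (subcohort only) -> age-relatedness -> lasso and concordance
-> lag sensitivity, writing TSVs, a manifest (versions, seed, counts at
each exclusion; no timestamps, so identical runs are byte-identical) and a
log. One top-level seed derives per-stage seeds as
`SeedSequence([seed, crc32(stage_name)])`, so stages are independently
reproducible and adding a stage never perturbs the others. A stage failure
aborts with the stage name and persists partial outputs.

The acceptance run uses 4000 analysis subjects, 1500 training subjects,
200 proteins, three organs, and mortality plus 13 diseases with Gompertz
slopes spanning 0.02-0.14/yr whose acceleration couplings track the slope
with mild scatter (emulating the empirical pattern that strongly
age-related diseases couple more tightly to biological aging). These sizes
keep a full run around a minute while leaving every estimate comfortably
identified.

## What the synthetic experiments show — and what they do not

Passing tests show the *estimators* are correct and calibrated under the
assumed data-generating process: linear age signal plus additive latent
acceleration, proportional hazards with log-linear frailty, independent
lifestyle marginals acting through one pathway, and missingness-free
proteomics. Real cohort data violate most of these in some degree —
batch and plate effects, assay calibration drift, non-proportional
hazards, correlated lifestyle factors, informative censoring, competing
risks — and none of those are simulated (deliberately: the generator
isolates the inferential machinery). Recovery of a hazard ratio of 1.4 per
acceleration SD here therefore validates the pipeline's arithmetic, not
any claim about real proteomes. Clock-mortality hazard ratios estimated
from gap z-scores are attenuated relative to the generating frailty
(the gap is a noisy proxy of the latent acceleration); the package reports
what the data identify and makes no deattenuation correction.

## Known limitations

- Single baseline measurement; no longitudinal gap trajectories.
- Breslow ties only; no Efron option.
- No competing-risks or time-varying-coefficient models; Prentice is the
  only case-cohort weighting scheme offered.
- The Gompertz fit uses band midpoints, adequate for 5-year bands but
  biased for very wide bands.
- The lasso CV-minimum rule over-selects by design; use the one-SE rule
  when the support itself is the question.
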