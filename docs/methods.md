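# Methods

`gsos-screen` simulates and evaluates a genomics-enabled osteoporosis
screening program: a polygenic score for heel ultrasound speed of sound
(SOS) is trained from genotype dosages, then used as a pre-screening gate in
a staged NOGG/FRAX screening algorithm, and the resulting trade-off between
screening-test burden and correct treatment assignment is quantified against
a BMD-based reference standard. This note records the models, the defaults
and their rationale, the numerical choices, and what the synthetic data do
and do not establish.

## 1. Synthetic cohorts

### Genotypes

Dosages are hard calls in {0, 1, 2}. For each individual, two latent
standard-Gaussian haplotype processes run across SNPs as a block AR(1):
within a block of `block_size` SNPs (default 10), `z_j = rho * z_{j-1} +
sqrt(1 - rho^2) * eps_j` with `block_rho` (default 0.8); blocks are
independent. Each latent is thresholded at `Phi^-1(maf_j)` into an allele
indicator, and the dosage is the sum of the two indicators, so every SNP is
in Hardy–Weinberg equilibrium at its allele frequency (drawn uniformly from
`maf_range`, default 0.05–0.5). This reproduces the one feature of linkage
disequilibrium that drives clumping and penalized-regression behavior —
blocks of positively correlated neighboring markers — at a fraction of the
cost of a coalescent simulation. Not modeled: long-range LD, allele-frequency
/ LD-decay coupling, population structure, imputation uncertainty,
missingness, X chromosome.

### Phenotypes

A chosen set of `n_causal` SNPs receives i.i.d. N(0,1) effects. The
standardized true genetic score contributes a variance fraction `h2_sos`
(default 0.25) to SOS, the remainder is Gaussian noise, and SOS is
re-standardized to mean 0, SD 1. The femoral-neck T-score is the Gaussian
mixture `rho * SOS + sqrt(1 - rho^2) * noise` with `sos_bmd_corr` (default
0.5, inside the 0.4–0.6 range reported for the two bone measures), plus a
deterministic location shift: −0.3 at age 50 for men, a further −0.3 for
women, and −0.02 T-score units per year after age 50. The partial
correlation of T-score and SOS given age and sex therefore equals
`sos_bmd_corr` by construction.

### Risk factors

The binary FRAX clinical risk factors are independent Bernoulli draws. Two
prevalence profiles ship with the package:

* `DEFAULT_PREVALENCES` — a middle-aged population-biobank profile (e.g.
  prior fracture 10.2%, smoking 8.0%, glucocorticoids 1.0%); alcohol
  (17.7%) and parental hip fracture (12.2%) default to rates typical of a
  population aging study because large biobanks often lack them.
* `VALIDATION_PREVALENCES` — the older, fracture-enriched profile of
  dedicated osteoporosis screening cohorts (prior fracture 21%, smoking
  10.3%, glucocorticoids 4.2%, …), used by `simulate_screening_cohort`.

Prior fracture gets a logistic age tilt of +0.06 log-odds per year centered
at the mid-age of the simulated range, since fracture history accumulates
with age; the other factors are flat by default. The joint distribution of
risk factors is otherwise independent — a pragmatic simplification, since no
generative model for their dependence is available.

`simulate_screening_cohort` generates an already-eligible population (age ≥
50, ≥1 risk factor, T-score present) in which the polygenic score is drawn
directly as a Gaussian with a configurable correlation to the de-trended BMD
latent (default 0.45) rather than retrained — for screening-strategy
experiments only the joint distribution of score and BMD matters.

## 2. FRAX surrogate

The real FRAX calculator is proprietary; the analysis consumes only its
outputs, so the package substitutes a transparent monotone parametric model
and accepts externally computed probabilities verbatim whenever `crf_frax` /
`bmd_frax` columns are already present. The 10-year major-osteoporotic-
fracture probability is a complementary log-log transform of a Gompertz-like
hazard:

    P = 100 * (1 - exp(-H))
    H = s_sex * exp(b_age (age-50) + Σ_f log RR_f x_f + b_BMI (BMI-25)
                    [+ b_T (t_center - T)])

with the bracketed term only in the BMD-based score. Defaults: `s_female =
0.036`, `s_male = 0.024`, `b_age = 0.069`/year, relative risks 1.8 (prior
fracture), 1.6 (glucocorticoids), 1.5 (parental hip fracture), 1.3
(rheumatoid arthritis, secondary osteoporosis), 1.25 (smoking), 1.2
(alcohol), `b_BMI = -0.015`/unit, `b_T = log(1.6)` per T-score unit,
`t_center = -1.0`. They were fixed once against published cohort tables:
the baseline scales and age slope put the mean CRF score of a mixed-sex
cohort around age 57 near 5–6% and of an all-female cohort around age 71
near 19–21%, and `t_center` sits at the mean T-score of a screening-eligible
population so that the CRF-based and BMD-based probabilities agree on
average, as cohort tables show for the real calculator. Ages outside
[50, 90] are clamped with a logged warning. Competing mortality is not
modeled separately; the age slope absorbs it. Country-specific FRAX variants
collapse to this single parameterization.

The age-specific intervention threshold IT(age) is, as in the NOGG
guidance, the CRF-based probability of a reference woman (BMI 25) of that
age whose only risk factor is a prior fragility fracture.

## 3. Polygenic score training

The cohort is split uniformly at random into training / model-selection /
test sets (default fractions 0.80 / 0.0125 / 0.1875).

**Association scan.** Each SNP is tested separately by OLS of the phenotype
on dosage plus covariates, computed by residualizing both sides against the
covariate block (exact for the joint model); p-values come from the t
statistic of the dosage term. The pipeline's covariates are age, sex and
the top 10 genotype principal components. A linear mixed model is
unnecessary here because the generator produces no cryptic relatedness;
PCs stand in for the population-stratification adjustment. Monomorphic SNPs
are flagged with beta 0, p 1.

**LD clumping** is greedy: repeatedly take the most significant unassigned
SNP with p ≤ p_max as an index SNP and remove every SNP whose squared
dosage correlation with it exceeds `r2_max` (default 0.05). Ties on p go to
the smaller column index; correlations are computed on the training subset.

**LASSO path.** For each p-value threshold in {5e-8, 5e-6, 5e-4, 5e-3,
5e-2, 1} (six nested SNP sets; configurable), the solver minimizes
`(2n)^-1 ||y - Xb||^2 + lambda ||b||_1` on the column-standardized dosage
submatrix by cyclic coordinate descent on the Gram matrix, warm-started down
50 log-spaced penalties from `lambda_max` to `0.001 * lambda_max`.
Convergence is declared when the largest coefficient change in a sweep falls
below 1e-7 (standardized scale), with a 10,000-sweep cap and a hard error
otherwise; KKT subgradient residuals are recorded for every solution. The
Gram matrix of the largest SNP set is computed once and sliced for the
nested subsets. The phenotype is residualized against the covariates before
the fit, keeping the design genotype-only so the resulting score predicts
the phenotype from genotype alone; covariates could alternatively enter
unpenalized, but residualization keeps the score portable to cohorts with
different covariate distributions.

**Model selection.** Every (threshold, lambda) candidate is scored by RMSE
on the model-selection set; exactly one winner goes forward. Ties go to the
sparser candidate, then the larger penalty. The selected score ("gSOS") is
standardized to mean 0, SD 1 on a stated reference population (the test set
in the pipeline), with the constants stored in the model file.

**Comparator.** Traditional clump+threshold scores use the GWAS betas of
clumped index SNPs passing each threshold, zero intercept.

**Variance explained** is the squared Pearson correlation; its 95% CI is a
nonparametric percentile bootstrap over individuals (1,000 replicates) —
the CI method for the published figure is unstated, and the bootstrap is the
assumption-light default.

## 4. Screening strategies

Eligibility: age ≥ 50, at least one FRAX clinical risk factor, T-score
available. Ineligible individuals are recorded as `not_screened` and enter
no denominator.

Base strategy: women ≥ 50 with a prior fragility fracture are recommended
treatment with zero FRAX tests. Everyone else receives CRF-FRAX;
≥ 1.2 × IT(age) means treat, below the lower assessment threshold means
reassure, and the intermediate band receives BMD-FRAX with treatment iff
BMD-FRAX ≥ IT(age). The lower assessment threshold defaults to the CRF
score of a same-age reference woman with no risk factors (a fixed
multiplier of IT is available instead); the published analysis never prints
its assessment-band bounds, so both bounds are configurable and every
report embeds the values used.

Gated strategy: after the auto-treat check, any individual whose
standardized score strictly exceeds the sex-specific threshold (defaults
0.5 men / 0.0 women) is reassured with no further testing. Auto-treatment
precedes the gate because those women are assigned intervention by the
reference standard; gating them out would contradict it (configurable).
`gate_placement="after_crf"` instead applies the gate only to individuals
left unresolved by CRF-FRAX. All treat-side comparisons use ≥, and the gate
uses strict >, so ties are deterministic and a +inf threshold reproduces
the base strategy exactly, field by field.

Reference standard: treat iff BMD-FRAX ≥ IT(age), or auto-treated woman.

## 5. Evaluation

Confusion counts take the reference's treat/reassure as truth and the
strategy's recommendation as prediction (gate-excluded individuals are
predicted reassure). Sensitivity, specificity, PPV and NPV are percentages;
empty denominators yield `None` plus a flag, never 0. Test burden is the
percentage of the eligible population receiving each FRAX test and the
percentage of those tests ending in reassurance. Strategy comparisons report
`100 * (1 - variant/base)` per test type (rounded to 0 decimals in reports;
accuracy metrics to 1, matching the field's reporting style).

Threshold selection formalizes the published visual trade-off as a
constrained optimization: per sex, over a grid that must include +inf,
choose the threshold minimizing BMD tests that end in reassurance subject to
sensitivity ≥ `min_sensitivity` (default 90%); ties go to the larger
threshold, and if nothing qualifies the gate is disabled. The exact
operational rule behind the published 0.5/0 choice is unstated; the
constraint form makes the choice reproducible and auditable by exhaustive
grid re-evaluation.

## 6. Problem sizes and what the tests show

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which the phenomena of interest are stable: score
training on 25,000 individuals × 2,000 SNPs (200 causal, h² = 0.25; splits
20,000 / 1,000 / 4,000) and screening on 10,000 eligible individuals with a
score–BMD correlation of 0.45. At these sizes the selected score recovers
≥ 90% of the predictable variance ratio and the gate cuts BMD testing by
~40% at ~92% sensitivity — directionally and often numerically close to the
published large-cohort results, but the published headline values
themselves were computed on restricted-access cohorts two orders of
magnitude larger and are not reproduction targets. Passing tests establish
that the algorithms are implemented correctly and behave as the design
predicts on data with the assumed structure; they cannot establish
real-data properties the generator does not model (ancestry structure,
genotyping artifacts, non-Gaussian phenotypes, correlated risk factors,
true FRAX nonlinearities).

## 7. Known limitations

* The FRAX surrogate is monotone and well-calibrated in the mean but makes
  no claim of matching real FRAX probabilities individual by individual.
* Risk factors are conditionally independent given age; real comorbidity
  clustering would change burden estimates somewhat.
* The LASSO solver targets dense Gram matrices up to ~50k SNPs in memory;
  it is not a genome-wide (millions of SNPs) solver.
* Bootstrap CIs assume exchangeable individuals (no relatedness).
* One surrogate parameterization stands in for country-specific FRAX
  models; hip-fracture-specific thresholds are out of scope.
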