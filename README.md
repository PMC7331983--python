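# gsos-screen

Polygenic pre-screening for fracture-risk programs: train a polygenic score
for heel ultrasound speed of sound (gSOS), gate a staged NOGG/FRAX
osteoporosis screening algorithm on it, and measure what the gate buys —
fewer screening tests — and what it costs — missed treatment
recommendations.

## The problem

Staged fracture-risk screening first computes a clinical-risk-factor FRAX
probability (CRF-FRAX) for everyone eligible, sends the intermediate-risk
band for a bone-mineral-density measurement and a BMD-based FRAX
(BMD-FRAX), and recommends treatment when the 10-year probability of major
osteoporotic fracture exceeds an age-specific intervention threshold
IT(age) — the probability of a same-age woman with a prior fragility
fracture. Most people screened end up reassured, so most of the testing
budget is spent on individuals who needed no intervention. Because bone
strength is highly heritable, a polygenic score available from a one-time
genotyping can identify people whose genetic bone profile makes a
treatment-level result unlikely, and excuse them from testing altogether.

This package implements that whole analysis as a reusable, tested pipeline:

* **`synthetic`** — cohort generator: LD-structured genotype dosages
  (block-AR latent Gaussian, Hardy–Weinberg hard calls), a polygenic
  standardized SOS phenotype with configurable heritability, a femoral-neck
  T-score correlated with SOS (r = 0.4–0.6 range), FRAX risk factors at
  realistic prevalences, plus ground truth for recovery tests.
* **`frax`** — a transparent parametric surrogate for the proprietary FRAX
  calculator: `P = 100(1 − exp(−H))` with a Gompertz-like hazard
  `H = s_sex · exp(b_age(age−50) + Σ log RR_f · x_f + b_BMI(BMI−25)
  [+ b_T(t_c − T)])`, monotone in every input; externally computed
  probabilities are used verbatim if supplied.
* **`prs`** — training/model-selection/test splits (80 / 1.25 / 18.75%),
  per-SNP OLS association scan, greedy LD clumping (r² > 0.05), LASSO
  paths by coordinate descent over p-value-thresholded SNP sets with
  held-out RMSE model selection, traditional clump+threshold comparators,
  scoring with allele flipping and reference standardization, bootstrap
  r² confidence intervals.
* **`screening`** — the NOGG decision algorithm, its gSOS-gated variant
  (gate before or after CRF-FRAX; auto-treatment of women ≥ 50 with prior
  fracture precedes the gate), and the BMD-FRAX reference standard, with a
  full per-individual decision trace.
* **`evaluation`** — sensitivity/specificity/PPV/NPV of correct treatment
  assignment, test-burden percentages, relative reductions between
  strategies, constrained sex-specific gate-threshold selection, stratified
  reports.
* **`io` / `pipeline` / `cli`** — TSV cohorts, PLINK-`.raw`/VCF genotypes,
  PGS-Catalog-style scoring files, YAML configs, and a deterministic
  end-to-end runner (same config ⇒ byte-identical artifacts).

See `docs/methods.md` for models, defaults, and rationale.

## Worked example

```python
import gsos_screen as gs

# an eligible screening cohort with a polygenic score correlated 0.45
# with the (de-trended) BMD latent
cohort = gs.simulate_screening_cohort(10_000, gsos_bmd_corr=0.45, seed=1)

ref   = gs.reference_standard_cohort(cohort)          # BMD-FRAX truth
base  = gs.performance_report(gs.screen_cohort(cohort, strategy="nogg"), ref)
gated = gs.performance_report(gs.screen_cohort(cohort, strategy="gsos-nogg"), ref)
cmp   = gs.compare_strategies(base, gated)

print(f"base : sens {base.sensitivity:.1f}%  spec {base.specificity:.1f}%  "
      f"CRF {base.pct_crf_tested:.0f}%  BMD {base.pct_bmd_tested:.0f}%")
print(f"gated: sens {gated.sensitivity:.1f}%  spec {gated.specificity:.1f}%  "
      f"CRF {gated.pct_crf_tested:.0f}%  BMD {gated.pct_bmd_tested:.0f}%")
print(f"relative reductions: CRF {cmp.rounded()['rel_reduction_crf']}%, "
      f"BMD {cmp.rounded()['rel_reduction_bmd']}%")
```

prints

```
base : sens 98.8%  spec 99.7%  CRF 74%  BMD 55%
gated: sens 91.0%  spec 99.9%  CRF 46%  BMD 32%
relative reductions: CRF 39%, BMD 41%
```

Read: without the gate, 74% of the eligible population needs a CRF-FRAX
test and 55% a BMD measurement to reach 98.8% sensitivity against the
BMD-FRAX reference. Gating on the polygenic score (reassure men above +0.5
SD, women above 0 SD) cuts BMD testing by 41% while sensitivity falls ~8
points and specificity ticks up — the burden/accuracy trade-off the
screening analysis quantifies.

The full pipeline (genotypes → GWAS → LASSO → score → screen → evaluate)
runs from one config:

```bash
gsos-screen run-all --seed 1 --out-dir run1        # or run_pipeline(RunConfig(...))
```

and writes the cohort, GWAS table, scoring file, decision traces, and
JSON reports, all stamped with the config hash and seed.

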