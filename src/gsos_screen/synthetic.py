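"""Synthetic cohort generation.

Generates cohorts with the statistical structure the screening analysis
assumes: LD-structured biallelic dosages, a polygenic standardized heel
ultrasound speed-of-sound (SOS) phenotype, a femoral-neck BMD T-score
correlated with SOS, and binary FRAX clinical risk factors at realistic
prevalences.  Every downstream stage of the pipeline is testable against
cohorts produced here, with the generating truth retained for
parameter-recovery checks.

LD is modeled as a block-autoregressive latent Gaussian: within a block of
``block_size`` adjacent SNPs the two latent haplotype processes follow an
AR(1) with coefficient ``block_rho``; thresholding each latent at the
normal quantile of the allele frequency yields two Hardy-Weinberg allele
draws per individual, and the dosage is their sum.  This is cheap,
controllable, and reproduces the feature that matters for clumping and
LASSO behavior -- correlated neighboring markers -- without a coalescent
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypePanel",
    "TrueGeneticModel",
    "DEFAULT_PREVALENCES",
    "DEFAULT_AGE_TILTS",
    "RISK_FACTOR_COLUMNS",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_risk_factors",
    "assemble_cohort",
    "simulate_screening_cohort",
]

#: FRAX clinical risk factors carried by every cohort table.
RISK_FACTOR_COLUMNS = (
    "prior_fracture",
    "smoking",
    "glucocorticoids",
    "rheumatoid_arthritis",
    "secondary_osteoporosis",
    "parental_hip_fracture",
    "alcohol",
)

#: Default risk-factor prevalences for a UK-Biobank-like middle-aged cohort.
#: Alcohol (>2 units/day) and parental hip fracture are unavailable in UK
#: Biobank and default to rates typical of the Canadian Longitudinal Study
#: on Aging.
DEFAULT_PREVALENCES: dict[str, float] = {
    "prior_fracture": 0.102,
    "smoking": 0.080,
    "glucocorticoids": 0.010,
    "rheumatoid_arthritis": 0.010,
    "secondary_osteoporosis": 0.043,
    "parental_hip_fracture": 0.122,
    "alcohol": 0.177,
}

#: Risk-factor prevalences typical of dedicated osteoporosis screening
#: cohorts (age >= 50, enriched for fracture history relative to a
#: middle-aged biobank); used by :func:`simulate_screening_cohort`.
VALIDATION_PREVALENCES: dict[str, float] = {
    "prior_fracture": 0.21,
    "smoking": 0.103,
    "glucocorticoids": 0.042,
    "rheumatoid_arthritis": 0.034,
    "secondary_osteoporosis": 0.023,
    "parental_hip_fracture": 0.103,
    "alcohol": 0.065,
}

#: Per-year log-odds tilt applied around the mid-age of the simulated range,
#: so prevalence rises with age while the cohort-wide rate stays close to the
#: nominal value.  Only prior fracture gets a tilt by default: fracture
#: history accumulates with age, whereas smoking and the rarer factors are
#: roughly flat over 50-85 in cohort tables.
DEFAULT_AGE_TILTS: dict[str, float] = {"prior_fracture": 0.06}

# BMD T-score generative defaults: mean T at age 50 for men, the additional
# deficit in women at 50, and the per-year decline after age 50.
_T_BASELINE = -0.3
_T_FEMALE_OFFSET = -0.3
_T_AGE_SLOPE = 0.02


@dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix with per-SNP metadata."""

    dosages: np.ndarray  # (n_individuals, n_snps), values in [0, 2]
    snp_ids: list[str]
    positions: np.ndarray  # int basepair coordinates
    effect_alleles: list[str]
    allele_freqs: np.ndarray  # generating frequency of the effect allele

    def __post_init__(self) -> None:
        n_snps = self.dosages.shape[1]
        if not (
            len(self.snp_ids)
            == len(self.positions)
            == len(self.effect_alleles)
            == len(self.allele_freqs)
            == n_snps
        ):
            raise ValueError("SNP metadata length does not match dosage columns")
        if np.isnan(self.dosages).any():
            raise ValueError("dosage matrix contains missing values")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, snp_idx: np.ndarray) -> "GenotypePanel":
        snp_idx = np.asarray(snp_idx)
        return GenotypePanel(
            dosages=self.dosages[:, snp_idx],
            snp_ids=[self.snp_ids[j] for j in snp_idx],
            positions=self.positions[snp_idx],
            effect_alleles=[self.effect_alleles[j] for j in snp_idx],
            allele_freqs=self.allele_freqs[snp_idx],
        )

    def subset_individuals(self, idx: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            dosages=self.dosages[np.asarray(idx), :],
            snp_ids=list(self.snp_ids),
            positions=self.positions,
            effect_alleles=list(self.effect_alleles),
            allele_freqs=self.allele_freqs,
        )


@dataclass
class TrueGeneticModel:
    """Ground truth of the generative polygenic model, for recovery tests."""

    causal_indices: np.ndarray
    causal_effects: np.ndarray
    h2_target: float

    def genetic_score(self, panel: GenotypePanel) -> np.ndarray:
        """Standardized true genetic score of *panel* individuals."""
        g = panel.dosages[:, self.causal_indices] @ self.causal_effects
        return (g - g.mean()) / g.std()


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    block_size: int = 10,
    block_rho: float = 0.8,
    seed: int = 0,
) -> GenotypePanel:
    """Draw an LD-structured biallelic dosage panel.

    Two latent Gaussian haplotype processes per individual follow a block
    AR(1) across SNPs; each is thresholded at ``Phi^-1(maf)`` into an allele
    indicator and the two indicators are summed into a hard-call dosage
    (0/1/2).  Within a block, adjacent SNPs share positive LD governed by
    ``block_rho``; blocks are independent.

    Parameters
    ----------
    maf_range
        Interval (subset of (0, 0.5]) from which per-SNP effect-allele
        frequencies are drawn uniformly.
    block_size
        Number of adjacent SNPs per LD block.
    block_rho
        AR(1) coefficient of the latent process within a block, in [0, 1).
    """
    if n_individuals < 1 or n_snps < 1:
        raise ValueError("n_individuals and n_snps must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must be within (0, 0.5], got {maf_range}")
    if not (0.0 <= block_rho < 1.0):
        raise ValueError(f"block_rho must be in [0, 1), got {block_rho}")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")

    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    thresholds = stats.norm.ppf(mafs)

    dosages = np.empty((n_individuals, n_snps), dtype=np.float64)
    innov = np.sqrt(1.0 - block_rho**2)
    # two independent latent haplotype tracks
    z = np.empty((2, n_individuals))
    for j in range(n_snps):
        eps = rng.standard_normal((2, n_individuals))
        if j % block_size == 0:  # block boundary: restart the AR process
            z[:] = eps
        else:
            z = block_rho * z + innov * eps
        # sum of two Hardy-Weinberg allele indicators (cast: bool+bool is OR)
        dosages[:, j] = (z[0] < thresholds[j]).astype(np.int8) + (z[1] < thresholds[j])

    bases = ("A", "C", "G", "T")
    return GenotypePanel(
        dosages=dosages,
        snp_ids=[f"rs{j + 1:07d}" for j in range(n_snps)],
        positions=np.arange(1, n_snps + 1, dtype=np.int64) * 5_000,
        effect_alleles=[bases[j % 4] for j in range(n_snps)],
        allele_freqs=mafs,
    )


def simulate_phenotypes(
    panel: GenotypePanel,
    n_causal: int,
    h2_sos: float,
    sos_bmd_corr: float = 0.5,
    age_bmd_slope: float = _T_AGE_SLOPE,
    seed: int = 0,
    age: np.ndarray | None = None,
    sex: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, TrueGeneticModel]:
    """Simulate standardized SOS and a correlated femoral-neck T-score.

    ``n_causal`` SNPs receive N(0,1) effects; the standardized true genetic
    score contributes a variance fraction ``h2_sos`` to SOS, the remainder
    being Gaussian noise, and SOS is re-standardized empirically.  The
    T-score is built from the mixture ``rho*sos + sqrt(1-rho^2)*noise`` so
    that its partial correlation with SOS given age and sex equals
    ``sos_bmd_corr``; its location declines by ``age_bmd_slope`` T-units per
    year after age 50 and is 0.3 lower in women.

    Returns the SOS vector, the T-score vector, and the generating truth.
    """
    if not (0.0 < h2_sos < 1.0):
        raise ValueError(f"h2_sos must be in (0, 1), got {h2_sos}")
    if not (0.0 < sos_bmd_corr <= 1.0):
        raise ValueError(f"sos_bmd_corr must be in (0, 1], got {sos_bmd_corr}")
    if panel.n_individuals == 0 or panel.n_snps == 0:
        raise ValueError("panel must be nonempty")
    if n_causal > panel.n_snps:
        raise ValueError("n_causal cannot exceed the panel's SNP count")

    rng = np.random.default_rng(seed)
    n = panel.n_individuals

    causal_idx = np.sort(rng.choice(panel.n_snps, size=n_causal, replace=False))
    effects = rng.standard_normal(n_causal)
    truth = TrueGeneticModel(causal_idx, effects, h2_sos)

    g = truth.genetic_score(panel)
    sos = np.sqrt(h2_sos) * g + np.sqrt(1.0 - h2_sos) * rng.standard_normal(n)
    sos_std = (sos - sos.mean()) / sos.std()

    rho = sos_bmd_corr
    latent = rho * sos_std + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    t_mean = np.full(n, _T_BASELINE)
    if age is not None:
        t_mean = t_mean - age_bmd_slope * np.maximum(np.asarray(age, float) - 50.0, 0.0)
    if sex is not None:
        t_mean = t_mean + np.where(np.asarray(sex) == "female", _T_FEMALE_OFFSET, 0.0)
    fn_bmd_tscore = t_mean + latent

    return sos_std, fn_bmd_tscore, truth


def simulate_risk_factors(
    n: int,
    age_range: tuple[float, float] = (50.0, 85.0),
    female_fraction: float = 0.54,
    prevalence_table: dict[str, float] | None = None,
    seed: int = 0,
    age_tilts: dict[str, float] | None = None,
    bmi_mean: float = 27.4,
    bmi_sd: float = 4.6,
) -> pd.DataFrame:
    """Draw demographics and binary FRAX clinical risk factors.

    Ages are uniform on ``age_range``; sex is Bernoulli(``female_fraction``);
    each risk factor is an independent Bernoulli at its table rate, with an
    optional logistic tilt in age (centered at the middle of the age range so
    the cohort-wide rate stays near the nominal prevalence).
    """
    lo, hi = age_range
    if not lo < hi:
        raise ValueError(f"age_range must be a nonempty interval, got {age_range}")
    prevalences = dict(DEFAULT_PREVALENCES)
    if prevalence_table is not None:
        unknown = set(prevalence_table) - set(RISK_FACTOR_COLUMNS)
        if unknown:
            raise ValueError(f"unknown risk factors: {sorted(unknown)}")
        prevalences.update(prevalence_table)
    bad = {k: v for k, v in prevalences.items() if not 0.0 <= v <= 1.0}
    if bad:
        raise ValueError(f"prevalences outside [0, 1]: {bad}")
    tilts = DEFAULT_AGE_TILTS if age_tilts is None else age_tilts

    rng = np.random.default_rng(seed)
    age = rng.uniform(lo, hi, size=n)
    sex = np.where(rng.random(n) < female_fraction, "female", "male")
    bmi = np.clip(rng.normal(bmi_mean, bmi_sd, size=n), 15.0, 55.0)

    table = pd.DataFrame(
        {
            "id": [f"id{i + 1:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "bmi": bmi,
        }
    )
    mid_age = 0.5 * (lo + hi)
    for factor in RISK_FACTOR_COLUMNS:
        rate = prevalences[factor]
        tilt = tilts.get(factor, 0.0)
        if rate in (0.0, 1.0) or tilt == 0.0:
            p = np.full(n, rate)
        else:
            logit = np.log(rate / (1.0 - rate)) + tilt * (age - mid_age)
            p = 1.0 / (1.0 + np.exp(-logit))
        table[factor] = rng.random(n) < p
    return table


def assemble_cohort(
    risk_factors: pd.DataFrame,
    sos_std: np.ndarray,
    fn_bmd_tscore: np.ndarray | None = None,
    gsos: np.ndarray | None = None,
) -> pd.DataFrame:
    """Join demographics/risk factors with phenotypes into one cohort table."""
    n = len(risk_factors)
    if len(sos_std) != n or (fn_bmd_tscore is not None and len(fn_bmd_tscore) != n):
        raise ValueError("row-count mismatch between risk factors and phenotypes")
    if gsos is not None and len(gsos) != n:
        raise ValueError("row-count mismatch between risk factors and gsos")
    if risk_factors["id"].duplicated().any():
        dupes = risk_factors.loc[risk_factors["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in cohort: {dupes[:5]}")
    cohort = risk_factors.copy()
    cohort["sos_std"] = np.asarray(sos_std, dtype=float)
    cohort["fn_bmd_tscore"] = (
        np.nan if fn_bmd_tscore is None else np.asarray(fn_bmd_tscore, dtype=float)
    )
    cohort["gsos"] = np.nan if gsos is None else np.asarray(gsos, dtype=float)
    return cohort


def simulate_screening_cohort(
    n_eligible: int = 10_000,
    gsos_bmd_corr: float = 0.45,
    sos_bmd_corr: float = 0.5,
    age_range: tuple[float, float] = (50.0, 85.0),
    female_fraction: float = 0.54,
    prevalence_table: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a screening-eligible cohort with a pre-made polygenic score.

    For screening-strategy studies the polygenic score itself need not be
    retrained: what matters is its joint distribution with BMD.  Here the
    standardized score (``gsos``), the de-trended BMD latent, and SOS form a
    Gaussian system with corr(gsos, BMD latent) = ``gsos_bmd_corr`` and
    corr(SOS, BMD latent) = ``sos_bmd_corr``; the T-score then gets the same
    age/sex location shifts as :func:`simulate_phenotypes`.  Rows are drawn
    until ``n_eligible`` individuals satisfy the screening entry rule
    (age >= 50, at least one risk factor, T-score available).  Risk-factor
    rates default to :data:`VALIDATION_PREVALENCES`, the older,
    fracture-enriched profile of dedicated screening cohorts.
    """
    if prevalence_table is None:
        prevalence_table = VALIDATION_PREVALENCES
    rng = np.random.default_rng(seed)
    collected: list[pd.DataFrame] = []
    n_have = 0
    attempt = 0
    while n_have < n_eligible and attempt < 50:
        batch = max(2 * (n_eligible - n_have) + 1000, 2000)
        rf = simulate_risk_factors(
            batch,
            age_range=age_range,
            female_fraction=female_fraction,
            prevalence_table=prevalence_table,
            seed=int(rng.integers(2**31)),
        )
        g = rng.standard_normal(batch)
        bmd_latent = gsos_bmd_corr * g + np.sqrt(1 - gsos_bmd_corr**2) * rng.standard_normal(batch)
        sos = sos_bmd_corr * bmd_latent + np.sqrt(1 - sos_bmd_corr**2) * rng.standard_normal(batch)
        t_mean = (
            _T_BASELINE
            - _T_AGE_SLOPE * np.maximum(rf["age"].to_numpy() - 50.0, 0.0)
            + np.where(rf["sex"].to_numpy() == "female", _T_FEMALE_OFFSET, 0.0)
        )
        cohort = assemble_cohort(rf, sos, t_mean + bmd_latent, gsos=g)
        any_factor = cohort[list(RISK_FACTOR_COLUMNS)].any(axis=1)
        eligible = cohort[(cohort["age"] >= 50.0) & any_factor].copy()
        collected.append(eligible)
        n_have += len(eligible)
        attempt += 1
    if n_have < n_eligible:
        raise RuntimeError(
            "could not generate enough screening-eligible individuals; "
            "check prevalence_table and age_range"
        )
    out = pd.concat(collected, ignore_index=True).head(n_eligible).copy()
    out["id"] = [f"id{i + 1:06d}" for i in range(len(out))]
    # re-standardize the score within the eligible sample, as a deployed
    # score would be referenced to its evaluation population
    out["gsos"] = (out["gsos"] - out["gsos"].mean()) / out["gsos"].std()
    return out.reset_index(drop=True)
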