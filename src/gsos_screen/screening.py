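"""Staged fracture-risk screening strategies.

Implements the NOGG-style assessment algorithm, its variant with a polygenic
pre-screening gate, and the BMD-based reference standard used to score
treatment assignments.

The base strategy: women >= 50 with a prior fragility fracture are
recommended treatment outright, without FRAX testing.  Everyone else
eligible receives a risk-factor-based FRAX (CRF-FRAX); a probability at or
above the upper assessment threshold (a multiplier of the age-specific
intervention threshold, IT) means treatment, below the lower assessment
threshold means reassurance, and the intermediate band triggers a BMD-based
FRAX (BMD-FRAX), with treatment iff BMD-FRAX >= IT.  The gated variant
reassures any non-auto-treated individual whose standardized polygenic score
exceeds a sex-specific threshold before (or, optionally, immediately after)
the CRF-FRAX step.

Two implementations are provided deliberately: a per-individual scalar path
(`nogg_screen`, `gsos_nogg_screen`) written as a direct transcription of the
decision flow, and a vectorized cohort path (`screen_cohort`) used by the
pipeline; tests assert they agree field by field.

Threshold conventions: all treat-side comparisons use >= so that ties are
deterministic; the polygenic gate excludes on strictly greater than the
threshold, so a threshold of +inf disables the gate exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .frax import (
    FraxSurrogateParams,
    bmd_frax,
    crf_frax,
    intervention_threshold,
    lower_assessment_threshold,
)
from .synthetic import RISK_FACTOR_COLUMNS

__all__ = [
    "NoggConfig",
    "ScreeningTrace",
    "is_eligible",
    "eligible_mask",
    "nogg_screen",
    "gsos_nogg_screen",
    "reference_standard",
    "screen_cohort",
    "reference_standard_cohort",
    "TRACE_COLUMNS",
]


@dataclass
class NoggConfig:
    """Tunable rules of the screening algorithm."""

    min_age: float = 50.0
    #: upper assessment threshold = multiplier x intervention threshold
    upper_assessment_multiplier: float = 1.2
    #: "reference-woman-no-crf": lower threshold is the CRF-FRAX of a
    #: same-age reference woman without risk factors; "multiplier": use
    #: lower_assessment_multiplier x IT instead.
    lower_assessment_rule: str = "reference-woman-no-crf"
    lower_assessment_multiplier: float = 0.55
    #: standardized polygenic-score thresholds above which individuals are
    #: reassured without further testing
    gsos_thresholds: dict[str, float] = field(
        default_factory=lambda: {"male": 0.5, "female": 0.0}
    )
    gate_placement: str = "before_crf"  # or "after_crf"
    auto_treat_women_prior_fracture: bool = True

    def __post_init__(self) -> None:
        if self.upper_assessment_multiplier <= 0 or self.lower_assessment_multiplier <= 0:
            raise ValueError("assessment multipliers must be positive")
        if self.lower_assessment_rule not in ("reference-woman-no-crf", "multiplier"):
            raise ValueError(f"unknown lower_assessment_rule {self.lower_assessment_rule!r}")
        if self.gate_placement not in ("before_crf", "after_crf"):
            raise ValueError(f"unknown gate_placement {self.gate_placement!r}")
        for sex in ("female", "male"):
            if sex not in self.gsos_thresholds:
                raise ValueError(f"gsos_thresholds missing entry for {sex!r}")
        if any(math.isnan(v) for v in self.gsos_thresholds.values()):
            raise ValueError("gsos thresholds must be finite or +/-inf, not NaN")


@dataclass
class ScreeningTrace:
    """Per-individual decision path through a screening strategy."""

    id: str
    eligible: bool
    excluded_by_gsos: bool = False
    auto_treated: bool = False
    crf_frax_done: bool = False
    crf_frax_value: float | None = None
    risk_band: str | None = None  # low / intermediate / high
    bmd_frax_done: bool = False
    bmd_frax_value: float | None = None
    recommendation: str = "not_screened"  # treat / reassure / not_screened


TRACE_COLUMNS = [
    "id",
    "eligible",
    "excluded_by_gsos",
    "auto_treated",
    "crf_frax_done",
    "crf_frax_value",
    "risk_band",
    "bmd_frax_done",
    "bmd_frax_value",
    "recommendation",
]


def _get(individual, key):
    if key not in individual or pd.isna(individual[key]):
        raise KeyError(f"required field '{key}' is missing")
    return individual[key]


def is_eligible(individual, config: NoggConfig | None = None) -> bool:
    """Screening entry rule: age >= minimum, at least one clinical risk
    factor, and an available femoral-neck T-score."""
    config = config or NoggConfig()
    age = _get(individual, "age")
    for f in RISK_FACTOR_COLUMNS:
        if f not in individual or pd.isna(individual[f]):
            raise KeyError(f"required risk-factor field '{f}' is missing")
    has_factor = any(bool(individual[f]) for f in RISK_FACTOR_COLUMNS)
    has_t = "fn_bmd_tscore" in individual and not pd.isna(individual["fn_bmd_tscore"])
    return bool(age >= config.min_age and has_factor and has_t)


def eligible_mask(cohort: pd.DataFrame, config: NoggConfig | None = None) -> pd.Series:
    """Vectorized :func:`is_eligible` over a cohort table."""
    config = config or NoggConfig()
    any_factor = cohort[list(RISK_FACTOR_COLUMNS)].astype(bool).any(axis=1)
    has_t = cohort["fn_bmd_tscore"].notna()
    return (cohort["age"] >= config.min_age) & any_factor & has_t


def _auto_treat(individual, config: NoggConfig) -> bool:
    return bool(
        config.auto_treat_women_prior_fracture
        and individual["sex"] == "female"
        and individual["age"] >= 50.0
        and individual["prior_fracture"]
    )


def _lower_threshold(age: float, params: FraxSurrogateParams, config: NoggConfig):
    if config.lower_assessment_rule == "reference-woman-no-crf":
        return lower_assessment_threshold(age, params)
    return config.lower_assessment_multiplier * intervention_threshold(age, params)


def nogg_screen(
    individual,
    frax_params: FraxSurrogateParams | None = None,
    config: NoggConfig | None = None,
) -> ScreeningTrace:
    """Run one individual through the base staged screening algorithm."""
    frax_params = frax_params or FraxSurrogateParams()
    config = config or NoggConfig()
    if not is_eligible(individual, config):
        raise ValueError("nogg_screen requires a screening-eligible individual")

    trace = ScreeningTrace(id=str(individual["id"]), eligible=True)
    if _auto_treat(individual, config):
        trace.auto_treated = True
        trace.recommendation = "treat"
        return trace

    age = float(individual["age"])
    it = intervention_threshold(age, frax_params)
    upper = config.upper_assessment_multiplier * it
    lower = _lower_threshold(age, frax_params, config)

    trace.crf_frax_done = True
    trace.crf_frax_value = crf_frax(individual, frax_params)
    if trace.crf_frax_value >= upper:
        trace.risk_band = "high"
        trace.recommendation = "treat"
    elif trace.crf_frax_value < lower:
        trace.risk_band = "low"
        trace.recommendation = "reassure"
    else:
        trace.risk_band = "intermediate"
        trace.bmd_frax_done = True
        trace.bmd_frax_value = bmd_frax(individual, frax_params)
        trace.recommendation = "treat" if trace.bmd_frax_value >= it else "reassure"
    return trace


def gsos_nogg_screen(
    individual,
    gsos: float | None = None,
    frax_params: FraxSurrogateParams | None = None,
    config: NoggConfig | None = None,
) -> ScreeningTrace:
    """Run one individual through the polygenic-gated screening algorithm.

    Auto-treatment of women with a prior fragility fracture precedes the
    gate; gating them out would contradict their reference-standard
    assignment.  With ``gate_placement="after_crf"`` the gate applies only
    to individuals not already resolved by CRF-FRAX.
    """
    frax_params = frax_params or FraxSurrogateParams()
    config = config or NoggConfig()
    if gsos is None:
        gsos = individual["gsos"] if "gsos" in individual else None
    if gsos is None or pd.isna(gsos):
        raise KeyError("gsos is required for the gated strategy")
    if not is_eligible(individual, config):
        raise ValueError("gsos_nogg_screen requires a screening-eligible individual")

    threshold = config.gsos_thresholds[str(individual["sex"])]

    trace = ScreeningTrace(id=str(individual["id"]), eligible=True)
    if _auto_treat(individual, config):
        trace.auto_treated = True
        trace.recommendation = "treat"
        return trace

    if config.gate_placement == "before_crf" and gsos > threshold:
        trace.excluded_by_gsos = True
        trace.recommendation = "reassure"
        return trace

    age = float(individual["age"])
    it = intervention_threshold(age, frax_params)
    upper = config.upper_assessment_multiplier * it
    lower = _lower_threshold(age, frax_params, config)

    trace.crf_frax_done = True
    trace.crf_frax_value = crf_frax(individual, frax_params)
    if trace.crf_frax_value >= upper:
        trace.risk_band = "high"
        trace.recommendation = "treat"
    elif trace.crf_frax_value < lower:
        trace.risk_band = "low"
        trace.recommendation = "reassure"
    else:
        trace.risk_band = "intermediate"
        if config.gate_placement == "after_crf" and gsos > threshold:
            trace.excluded_by_gsos = True
            trace.recommendation = "reassure"
            return trace
        trace.bmd_frax_done = True
        trace.bmd_frax_value = bmd_frax(individual, frax_params)
        trace.recommendation = "treat" if trace.bmd_frax_value >= it else "reassure"
    return trace


def reference_standard(
    individual,
    frax_params: FraxSurrogateParams | None = None,
    config: NoggConfig | None = None,
) -> str:
    """BMD-FRAX reference assignment: treat iff BMD-FRAX >= IT(age), or the
    individual is a woman >= 50 with a prior fragility fracture."""
    frax_params = frax_params or FraxSurrogateParams()
    config = config or NoggConfig()
    if "fn_bmd_tscore" not in individual or pd.isna(individual["fn_bmd_tscore"]):
        raise KeyError("reference standard requires fn_bmd_tscore")
    if _auto_treat(individual, config):
        return "treat"
    it = intervention_threshold(float(individual["age"]), frax_params)
    return "treat" if bmd_frax(individual, frax_params) >= it else "reassure"


# ---------------------------------------------------------------------------
# vectorized cohort path


def screen_cohort(
    cohort: pd.DataFrame,
    frax_params: FraxSurrogateParams | None = None,
    config: NoggConfig | None = None,
    strategy: str = "nogg",
) -> pd.DataFrame:
    """Screen a whole cohort; returns one trace row per individual.

    Ineligible individuals get recommendation ``not_screened`` and are kept
    in the output so that callers can account for them explicitly.
    """
    if strategy not in ("nogg", "gsos-nogg"):
        raise ValueError(f"unknown strategy {strategy!r}")
    frax_params = frax_params or FraxSurrogateParams()
    config = config or NoggConfig()
    n = len(cohort)
    gated = strategy == "gsos-nogg"

    eligible = eligible_mask(cohort, config).to_numpy()
    sex = cohort["sex"].to_numpy()
    age = cohort["age"].to_numpy(dtype=float)

    if gated:
        if "gsos" not in cohort.columns or cohort.loc[eligible, "gsos"].isna().any():
            raise KeyError("gsos is required (and must be non-missing) for the gated strategy")
        gsos = cohort["gsos"].to_numpy(dtype=float)
        thr = np.where(sex == "female",
                       config.gsos_thresholds["female"],
                       config.gsos_thresholds["male"])

    auto = (
        eligible
        & config.auto_treat_women_prior_fracture
        & (sex == "female")
        & (age >= 50.0)
        & cohort["prior_fracture"].to_numpy(dtype=bool)
    )

    excluded = np.zeros(n, dtype=bool)
    needs_crf = eligible & ~auto
    if gated and config.gate_placement == "before_crf":
        excluded = needs_crf & (gsos > thr)
        needs_crf = needs_crf & ~excluded

    it = intervention_threshold(age, frax_params)
    upper = config.upper_assessment_multiplier * it
    if config.lower_assessment_rule == "reference-woman-no-crf":
        lower = lower_assessment_threshold(age, frax_params)
    else:
        lower = config.lower_assessment_multiplier * it

    crf = np.asarray(crf_frax(cohort, frax_params))
    high = needs_crf & (crf >= upper)
    low = needs_crf & (crf < lower)
    intermediate = needs_crf & ~high & ~low

    needs_bmd = intermediate.copy()
    if gated and config.gate_placement == "after_crf":
        gate_hit = intermediate & (gsos > thr)
        excluded = excluded | gate_hit
        needs_bmd = intermediate & ~gate_hit

    # BMD-FRAX needs a T-score; eligibility guarantees one for everybody
    # reaching this stage, so evaluate on the needed rows only.
    bmd = np.full(n, np.nan)
    if needs_bmd.any():
        bmd[needs_bmd] = np.asarray(bmd_frax(cohort.loc[needs_bmd], frax_params))
    bmd_treat = needs_bmd & (bmd >= it)

    recommendation = np.full(n, "not_screened", dtype=object)
    recommendation[eligible] = "reassure"
    recommendation[auto | high | bmd_treat] = "treat"

    risk_band = np.full(n, "", dtype=object)
    risk_band[high] = "high"
    risk_band[low] = "low"
    risk_band[intermediate] = "intermediate"

    crf_value = np.where(needs_crf, crf, np.nan)
    return pd.DataFrame(
        {
            "id": cohort["id"].astype(str).to_numpy(),
            "eligible": eligible,
            "excluded_by_gsos": excluded,
            "auto_treated": auto,
            "crf_frax_done": needs_crf,
            "crf_frax_value": crf_value,
            "risk_band": risk_band,
            "bmd_frax_done": needs_bmd,
            "bmd_frax_value": bmd,
            "recommendation": recommendation,
        },
        columns=TRACE_COLUMNS,
    )


def reference_standard_cohort(
    cohort: pd.DataFrame,
    frax_params: FraxSurrogateParams | None = None,
    config: NoggConfig | None = None,
) -> pd.Series:
    """Vectorized reference standard; indexed by individual id.

    Only screening-eligible rows are assigned (the reference is undefined
    without a T-score and outside the screened population).
    """
    frax_params = frax_params or FraxSurrogateParams()
    config = config or NoggConfig()
    eligible = eligible_mask(cohort, config)
    sub = cohort.loc[eligible]
    it = intervention_threshold(sub["age"].to_numpy(dtype=float), frax_params)
    bmd = np.asarray(bmd_frax(sub, frax_params))
    auto = (
        config.auto_treat_women_prior_fracture
        & (sub["sex"].to_numpy() == "female")
        & (sub["age"].to_numpy(dtype=float) >= 50.0)
        & sub["prior_fracture"].to_numpy(dtype=bool)
    )
    treat = auto | (bmd >= it)
    return pd.Series(
        np.where(treat, "treat", "reassure"),
        index=pd.Index(sub["id"].astype(str), name="id"),
        name="reference",
    )
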