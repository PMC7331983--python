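"""Parametric surrogate for the FRAX 10-year fracture-probability calculator.

FRAX itself is proprietary and country-specific; screening research consumes
only its outputs.  This module provides a transparent, monotone stand-in: a
Gompertz-like hazard on the log scale, with multiplicative relative risks for
the clinical risk factors, mapped to a 10-year probability of major
osteoporotic fracture (MOF) via the complementary log-log link

    P = 100 * (1 - exp(-H)),
    H = s_sex * exp(b_age*(age-50) + sum_f log_rr_f * x_f
        + log_rr_bmi*(BMI-25) [+ log_rr_bmd*(t_center - T)]),

where the bracketed BMD term is present only in the BMD-based score.  At
``T = t_center`` the BMD-based and risk-factor-based probabilities coincide
by construction.  Every screening computation downstream is agnostic to how
the probabilities were produced, so externally computed true FRAX outputs
can replace the surrogate by supplying ``crf_frax``/``bmd_frax`` columns.

Default coefficients were chosen once for plausibility against published
cohort tables (mean CRF-FRAX near 5% in a mixed-sex cohort around age 57,
near 19% in women around age 71) and are all overridable in one config
block.  Competing mortality is not modeled explicitly; the age slope
absorbs it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import RISK_FACTOR_COLUMNS

__all__ = [
    "FraxSurrogateParams",
    "crf_frax",
    "bmd_frax",
    "intervention_threshold",
    "lower_assessment_threshold",
    "append_frax_columns",
]

logger = logging.getLogger(__name__)


@dataclass
class FraxSurrogateParams:
    """Coefficients of the surrogate 10-year MOF probability model."""

    baseline_scale_by_sex: dict[str, float] = field(
        default_factory=lambda: {"female": 0.036, "male": 0.024}
    )
    #: per-year log-hazard slope beyond age 50
    baseline_age_slope: float = 0.069
    log_rr: dict[str, float] = field(
        default_factory=lambda: {
            "prior_fracture": math.log(1.8),
            "smoking": math.log(1.25),
            "glucocorticoids": math.log(1.6),
            "rheumatoid_arthritis": math.log(1.3),
            "secondary_osteoporosis": math.log(1.3),
            "parental_hip_fracture": math.log(1.5),
            "alcohol": math.log(1.2),
        }
    )
    #: per-unit BMI effect on the log hazard (protective above BMI 25)
    log_rr_bmi: float = -0.015
    #: per-T-score-unit effect; risk increases as T decreases
    log_rr_bmd_per_t: float = math.log(1.6)
    #: T-score at which the BMD-based score equals the risk-factor-based
    #: one.  Set near the mean femoral-neck T-score of a screening-eligible
    #: (>= 50 y) population so the two scores agree on average, as cohort
    #: tables consistently show for the real calculator.
    t_center: float = -1.0
    age_domain: tuple[float, float] = (50.0, 90.0)
    #: treat absent risk-factor fields as "no", per FRAX guidance
    missing_as_no: bool = False

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.baseline_scale_by_sex.values()):
            raise ValueError("baseline scales must be positive")
        if any(lr < 0 for lr in self.log_rr.values()):
            raise ValueError("risk-factor relative risks must be >= 1")
        if self.log_rr_bmd_per_t <= 0:
            raise ValueError("log_rr_bmd_per_t must be positive")


def _clamped_age(age: np.ndarray, params: FraxSurrogateParams) -> np.ndarray:
    lo, hi = params.age_domain
    age = np.asarray(age, dtype=float)
    if np.any(age < lo) or np.any(age > hi):
        logger.warning(
            "age outside the surrogate domain [%g, %g]; clamping", lo, hi
        )
    return np.clip(age, lo, hi)


def _risk_factor_value(data, factor: str, params: FraxSurrogateParams) -> np.ndarray:
    if factor in data:
        vals = np.asarray(data[factor])
        if vals.dtype == object or np.issubdtype(vals.dtype, np.floating):
            mask = pd.isna(vals)
            if mask.any():
                if not params.missing_as_no:
                    raise KeyError(
                        f"risk factor '{factor}' has missing values and "
                        "missing_as_no is disabled"
                    )
                vals = np.where(mask, False, vals)
        return vals.astype(float)
    if params.missing_as_no:
        return np.float64(0.0)
    raise KeyError(f"required risk-factor field '{factor}' is missing")


def _hazard(data, params: FraxSurrogateParams) -> np.ndarray:
    for required in ("age", "sex", "bmi"):
        if required not in data:
            raise KeyError(f"required field '{required}' is missing")
    age = _clamped_age(data["age"], params)
    sex = np.asarray(data["sex"])
    unknown = set(np.unique(sex)) - set(params.baseline_scale_by_sex)
    if unknown:
        raise ValueError(f"unknown sex values: {sorted(unknown)}")
    scale = np.vectorize(params.baseline_scale_by_sex.get)(sex).astype(float)
    log_h = params.baseline_age_slope * (age - 50.0)
    log_h = log_h + params.log_rr_bmi * (np.asarray(data["bmi"], float) - 25.0)
    for factor in RISK_FACTOR_COLUMNS:
        lrr = params.log_rr.get(factor, 0.0)
        if lrr:
            log_h = log_h + lrr * _risk_factor_value(data, factor, params)
    return scale * np.exp(log_h)


def _as_mapping(individual):
    """Accept a DataFrame, Series (single row), or mapping uniformly."""
    if isinstance(individual, pd.DataFrame):
        return individual
    if isinstance(individual, pd.Series):
        return individual.to_dict()
    return individual


def crf_frax(individual, params: FraxSurrogateParams | None = None) -> np.ndarray | float:
    """10-year MOF probability (%) from clinical risk factors alone.

    Accepts a single individual (Series/dict) or a whole cohort DataFrame;
    returns a scalar or a vector of percentages in (0, 100) accordingly.
    """
    params = params or FraxSurrogateParams()
    data = _as_mapping(individual)
    h = _hazard(data, params)
    p = 100.0 * (1.0 - np.exp(-h))
    return float(p) if np.ndim(p) == 0 else np.asarray(p)


def bmd_frax(individual, params: FraxSurrogateParams | None = None) -> np.ndarray | float:
    """10-year MOF probability (%) incorporating the femoral-neck T-score."""
    params = params or FraxSurrogateParams()
    data = _as_mapping(individual)
    if "fn_bmd_tscore" not in data:
        raise KeyError("required field 'fn_bmd_tscore' is missing")
    t = np.asarray(data["fn_bmd_tscore"], dtype=float)
    if np.any(pd.isna(t)):
        raise ValueError("fn_bmd_tscore contains missing values")
    h = _hazard(data, params) * np.exp(params.log_rr_bmd_per_t * (params.t_center - t))
    p = 100.0 * (1.0 - np.exp(-h))
    return float(p) if np.ndim(p) == 0 else np.asarray(p)


def _reference_woman(age, prior_fracture: bool) -> dict:
    return {
        "age": np.asarray(age, dtype=float),
        "sex": "female",
        "bmi": 25.0,
        **{f: False for f in RISK_FACTOR_COLUMNS},
        "prior_fracture": prior_fracture,
    }


def intervention_threshold(age, params: FraxSurrogateParams | None = None):
    """Age-specific intervention threshold (%): the CRF-based 10-year MOF
    probability of a woman of that age whose only risk factor is a prior
    fragility fracture (BMI 25)."""
    params = params or FraxSurrogateParams()
    return crf_frax(_reference_woman(age, prior_fracture=True), params)


def lower_assessment_threshold(age, params: FraxSurrogateParams | None = None):
    """Lower assessment threshold (%): CRF-FRAX of a same-age reference woman
    with no risk factors; below it individuals are reassured without BMD."""
    params = params or FraxSurrogateParams()
    return crf_frax(_reference_woman(age, prior_fracture=False), params)


def append_frax_columns(
    cohort: pd.DataFrame, params: FraxSurrogateParams | None = None
) -> pd.DataFrame:
    """Return a copy of the cohort with ``crf_frax``, ``bmd_frax`` and ``it``
    (intervention threshold) columns.

    Columns already present are kept verbatim, so probabilities computed by
    an external calculator can be supplied instead of the surrogate;
    ``bmd_frax`` is left missing where the T-score is absent.
    """
    params = params or FraxSurrogateParams()
    out = cohort.copy()
    if "crf_frax" not in out.columns:
        out["crf_frax"] = crf_frax(out, params)
    if "bmd_frax" not in out.columns:
        has_t = out["fn_bmd_tscore"].notna()
        vals = np.full(len(out), np.nan)
        if has_t.any():
            vals[has_t.to_numpy()] = np.asarray(bmd_frax(out.loc[has_t], params))
        out["bmd_frax"] = vals
    if "it" not in out.columns:
        out["it"] = intervention_threshold(out["age"].to_numpy(dtype=float), params)
    return out
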