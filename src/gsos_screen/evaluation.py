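"""Performance accounting for screening strategies.

Scores a strategy's treat/reassure calls against the BMD-FRAX reference
standard (sensitivity, specificity, predictive values), tracks the test
burden (fractions of the eligible population receiving CRF-FRAX and
BMD-FRAX tests, and the fractions of those tests that end in reassurance),
compares strategies via relative reductions, and selects sex-specific
polygenic-score thresholds under an explicit sensitivity constraint.

Undefined ratios (empty denominators) are reported as ``None`` with the
report flagged, never coerced to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .frax import FraxSurrogateParams
from .screening import NoggConfig, screen_cohort, reference_standard_cohort

__all__ = [
    "PerformanceReport",
    "StrategyComparison",
    "performance_report",
    "compare_strategies",
    "select_gsos_thresholds",
    "stratified_reports",
]


@dataclass
class PerformanceReport:
    """Confusion counts, accuracy metrics (%) and test-burden metrics (%)."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_eligible: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    pct_crf_tested: float
    pct_bmd_tested: float
    pct_crf_reassured: float | None
    pct_bmd_reassured: float | None
    undefined_metrics: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def round(self, ndigits: int = 1) -> dict:
        """Report-style view with percentages rounded to *ndigits* places."""
        out = self.to_dict()
        for k, v in out.items():
            if isinstance(v, float):
                out[k] = round(v, ndigits)
        return out


def _pct(numer: int, denom: int) -> float | None:
    return 100.0 * numer / denom if denom else None


def performance_report(
    traces: pd.DataFrame,
    references: pd.Series | dict,
    config: dict | None = None,
) -> PerformanceReport:
    """Score screening traces against the reference standard.

    ``references`` maps individual id to ``"treat"``/``"reassure"``.  Only
    eligible traces enter any denominator; each must have a reference.
    Individuals excluded by the polygenic gate count as predicted reassure
    (their recommendation is already ``reassure``).
    """
    refs = pd.Series(references)
    elig = traces[traces["eligible"].astype(bool)]
    ids = elig["id"].astype(str)
    missing = set(ids) - set(refs.index.astype(str))
    if missing:
        raise ValueError(
            f"{len(missing)} eligible trace(s) lack a reference standard, "
            f"e.g. {sorted(missing)[:3]}"
        )
    ref = refs.loc[ids].to_numpy()
    pred = elig["recommendation"].to_numpy()
    if not np.isin(pred, ("treat", "reassure")).all():
        raise ValueError("eligible traces must resolve to treat or reassure")

    actual_pos = ref == "treat"
    pred_pos = pred == "treat"
    tp = int(np.sum(actual_pos & pred_pos))
    fp = int(np.sum(~actual_pos & pred_pos))
    fn = int(np.sum(actual_pos & ~pred_pos))
    tn = int(np.sum(~actual_pos & ~pred_pos))
    n_eligible = len(elig)

    crf_done = elig["crf_frax_done"].to_numpy(dtype=bool)
    bmd_done = elig["bmd_frax_done"].to_numpy(dtype=bool)
    reassured = pred == "reassure"

    metrics = {
        "sensitivity": _pct(tp, tp + fn),
        "specificity": _pct(tn, tn + fp),
        "ppv": _pct(tp, tp + fp),
        "npv": _pct(tn, tn + fn),
        "pct_crf_reassured": _pct(int(np.sum(crf_done & reassured)), int(crf_done.sum())),
        "pct_bmd_reassured": _pct(int(np.sum(bmd_done & reassured)), int(bmd_done.sum())),
    }
    undefined = sorted(k for k, v in metrics.items() if v is None)

    return PerformanceReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        n_eligible=n_eligible,
        pct_crf_tested=100.0 * crf_done.sum() / n_eligible if n_eligible else 0.0,
        pct_bmd_tested=100.0 * bmd_done.sum() / n_eligible if n_eligible else 0.0,
        undefined_metrics=undefined,
        config=dict(config or {}),
        **metrics,
    )


@dataclass
class StrategyComparison:
    """Relative test-burden reductions (%) and accuracy deltas between a
    base strategy and a variant on the same cohort."""

    rel_reduction_crf: float | None
    rel_reduction_bmd: float | None
    delta_sensitivity: float | None
    delta_specificity: float | None
    undefined: list[str] = field(default_factory=list)

    def rounded(self) -> dict:
        """Reporting convention: reductions to 0 dp, deltas to 1 dp."""
        out = asdict(self)
        for k in ("rel_reduction_crf", "rel_reduction_bmd"):
            if out[k] is not None:
                out[k] = round(out[k])
        for k in ("delta_sensitivity", "delta_specificity"):
            if out[k] is not None:
                out[k] = round(out[k], 1)
        return out


def compare_strategies(
    base: PerformanceReport, variant: PerformanceReport
) -> StrategyComparison:
    """Relative reduction in test burden, 100*(1 - variant/base), per test
    type, plus absolute accuracy differences (variant - base)."""
    if base.n_eligible != variant.n_eligible:
        raise ValueError("strategies must be compared on the same cohort")

    undefined = []

    def rel(base_pct: float, var_pct: float, name: str) -> float | None:
        if base_pct == 0:
            undefined.append(name)
            return None
        return 100.0 * (1.0 - var_pct / base_pct)

    def delta(b: float | None, v: float | None, name: str) -> float | None:
        if b is None or v is None:
            undefined.append(name)
            return None
        return v - b

    return StrategyComparison(
        rel_reduction_crf=rel(base.pct_crf_tested, variant.pct_crf_tested, "rel_reduction_crf"),
        rel_reduction_bmd=rel(base.pct_bmd_tested, variant.pct_bmd_tested, "rel_reduction_bmd"),
        delta_sensitivity=delta(base.sensitivity, variant.sensitivity, "delta_sensitivity"),
        delta_specificity=delta(base.specificity, variant.specificity, "delta_specificity"),
        undefined=undefined,
    )


def select_gsos_thresholds(
    cohort: pd.DataFrame,
    frax_params: FraxSurrogateParams | None = None,
    config: NoggConfig | None = None,
    grid: list[float] | np.ndarray | None = None,
    min_sensitivity: float = 90.0,
    per_sex: bool = True,
) -> dict[str, float]:
    """Choose the score threshold(s) trading test burden against missed
    treatments.

    For each sex independently (or pooled if ``per_sex`` is false), every
    grid threshold is evaluated by running the gated strategy on that sex's
    eligible members; among thresholds whose sensitivity against the
    reference standard is >= ``min_sensitivity`` (%), the one minimizing the
    number of BMD-FRAX tests that end in reassurance is returned.  Ties go
    to the larger threshold (less exclusion); if no threshold qualifies the
    gate is disabled (+inf).  The grid must contain +inf so the unconstrained
    strategy is always a candidate.
    """
    frax_params = frax_params or FraxSurrogateParams()
    config = config or NoggConfig()
    if grid is None:
        grid = np.concatenate([np.arange(-2.0, 2.0001, 0.1), [np.inf]])
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be nonempty")
    if not np.isinf(grid).any():
        raise ValueError("threshold grid must include +inf (gate disabled)")
    if not 0.0 < min_sensitivity <= 100.0:
        raise ValueError("min_sensitivity must be in (0, 100]")

    references = reference_standard_cohort(cohort, frax_params, config)
    groups = (
        [("female", cohort[cohort["sex"] == "female"]), ("male", cohort[cohort["sex"] == "male"])]
        if per_sex
        else [("all", cohort)]
    )

    chosen: dict[str, float] = {}
    for label, sub in groups:
        best_thr = math.inf
        best_cost = None
        for thr in sorted(grid):
            cfg = NoggConfig(**{**asdict(config), "gsos_thresholds": {"female": thr, "male": thr}})
            traces = screen_cohort(sub, frax_params, cfg, strategy="gsos-nogg")
            report = performance_report(traces, references)
            cost = int(
                (
                    traces["bmd_frax_done"].to_numpy(dtype=bool)
                    & (traces["recommendation"].to_numpy() == "reassure")
                ).sum()
            )
            sens = report.sensitivity
            if sens is not None and sens < min_sensitivity:
                continue
            # ties go to the larger threshold: iterate ascending, accept >=
            if best_cost is None or cost <= best_cost:
                best_cost = cost
                best_thr = float(thr)
        chosen[label] = best_thr
    if not per_sex:
        return {"female": chosen["all"], "male": chosen["all"]}
    return chosen


def stratified_reports(
    cohort: pd.DataFrame,
    traces_base: pd.DataFrame,
    traces_variant: pd.DataFrame,
    references: pd.Series,
    strata: str = "sex",
) -> dict[str, tuple[PerformanceReport, PerformanceReport, StrategyComparison]]:
    """Per-stratum base/variant reports and comparison.

    ``strata`` is ``"sex"`` or ``"age_band"`` (50-59 / 60-69 / 70+); all
    denominators use only the stratum's members.
    """
    if strata == "sex":
        labels = cohort["sex"].astype(str)
    elif strata == "age_band":
        age = cohort["age"].to_numpy(dtype=float)
        labels = pd.Series(
            np.select([age < 60, age < 70], ["50-59", "60-69"], default="70+"),
            index=cohort.index,
        )
    else:
        raise ValueError(f"unknown stratification {strata!r}")

    base_by_id = traces_base.set_index(traces_base["id"].astype(str))
    var_by_id = traces_variant.set_index(traces_variant["id"].astype(str))

    out = {}
    for label in sorted(labels.unique()):
        ids = cohort.loc[labels == label, "id"].astype(str)
        tb = base_by_id.loc[base_by_id.index.intersection(ids)].reset_index(drop=True)
        tv = var_by_id.loc[var_by_id.index.intersection(ids)].reset_index(drop=True)
        rb = performance_report(tb, references)
        rv = performance_report(tv, references)
        out[str(label)] = (rb, rv, compare_strategies(rb, rv))
    return out
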