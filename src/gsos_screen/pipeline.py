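"""End-to-end orchestration: simulate -> split -> GWAS -> train -> score ->
FRAX -> screen (base and gated) -> evaluate -> compare.

Every artifact is stamped with the config hash and global seed, per-stage
seeds are derived deterministically from the global seed, and a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, frax, prs, screening, synthetic
from .io import RunConfig, write_cohort, write_genotypes_raw, write_prs_model

__all__ = ["run_pipeline", "PipelineError", "stage_seeds"]

logger = logging.getLogger(__name__)

_STAGES = ("genotypes", "phenotypes", "risk_factors", "split", "pcs", "train", "bootstrap")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive one child seed per stage from the global seed, so any stage
    can be rerun in isolation with the same randomness."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def _config_hash(config: RunConfig) -> str:
    """Hash of the scientific configuration (the output location is not
    part of what the artifacts depend on)."""
    payload = config.to_dict()
    payload.pop("out_dir", None)
    import yaml

    return hashlib.sha256(yaml.safe_dump(payload, sort_keys=True).encode()).hexdigest()[:16]


def _dump_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if o in (float("inf"), float("-inf")):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(_sanitize(obj), indent=2, sort_keys=True, default=default) + "\n")


def _sanitize(obj):
    """Make infinities JSON-safe (they appear in gate-off thresholds)."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis described by *config*; artifacts land in
    ``out_dir`` (default ``config.out_dir``).  Returns the run summary."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    chash = _config_hash(config)
    stamp = f"config_hash={chash} seed={config.seed}"
    cc = config.cohort
    frax_params = frax.FraxSurrogateParams(**config.frax_surrogate)
    nogg = screening.NoggConfig(**config.screening)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        panel = synthetic.simulate_genotypes(
            cc.n_individuals,
            cc.n_snps,
            maf_range=tuple(cc.maf_range),
            block_size=cc.block_size,
            block_rho=cc.block_rho,
            seed=seeds["genotypes"],
        )
        rf = synthetic.simulate_risk_factors(
            cc.n_individuals,
            age_range=tuple(cc.age_range),
            female_fraction=cc.female_fraction,
            prevalence_table=cc.prevalences,
            seed=seeds["risk_factors"],
        )
        sos, tsc, truth = synthetic.simulate_phenotypes(
            panel,
            n_causal=cc.n_causal,
            h2_sos=cc.h2_sos,
            sos_bmd_corr=cc.sos_bmd_corr,
            age_bmd_slope=cc.age_bmd_slope,
            seed=seeds["phenotypes"],
            age=rf["age"].to_numpy(),
            sex=rf["sex"].to_numpy(),
        )
        cohort = synthetic.assemble_cohort(rf, sos, tsc)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e) from e

    try:
        stage("split")
        split = prs.split_cohort(cc.n_individuals, tuple(config.prs.fractions), seed=seeds["split"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError("split", e) from e

    try:
        stage("train-prs")
        pcs = prs.genotype_pcs(panel, n_pcs=config.prs.n_pcs, seed=seeds["pcs"])
        covars = np.column_stack(
            [cohort["age"].to_numpy(), (cohort["sex"] == "female").to_numpy(dtype=float), pcs]
        )
        model, gwas_table, grid = prs.train_gsos(
            panel,
            cohort["sos_std"].to_numpy(),
            covars,
            split.training_idx,
            split.selection_idx,
            p_thresholds=tuple(config.prs.p_thresholds),
            n_lambda=config.prs.n_lambda,
            lambda_min_ratio=config.prs.lambda_min_ratio,
            tol=config.prs.tol,
            max_sweeps=config.prs.max_sweeps,
            seed=seeds["train"],
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("train-prs", e) from e

    try:
        stage("score")
        gsos_all = prs.score_and_standardize(model, panel, reference_idx=split.test_idx)
        cohort["gsos"] = gsos_all
    except Exception as e:  # noqa: BLE001
        raise PipelineError("score", e) from e

    try:
        stage("frax")
        cohort = frax.append_frax_columns(cohort, frax_params)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("frax", e) from e

    try:
        stage("evaluate-prs")
        test = cohort.iloc[split.test_idx]
        r2_gsos, ci_gsos = prs.variance_explained(
            test["gsos"].to_numpy(), test["sos_std"].to_numpy(), seed=seeds["bootstrap"]
        )
        true_score = truth.genetic_score(panel)[split.test_idx]
        r2_truth, _ = prs.variance_explained(
            true_score, test["sos_std"].to_numpy(), n_boot=10, seed=seeds["bootstrap"]
        )
        r2_base, r2_crf = prs.incremental_r2(
            test,
            "sos_std",
            ["age", "sex", "bmi"],
            ["prior_fracture", "smoking", "glucocorticoids", "rheumatoid_arthritis",
             "secondary_osteoporosis"],
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("evaluate-prs", e) from e

    try:
        stage("screen")
        traces_base = screening.screen_cohort(test, frax_params, nogg, strategy="nogg")
        traces_gated = screening.screen_cohort(test, frax_params, nogg, strategy="gsos-nogg")
        references = screening.reference_standard_cohort(test, frax_params, nogg)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("screen", e) from e

    try:
        stage("evaluate")
        cfg_snapshot = {
            "screening": dataclasses.asdict(nogg),
            "frax_surrogate": dataclasses.asdict(frax_params),
        }
        report_base = evaluation.performance_report(traces_base, references, config=cfg_snapshot)
        report_gated = evaluation.performance_report(traces_gated, references, config=cfg_snapshot)
        comparison = evaluation.compare_strategies(report_base, report_gated)
        thresholds = None
        if config.evaluation.select_thresholds:
            thresholds = evaluation.select_gsos_thresholds(
                test,
                frax_params,
                nogg,
                grid=config.evaluation.threshold_grid,
                min_sensitivity=config.evaluation.min_sensitivity,
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("evaluate", e) from e

    try:
        stage("write")
        config.to_yaml(out / "config_resolved.yaml")
        write_cohort(cohort, out / "cohort.tsv", header_comment=stamp)
        if config.write_genotypes:
            write_genotypes_raw(panel, out / "genotypes.raw", sample_ids=cohort["id"].tolist())
        with open(out / "gwas.tsv", "w") as fh:
            fh.write(f"# {stamp}\n")
            gwas_table.to_csv(fh, sep="\t", index=False)
        write_prs_model(model, out / "prs_model.tsv")
        grid.to_csv(out / "prs_grid.tsv", sep="\t", index=False)
        for name, traces in (("nogg", traces_base), ("gsos_nogg", traces_gated)):
            with open(out / f"traces_{name}.tsv", "w") as fh:
                fh.write(f"# {stamp}\n")
                traces.to_csv(fh, sep="\t", index=False)
        _dump_json(report_base.to_dict(), out / "report_nogg.json")
        _dump_json(report_gated.to_dict(), out / "report_gsos_nogg.json")

        summary = {
            "config_hash": chash,
            "seed": config.seed,
            "stage_seeds": seeds,
            "n_individuals": cc.n_individuals,
            "n_snps": cc.n_snps,
            "split_sizes": {
                "training": len(split.training_idx),
                "selection": len(split.selection_idx),
                "test": len(split.test_idx),
            },
            "prs": {
                "p_threshold": model.p_threshold,
                "lambda": model.lam,
                "n_activated_snps": model.n_snps,
                "selection_rmse": model.selection_rmse,
                "test_r2_gsos": r2_gsos,
                "test_r2_gsos_ci95": list(ci_gsos),
                "test_r2_true_score": r2_truth,
                "test_r2_age_sex_bmi": r2_base,
                "test_r2_plus_crfs": r2_crf,
            },
            "screening": {
                "n_eligible": report_base.n_eligible,
                "base": report_base.round(),
                "gated": report_gated.round(),
                "comparison": comparison.rounded(),
                "selected_thresholds": thresholds,
            },
        }
        _dump_json(summary, out / "summary.json")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("write", e) from e

    return summary
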