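"""File formats and run configuration.

Tables are TSV throughout (booleans as 0/1, missing values as empty
fields), genotypes are read from the PLINK ``.raw`` dosage dialect or from
VCF (GT mapped to an alternate-allele count), PRS weights are exchanged as
PGS-Catalog-style scoring files with a YAML sidecar for standardization
constants, and runs are driven by a single YAML config with one global
seed.  Lines starting with ``#`` are treated as comments in all TSV
formats, which is where artifacts carry their config-hash/seed stamp.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import RISK_FACTOR_COLUMNS, GenotypePanel
from .prs import PrsModel

__all__ = [
    "CohortDataError",
    "read_cohort",
    "write_cohort",
    "read_genotypes",
    "write_genotypes_raw",
    "write_prs_model",
    "read_prs_model",
    "RunConfig",
    "COHORT_COLUMNS",
]


class CohortDataError(ValueError):
    """Malformed cohort or genotype file; message carries the row/line."""


#: canonical cohort column order; later columns may be absent per row
COHORT_COLUMNS = (
    ["id", "age", "sex", "bmi"]
    + list(RISK_FACTOR_COLUMNS)
    + ["fn_bmd_tscore", "sos_std", "gsos"]
)
#: appended-result columns tolerated on input and used verbatim if present
OPTIONAL_COLUMNS = ("crf_frax", "bmd_frax", "it")

_BOOL_MAP = {"0": False, "1": True, "true": True, "false": False}


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort TSV with strict typing.

    Unknown columns, malformed booleans, non-numeric ages and invalid sex
    values raise :class:`CohortDataError` naming the offending row (1-based,
    excluding the header).  Empty numeric fields become missing values.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    unknown = set(raw.columns) - set(COHORT_COLUMNS) - set(OPTIONAL_COLUMNS)
    if unknown:
        raise CohortDataError(f"unknown column(s) in cohort file: {sorted(unknown)}")
    missing = {"id", "age", "sex"} - set(raw.columns)
    if missing:
        raise CohortDataError(f"cohort file lacks required column(s): {sorted(missing)}")

    out = pd.DataFrame({"id": raw["id"].astype(str)})

    def numeric(col: str, required: bool) -> pd.Series:
        vals = []
        for i, s in enumerate(raw[col], start=1):
            s = s.strip()
            if s == "":
                if required:
                    raise CohortDataError(f"row {i}: empty value in required column '{col}'")
                vals.append(np.nan)
                continue
            try:
                vals.append(float(s))
            except ValueError:
                raise CohortDataError(f"row {i}: non-numeric {col} value {s!r}") from None
        return pd.Series(vals, dtype=float)

    out["age"] = numeric("age", required=True)
    bad_sex = [i for i, s in enumerate(raw["sex"], start=1) if s not in ("female", "male")]
    if bad_sex:
        raise CohortDataError(
            f"row {bad_sex[0]}: sex must be 'female' or 'male', got {raw['sex'].iloc[bad_sex[0] - 1]!r}"
        )
    out["sex"] = raw["sex"]
    out["bmi"] = numeric("bmi", required=True) if "bmi" in raw.columns else np.nan

    for col in RISK_FACTOR_COLUMNS:
        if col not in raw.columns:
            out[col] = pd.array([pd.NA] * len(raw), dtype="boolean")
            continue
        vals = []
        for i, s in enumerate(raw[col], start=1):
            s = s.strip().lower()
            if s == "":
                vals.append(pd.NA)
            elif s in _BOOL_MAP:
                vals.append(_BOOL_MAP[s])
            else:
                raise CohortDataError(f"row {i}: malformed boolean {s!r} in column '{col}'")
        out[col] = pd.array(vals, dtype="boolean")

    for col in ("fn_bmd_tscore", "sos_std", "gsos") + OPTIONAL_COLUMNS:
        out[col] = numeric(col, required=False) if col in raw.columns else np.nan
    return out


def write_cohort(cohort: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a cohort TSV (booleans as 0/1, missing as empty fields)."""
    out = cohort.copy()
    for col in RISK_FACTOR_COLUMNS:
        if col in out.columns:
            bools = out[col]
            out[col] = [("" if pd.isna(v) else str(int(bool(v)))) for v in bools]
    cols = [c for c in list(COHORT_COLUMNS) + list(OPTIONAL_COLUMNS) if c in out.columns]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out[cols].to_csv(fh, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# genotypes

_RAW_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypePanel:
    """Read a dosage panel from PLINK ``.raw`` text or VCF.

    ``.raw``: whitespace-delimited, six metadata columns then one
    ``SNPID_A`` column per SNP holding counts of allele A.  VCF: diploid GT
    fields are mapped to alternate-allele dosage (0/0 -> 0, 0/1 -> 1,
    1/1 -> 2); a missing genotype is an error -- no imputation is done.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "raw"
    if format == "raw":
        return _read_raw(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_raw(path: Path) -> GenotypePanel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise CohortDataError(f"{path}: empty genotype file")
    header = lines[0].split()
    if tuple(header[:6]) != _RAW_META:
        raise CohortDataError(f"{path}: not a PLINK .raw header (expected {' '.join(_RAW_META)} ...)")
    snp_cols = header[6:]
    snp_ids, alleles = [], []
    for colname in snp_cols:
        if "_" not in colname:
            raise CohortDataError(f"{path}: SNP column {colname!r} lacks an _allele suffix")
        snp, allele = colname.rsplit("_", 1)
        snp_ids.append(snp)
        alleles.append(allele)

    n_fields = len(header)
    dosages = np.empty((len(lines) - 1, len(snp_cols)))
    for li, line in enumerate(lines[1:], start=2):
        parts = line.split()
        if len(parts) != n_fields:
            raise CohortDataError(
                f"{path}: line {li} has {len(parts)} fields, expected {n_fields}"
            )
        for jj, s in enumerate(parts[6:]):
            if s in ("NA", "", "."):
                raise CohortDataError(f"{path}: line {li}: missing dosage for {snp_cols[jj]}")
            try:
                dosages[li - 2, jj] = float(s)
            except ValueError:
                raise CohortDataError(f"{path}: line {li}: bad dosage {s!r}") from None

    freqs = dosages.mean(axis=0) / 2.0
    return GenotypePanel(
        dosages=dosages,
        snp_ids=snp_ids,
        positions=np.arange(1, len(snp_ids) + 1, dtype=np.int64),
        effect_alleles=alleles,
        allele_freqs=np.clip(freqs, 1e-6, 1 - 1e-6),
    )


def _read_vcf(path: Path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    snp_ids, positions, alleles, rows = [], [], [], []
    for var in vcf:
        gts = np.asarray([g[:2] for g in var.genotypes], dtype=float)
        if np.any(gts < 0):
            raise CohortDataError(
                f"{path}: missing genotype at {var.ID or var.POS}; no imputation is done"
            )
        rows.append(gts.sum(axis=1))
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        alleles.append(var.ALT[0] if var.ALT else var.REF)
    if not rows:
        raise CohortDataError(f"{path}: no variants found")
    dosages = np.asarray(rows).T
    return GenotypePanel(
        dosages=dosages,
        snp_ids=snp_ids,
        positions=np.asarray(positions, dtype=np.int64),
        effect_alleles=alleles,
        allele_freqs=np.clip(dosages.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6),
    )


def write_genotypes_raw(
    panel: GenotypePanel, path: str | Path, sample_ids: list[str] | None = None
) -> None:
    """Write a panel in the PLINK ``.raw`` dosage dialect."""
    ids = sample_ids or [f"id{i + 1:06d}" for i in range(panel.n_individuals)]
    with open(path, "w") as fh:
        cols = [f"{s}_{a}" for s, a in zip(panel.snp_ids, panel.effect_alleles)]
        fh.write(" ".join(list(_RAW_META) + cols) + "\n")
        for i, sid in enumerate(ids):
            row = panel.dosages[i]
            fh.write(
                f"{sid} {sid} 0 0 0 -9 " + " ".join(_fmt_dosage(v) for v in row) + "\n"
            )


def _fmt_dosage(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# PRS model files


def write_prs_model(model: PrsModel, path: str | Path) -> None:
    """Write a scoring TSV (rsID, effect_allele, effect_weight) plus a YAML
    sidecar (``<path>.yaml``) holding intercept, tuning parameters,
    standardization constants and provenance."""
    path = Path(path)
    pd.DataFrame(
        {
            "rsID": model.snp_ids,
            "effect_allele": model.effect_alleles,
            "effect_weight": model.weights,
        }
    ).to_csv(path, sep="\t", index=False)
    sidecar = {
        "intercept": float(model.intercept),
        "p_threshold": model.p_threshold,
        "lambda": model.lam,
        "ref_mean": model.ref_mean,
        "ref_sd": model.ref_sd,
        "train_n": model.train_n,
        "seed": model.seed,
        "selection_rmse": model.selection_rmse,
    }
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def read_prs_model(path: str | Path) -> PrsModel:
    path = Path(path)
    tab = pd.read_csv(path, sep="\t")
    sidecar_path = path.with_suffix(path.suffix + ".yaml")
    meta = {}
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            meta = yaml.safe_load(fh) or {}
    return PrsModel(
        snp_ids=tab["rsID"].astype(str).tolist(),
        effect_alleles=tab["effect_allele"].astype(str).tolist(),
        weights=tab["effect_weight"].to_numpy(dtype=float),
        intercept=float(meta.get("intercept", 0.0)),
        p_threshold=meta.get("p_threshold"),
        lam=meta.get("lambda"),
        ref_mean=meta.get("ref_mean"),
        ref_sd=meta.get("ref_sd"),
        train_n=meta.get("train_n"),
        seed=meta.get("seed"),
        selection_rmse=meta.get("selection_rmse"),
    )


# ---------------------------------------------------------------------------
# run configuration


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class CohortBlock:
    n_individuals: int = 5000
    n_snps: int = 1000
    n_causal: int = 100
    h2_sos: float = 0.25
    sos_bmd_corr: float = 0.5
    maf_range: list[float] = field(default_factory=lambda: [0.05, 0.5])
    block_size: int = 10
    block_rho: float = 0.8
    age_range: list[float] = field(default_factory=lambda: [50.0, 85.0])
    female_fraction: float = 0.54
    age_bmd_slope: float = 0.02
    prevalences: dict[str, float] | None = None


@dataclass
class PrsBlock:
    fractions: list[float] = field(default_factory=lambda: [0.80, 0.0125, 0.1875])
    p_thresholds: list[float] = field(default_factory=lambda: [5e-8, 5e-6, 5e-4, 5e-3, 5e-2, 1.0])
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    tol: float = 1e-7
    max_sweeps: int = 10000
    n_pcs: int = 10
    r2_max: float = 0.05


@dataclass
class EvaluationBlock:
    min_sensitivity: float = 90.0
    select_thresholds: bool = False
    threshold_grid: list[float] | None = None


@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    seed: int = 0
    out_dir: str = "gsos_run"
    write_genotypes: bool = False
    cohort: CohortBlock = field(default_factory=CohortBlock)
    frax_surrogate: dict = field(default_factory=dict)  # FraxSurrogateParams overrides
    screening: dict = field(default_factory=dict)  # NoggConfig overrides
    prs: PrsBlock = field(default_factory=PrsBlock)
    evaluation: EvaluationBlock = field(default_factory=EvaluationBlock)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, sub in (("cohort", CohortBlock), ("prs", PrsBlock), ("evaluation", EvaluationBlock)):
            if key in data and isinstance(data[key], dict):
                data[key] = _from_dict(sub, data[key])
        return _from_dict(cls, data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text
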