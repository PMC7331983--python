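"""Polygenic score training: data splits, GWAS, clumping, LASSO path.

The training recipe mirrors large-biobank practice for quantitative-trait
scores: the cohort is split into a training set (per-SNP association scan
and LASSO fits), a small model-selection set (picking the p-value threshold
and penalty that minimize prediction RMSE), and a held-out test set where
the single selected score is evaluated -- so exactly one final model is ever
assessed on held-out data.

The per-SNP scan is ordinary least squares of the phenotype on each dosage
with covariates (age, sex, and genotype principal components); p-values come
from the t statistic of the dosage term.  LASSO solutions are computed by
cyclic coordinate descent on the Gram matrix with warm starts down a
decreasing penalty grid, minimizing

    (2n)^-1 ||y - X b||^2 + lambda ||b||_1

on column-standardized X; KKT subgradient residuals are exposed for
verification.  Traditional clump+threshold scores (GWAS betas of LD-clumped
index SNPs) are provided as the comparator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import GenotypePanel

__all__ = [
    "SplitAssignment",
    "split_cohort",
    "run_gwas",
    "ld_clump",
    "LassoPath",
    "fit_lasso_path",
    "lasso_kkt_residual",
    "PrsCandidate",
    "PrsModel",
    "select_model",
    "traditional_prs",
    "score_and_standardize",
    "variance_explained",
    "incremental_r2",
    "genotype_pcs",
    "train_gsos",
    "ConvergenceError",
    "DEFAULT_P_THRESHOLDS",
]

logger = logging.getLogger(__name__)

#: p-value threshold grid defining the nested SNP sets fed to the LASSO.
DEFAULT_P_THRESHOLDS = (5e-8, 5e-6, 5e-4, 5e-3, 5e-2, 1.0)


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitAssignment:
    training_idx: np.ndarray
    selection_idx: np.ndarray
    test_idx: np.ndarray


def split_cohort(
    n: int,
    fractions: tuple[float, float, float] = (0.80, 0.0125, 0.1875),
    seed: int = 0,
) -> SplitAssignment:
    """Randomly partition ``n`` individuals into training / model-selection /
    test sets with the given fractions (default 80% / 1.25% / 18.75%)."""
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    perm = np.random.default_rng(seed).permutation(n)
    c1 = round(fractions[0] * n)
    c2 = round((fractions[0] + fractions[1]) * n)
    return SplitAssignment(
        training_idx=np.sort(perm[:c1]),
        selection_idx=np.sort(perm[c1:c2]),
        test_idx=np.sort(perm[c2:]),
    )


# ---------------------------------------------------------------------------
# GWAS


def run_gwas(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP additive-allelic association scan.

    Fits, for each SNP separately, least squares of the phenotype on dosage
    plus covariates (an intercept is always included), via residualization
    of both sides against the covariate block; the slope, its standard
    error, and the two-sided p-value of the dosage t statistic are exact for
    the joint model.  Monomorphic SNPs are flagged with beta 0 and p 1.
    """
    y = np.asarray(phenotype, dtype=float)
    n = panel.n_individuals
    if len(y) != n:
        raise ValueError("phenotype length must equal panel rows")
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    q, _ = np.linalg.qr(C)

    yr = y - q @ (q.T @ y)
    X = panel.dosages
    Xr = X - q @ (q.T @ X)

    sx2 = np.einsum("ij,ij->j", Xr, Xr)
    mono = X.std(axis=0) == 0.0
    safe = np.where(sx2 > 0, sx2, 1.0)
    xty = Xr.T @ yr
    beta = np.where(mono, 0.0, xty / safe)
    df = n - C.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    rss = np.maximum(yr @ yr - beta * xty, 0.0)
    se = np.sqrt(rss / df / safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(mono, 1.0, np.clip(p, np.nextafter(0, 1), 1.0))
    se = np.where(mono, np.inf, se)

    if mono.any():
        logger.warning("%d monomorphic SNP(s) flagged in GWAS", int(mono.sum()))
    return pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "chrom": 1,
            "pos": panel.positions,
            "effect_allele": panel.effect_alleles,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
            "monomorphic": mono,
        }
    )


# ---------------------------------------------------------------------------
# LD clumping


def ld_clump(
    gwas: pd.DataFrame,
    panel: GenotypePanel,
    r2_max: float = 0.05,
    p_max: float = 1.0,
    individual_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy LD clumping: repeatedly take the most significant unassigned
    SNP with p <= p_max as an index SNP and remove every SNP whose squared
    dosage correlation with it exceeds ``r2_max``.

    ``individual_idx`` restricts the correlation computation to a subset of
    individuals (typically the training set).  Returns panel column indices
    of the index SNPs in selection order; ties on p go to the smaller column
    index.
    """
    if not 0.0 < r2_max < 1.0:
        raise ValueError("r2_max must be in (0, 1)")
    p = gwas["p"].to_numpy(dtype=float)
    if len(p) != panel.n_snps:
        raise ValueError("gwas table and panel disagree on SNP count")
    mono = gwas["monomorphic"].to_numpy(dtype=bool) if "monomorphic" in gwas else np.zeros(len(p), bool)
    candidates = np.flatnonzero((p <= p_max) & ~mono)
    if candidates.size == 0:
        return np.array([], dtype=int)

    D = panel.dosages if individual_idx is None else panel.dosages[np.asarray(individual_idx)]
    Z = D[:, candidates]
    Z = Z - Z.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", Z, Z))
    norms[norms == 0] = 1.0
    Z = Z / norms

    order = np.lexsort((candidates, p[candidates]))  # by p, then column index
    available = np.ones(candidates.size, dtype=bool)
    selected = []
    for k in order:
        if not available[k]:
            continue
        selected.append(int(candidates[k]))
        r = Z[:, available].T @ Z[:, k]
        drop = np.flatnonzero(available)[r**2 > r2_max]
        available[drop] = False
        available[k] = False  # the index SNP is assigned to its own clump
    return np.array(selected, dtype=int)


# ---------------------------------------------------------------------------
# LASSO path by coordinate descent on the Gram matrix


def _soft(z: float, lam: float) -> float:
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


def _cd_pass(G, c, lam, beta, grad, index_set) -> float:
    """One cyclic pass over ``index_set``; updates beta/grad in place and
    returns the largest coefficient change.  grad maintains c - G @ beta."""
    max_delta = 0.0
    for j in index_set:
        z = grad[j] + beta[j]  # G has unit diagonal on the standardized scale
        new = _soft(z, lam)
        delta = new - beta[j]
        if delta != 0.0:
            grad -= G[:, j] * delta
            beta[j] = new
            if abs(delta) > max_delta:
                max_delta = abs(delta)
    return max_delta


@dataclass
class LassoPath:
    """Solutions down a decreasing penalty grid (warm-started)."""

    lambdas: np.ndarray
    betas: np.ndarray  # (n_lambda, p) on the original dosage scale
    intercepts: np.ndarray
    betas_std: np.ndarray  # (n_lambda, p) on the standardized design
    kkt_residuals: np.ndarray
    n_active: np.ndarray
    col_mean: np.ndarray
    col_sd: np.ndarray


def lasso_kkt_residual(G: np.ndarray, c: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """Max violation of the subgradient stationarity conditions."""
    grad = c - G @ beta
    active = beta != 0
    res = 0.0
    if (~active).any():
        res = max(res, float(np.max(np.abs(grad[~active]))) - lam)
    if active.any():
        res = max(res, float(np.max(np.abs(grad[active] - lam * np.sign(beta[active])))))
    return max(res, 0.0)


def fit_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
    gram: np.ndarray | None = None,
    xty: np.ndarray | None = None,
) -> LassoPath:
    """Fit the L1 path ``argmin (2n)^-1 ||y - Xb||^2 + lam ||b||_1``.

    X is column-standardized internally; returned coefficients are mapped
    back to the original dosage scale with a matching intercept.  If no grid
    is supplied, ``n_lambda`` log-spaced penalties from lambda_max (the
    smallest penalty with an all-zero solution) down to
    ``lambda_min_ratio * lambda_max`` are used.  ``gram``/``xty`` allow a
    precomputed standardized Gram matrix X'X/n and correlation vector X'y/n
    to be reused across nested SNP subsets.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on sample count")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    y_mean = y.mean()
    yc = y - y_mean

    if gram is None or xty is None:
        Xs = (X - mu) / sd_safe
        gram = (Xs.T @ Xs) / n
        xty = (Xs.T @ yc) / n
    c = np.asarray(xty, dtype=float)
    G = np.asarray(gram, dtype=float)

    lam_max = float(np.max(np.abs(c))) if p else 0.0
    if lambda_grid is None:
        if lam_max == 0.0:
            raise ValueError("phenotype is uncorrelated with every column; supply a grid")
        lambda_grid = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(lambda_grid <= 0) or np.any(np.diff(lambda_grid) >= 0):
        raise ValueError("lambda grid must be positive and strictly decreasing")

    L = len(lambda_grid)
    beta = np.zeros(p)
    grad = c.copy()
    betas_std = np.empty((L, p))
    kkt = np.empty(L)
    all_idx = np.arange(p)
    for li, lam in enumerate(lambda_grid):
        sweeps = 0
        while True:
            max_d = _cd_pass(G, c, lam, beta, grad, all_idx)
            sweeps += 1
            if max_d < tol:
                break
            active = np.flatnonzero(beta)
            while max_d >= tol and sweeps < max_sweeps:
                max_d = _cd_pass(G, c, lam, beta, grad, active)
                sweeps += 1
            if sweeps >= max_sweeps:
                raise ConvergenceError(
                    f"coordinate descent did not converge at lambda={lam:g} "
                    f"({sweeps} sweeps, last max change {max_d:g})"
                )
        betas_std[li] = beta
        kkt[li] = lasso_kkt_residual(G, c, beta, lam)

    betas = betas_std / sd_safe
    intercepts = y_mean - betas @ mu
    return LassoPath(
        lambdas=lambda_grid,
        betas=betas,
        intercepts=intercepts,
        betas_std=betas_std,
        kkt_residuals=kkt,
        n_active=(betas_std != 0).sum(axis=1),
        col_mean=mu,
        col_sd=sd,
    )


# ---------------------------------------------------------------------------
# models


@dataclass
class PrsCandidate:
    """One (p-threshold, lambda) point of the training grid."""

    p_threshold: float
    lam: float
    snp_indices: np.ndarray  # panel column indices
    snp_ids: list[str]
    effect_alleles: list[str]
    weights: np.ndarray  # original dosage scale, aligned with snp_indices
    intercept: float

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.weights))


@dataclass
class PrsModel:
    """Sparse SNP weight vector with training provenance and the
    standardization constants of the reference population."""

    snp_ids: list[str]
    effect_alleles: list[str]
    weights: np.ndarray
    intercept: float = 0.0
    p_threshold: float | None = None
    lam: float | None = None
    ref_mean: float | None = None
    ref_sd: float | None = None
    train_n: int | None = None
    seed: int | None = None
    selection_rmse: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("PRS weights must be finite")
        if len(self.snp_ids) != len(self.weights) or len(self.effect_alleles) != len(self.weights):
            raise ValueError("snp metadata and weights disagree in length")
        if self.ref_sd is not None and self.ref_sd <= 0:
            raise ValueError("reference sd must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def select_model(
    candidates: list[PrsCandidate],
    selection_X: np.ndarray,
    selection_y: np.ndarray,
    train_n: int | None = None,
    seed: int | None = None,
) -> PrsModel:
    """Pick the candidate with the lowest selection-set RMSE.

    Ties go to the sparser candidate, then to the larger penalty, so the
    chosen model is deterministic.  Exactly one model is returned for
    downstream evaluation.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    y = np.asarray(selection_y, dtype=float)

    best = None
    best_key = None
    for cand in candidates:
        pred = selection_X[:, cand.snp_indices] @ cand.weights + cand.intercept
        rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
        key = (rmse, cand.n_active, -cand.lam)
        if best_key is None or key < best_key:
            best, best_key = cand, key

    keep = best.weights != 0
    return PrsModel(
        snp_ids=[s for s, k in zip(best.snp_ids, keep) if k],
        effect_alleles=[a for a, k in zip(best.effect_alleles, keep) if k],
        weights=best.weights[keep],
        intercept=best.intercept,
        p_threshold=best.p_threshold,
        lam=best.lam,
        train_n=train_n,
        seed=seed,
        selection_rmse=best_key[0],
    )


def traditional_prs(
    gwas: pd.DataFrame,
    panel: GenotypePanel,
    p_threshold: float,
    r2_max: float = 0.05,
    individual_idx: np.ndarray | None = None,
) -> PrsModel:
    """Clump+threshold score: GWAS betas of LD-clumped index SNPs passing
    the p-value threshold, with zero intercept."""
    idx = ld_clump(gwas, panel, r2_max=r2_max, p_max=p_threshold, individual_idx=individual_idx)
    if idx.size == 0:
        logger.warning("traditional PRS at p<=%g contains zero SNPs", p_threshold)
    betas = gwas["beta"].to_numpy(dtype=float)
    return PrsModel(
        snp_ids=[panel.snp_ids[j] for j in idx],
        effect_alleles=[panel.effect_alleles[j] for j in idx],
        weights=betas[idx],
        intercept=0.0,
        p_threshold=p_threshold,
    )


def score_and_standardize(
    model: PrsModel,
    panel: GenotypePanel,
    reference_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Apply a PRS to a panel and standardize it.

    The raw score is the weighted dosage sum (plus intercept); SNPs whose
    panel effect allele disagrees with the model's are counted as ``2 - d``.
    Standardization constants are computed on ``reference_idx`` (and stored
    in the model) or reused from the model if already set.
    """
    col = {s: j for j, s in enumerate(panel.snp_ids)}
    missing = [s for s in model.snp_ids if s not in col]
    if missing:
        raise KeyError(f"panel lacks {len(missing)} model SNP(s): {missing[:5]}")
    if model.n_snps == 0:
        raise ValueError("cannot score with an empty model")
    idx = np.array([col[s] for s in model.snp_ids], dtype=int)
    D = panel.dosages[:, idx]
    flip = np.array(
        [panel.effect_alleles[j] != a for j, a in zip(idx, model.effect_alleles)]
    )
    if flip.any():
        logger.warning("flipping %d SNP(s) with mismatched effect alleles", int(flip.sum()))
        D = np.where(flip, 2.0 - D, D)
    raw = D @ model.weights + model.intercept

    if reference_idx is not None:
        ref = raw[np.asarray(reference_idx)]
        mean, sd = float(ref.mean()), float(ref.std())
        if sd == 0.0:
            raise ValueError("zero variance on the standardization reference set")
        model.ref_mean, model.ref_sd = mean, sd
    elif model.ref_mean is None or model.ref_sd is None:
        raise ValueError("model has no standardization reference; pass reference_idx")
    return (raw - model.ref_mean) / model.ref_sd


# ---------------------------------------------------------------------------
# variance explained


def variance_explained(
    predictions: np.ndarray,
    outcome: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Squared Pearson correlation with a nonparametric bootstrap
    percentile 95% CI over individuals."""
    x = np.asarray(predictions, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if len(x) != len(y):
        raise ValueError("predictions and outcome disagree in length")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")

    def r2(a, b):
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    est = r2(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        boots[b] = r2(xb, yb) if xb.std() > 0 and yb.std() > 0 else 0.0
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return est, (float(lo), float(hi))


def incremental_r2(
    cohort: pd.DataFrame,
    outcome: str | np.ndarray,
    base_covariates: list[str],
    added_covariates: list[str],
) -> tuple[float, float]:
    """Variance explained by nested least-squares fits: the base covariate
    set and base plus added.  Returns (r2_base, r2_full)."""
    y = cohort[outcome].to_numpy(dtype=float) if isinstance(outcome, str) else np.asarray(outcome, float)

    def design(cols: list[str]) -> np.ndarray:
        mats = [np.ones(len(cohort))]
        for c in cols:
            v = cohort[c]
            if v.dtype == object or str(v.dtype) == "category":
                mats.append((v == "female").to_numpy(dtype=float))
            else:
                mats.append(v.to_numpy(dtype=float))
        return np.column_stack(mats)

    def fit_r2(Z: np.ndarray) -> float:
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("collinear covariates")
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
        tss = np.sum((y - y.mean()) ** 2)
        return float(1.0 - resid @ resid / tss)

    return fit_r2(design(base_covariates)), fit_r2(design(base_covariates + added_covariates))


# ---------------------------------------------------------------------------
# covariates & end-to-end training


def genotype_pcs(
    panel: GenotypePanel,
    n_pcs: int = 10,
    individual_idx: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Top principal components of the standardized dosage matrix, as
    population-structure covariates for the association scan."""
    from sklearn.decomposition import PCA

    D = panel.dosages if individual_idx is None else panel.dosages[np.asarray(individual_idx)]
    sd = D.std(axis=0)
    Z = (D - D.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n_pcs = min(n_pcs, min(Z.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    return pca.fit_transform(Z)


def _residualize(y: np.ndarray, C: np.ndarray, coef: np.ndarray | None = None):
    """Residual of y on covariates C (with intercept); returns (resid, coef)."""
    Z = np.column_stack([np.ones(len(y)), C]) if C is not None else np.ones((len(y), 1))
    if coef is None:
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ coef, coef


def train_gsos(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    train_idx: np.ndarray,
    selection_idx: np.ndarray,
    p_thresholds: tuple[float, ...] = DEFAULT_P_THRESHOLDS,
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
    seed: int | None = None,
) -> tuple[PrsModel, pd.DataFrame, pd.DataFrame]:
    """Full training loop: GWAS on the training set, LASSO paths on
    p-value-thresholded SNP sets, candidate selection by RMSE on the
    model-selection set.

    The LASSO is fit on the phenotype residualized against the covariates,
    keeping the design genotype-only so the resulting score predicts the
    phenotype from genotype alone.  Returns the selected model, the GWAS
    table, and a candidate grid summary (threshold, lambda, SNP counts,
    selection RMSE).
    """
    train_idx = np.asarray(train_idx)
    selection_idx = np.asarray(selection_idx)
    y = np.asarray(phenotype, dtype=float)
    train_panel = panel.subset_individuals(train_idx)
    C_train = None if covariates is None else np.asarray(covariates)[train_idx]
    C_sel = None if covariates is None else np.asarray(covariates)[selection_idx]

    gwas = run_gwas(train_panel, y[train_idx], C_train)

    y_train, cov_coef = _residualize(y[train_idx], C_train)
    y_sel, _ = _residualize(y[selection_idx], C_sel, coef=cov_coef)

    p_vals = gwas["p"].to_numpy()
    mono = gwas["monomorphic"].to_numpy(dtype=bool)
    X_train = train_panel.dosages
    X_sel = panel.dosages[selection_idx]

    # Gram matrix of the largest SNP set, sliced for the nested subsets.
    full_set = np.flatnonzero((p_vals <= max(p_thresholds)) & ~mono)
    mu = X_train[:, full_set].mean(axis=0)
    sd = X_train[:, full_set].std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X_train[:, full_set] - mu) / sd
    yc = y_train - y_train.mean()
    G_full = (Xs.T @ Xs) / len(train_idx)
    c_full = (Xs.T @ yc) / len(train_idx)
    pos_in_full = {j: k for k, j in enumerate(full_set)}

    candidates: list[PrsCandidate] = []
    rows = []
    for thr in sorted(p_thresholds):
        snp_set = np.flatnonzero((p_vals <= thr) & ~mono)
        if snp_set.size == 0:
            logger.warning("no SNPs pass p<=%g; skipping threshold", thr)
            continue
        sub = np.array([pos_in_full[j] for j in snp_set])
        path = fit_lasso_path(
            X_train[:, snp_set],
            y_train,
            n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio,
            tol=tol,
            max_sweeps=max_sweeps,
            gram=G_full[np.ix_(sub, sub)],
            xty=c_full[sub],
        )
        ids = [panel.snp_ids[j] for j in snp_set]
        alleles = [panel.effect_alleles[j] for j in snp_set]
        for li, lam in enumerate(path.lambdas):
            candidates.append(
                PrsCandidate(
                    p_threshold=thr,
                    lam=float(lam),
                    snp_indices=snp_set,
                    snp_ids=ids,
                    effect_alleles=alleles,
                    weights=path.betas[li],
                    intercept=float(path.intercepts[li]),
                )
            )
            rows.append(
                {
                    "p_threshold": thr,
                    "lambda": float(lam),
                    "n_snps": snp_set.size,
                    "n_active": int(path.n_active[li]),
                    "kkt_residual": float(path.kkt_residuals[li]),
                }
            )

    model = select_model(candidates, panel.dosages[selection_idx], y_sel,
                         train_n=len(train_idx), seed=seed)
    grid = pd.DataFrame(rows)
    # attach selection RMSE per candidate for reporting
    rmses = []
    for cand in candidates:
        pred = X_sel[:, cand.snp_indices] @ cand.weights + cand.intercept
        rmses.append(float(np.sqrt(np.mean((y_sel - pred) ** 2))))
    grid["selection_rmse"] = rmses
    return model, gwas, grid
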