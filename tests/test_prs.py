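"""Association scan, clumping, penalized path, model selection, scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import hadamard

import gsos_screen as gs
from gsos_screen.prs import (
    ConvergenceError,
    PrsCandidate,
    fit_lasso_path,
    lasso_kkt_residual,
    select_model,
)


class TestSplit:
    def test_published_fractions_give_exact_sizes(self):
        s = gs.split_cohort(10_000, (0.80, 0.0125, 0.1875), seed=1)
        assert (len(s.training_idx), len(s.selection_idx), len(s.test_idx)) == (8000, 125, 1875)

    def test_partition_disjoint_and_complete(self):
        s = gs.split_cohort(3, (1 / 3, 1 / 3, 1 / 3), seed=2)
        all_idx = np.concatenate([s.training_idx, s.selection_idx, s.test_idx])
        assert sorted(all_idx) == [0, 1, 2]

    def test_deterministic_given_seed(self):
        a = gs.split_cohort(1000, seed=3)
        b = gs.split_cohort(1000, seed=3)
        c = gs.split_cohort(1000, seed=4)
        assert np.array_equal(a.training_idx, b.training_idx)
        assert not np.array_equal(a.training_idx, c.training_idx)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            gs.split_cohort(100, (0.5, 0.2, 0.2), seed=0)
        with pytest.raises(ValueError):
            gs.split_cohort(100, (1.2, -0.1, -0.1), seed=0)


class TestGwas:
    def test_exact_linear_phenotype_recovered(self, small_panel):
        j = 7
        y = 2.0 * small_panel.dosages[:, j]
        table = gs.run_gwas(small_panel, y)
        assert table.loc[j, "beta"] == pytest.approx(2.0, abs=1e-8)
        assert table.loc[j, "p"] < 1e-100

    def test_allele_recode_flips_beta_not_p(self, small_panel):
        rng = np.random.default_rng(5)
        y = small_panel.dosages[:, 0] * 0.3 + rng.standard_normal(small_panel.n_individuals)
        t1 = gs.run_gwas(small_panel, y)
        flipped = gs.GenotypePanel(
            dosages=2.0 - small_panel.dosages,
            snp_ids=small_panel.snp_ids,
            positions=small_panel.positions,
            effect_alleles=small_panel.effect_alleles,
            allele_freqs=1 - small_panel.allele_freqs,
        )
        t2 = gs.run_gwas(flipped, y)
        assert np.allclose(t1["beta"], -t2["beta"])
        assert np.allclose(t1["p"], t2["p"])

    def test_monomorphic_flagged(self, small_panel):
        panel = gs.GenotypePanel(
            dosages=np.column_stack([small_panel.dosages[:, :3], np.ones(2000)]),
            snp_ids=[*small_panel.snp_ids[:3], "rs_mono"],
            positions=np.arange(4),
            effect_alleles=["A"] * 4,
            allele_freqs=np.array([0.2, 0.2, 0.2, 0.5]),
        )
        t = gs.run_gwas(panel, np.random.default_rng(0).standard_normal(2000))
        assert t.loc[3, "monomorphic"]
        assert t.loc[3, "beta"] == 0.0 and t.loc[3, "p"] == 1.0

    def test_rank_deficient_covariates_rejected(self, small_panel):
        n = small_panel.n_individuals
        cov = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank"):
            gs.run_gwas(small_panel, np.zeros(n), cov)

    def test_covariate_adjustment_matches_statsmodels(self, small_panel):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n = small_panel.n_individuals
        cov = rng.standard_normal((n, 2))
        y = 0.2 * small_panel.dosages[:, 4] + cov @ [0.5, -0.3] + rng.standard_normal(n)
        table = gs.run_gwas(small_panel, y, cov)
        X = sm.add_constant(np.column_stack([small_panel.dosages[:, 4], cov]))
        fit = sm.OLS(y, X).fit()
        assert table.loc[4, "beta"] == pytest.approx(fit.params[1], abs=1e-10)
        assert table.loc[4, "se"] == pytest.approx(fit.bse[1], abs=1e-10)
        assert table.loc[4, "p"] == pytest.approx(fit.pvalues[1], rel=1e-8)


class TestClump:
    @staticmethod
    def brute_force_clump(p, D, r2_max, p_max):
        """Literal restatement of the greedy rule, kept independent of the
        implementation: repeatedly pick the smallest-p remaining SNP and
        drop everything correlated with it."""
        remaining = [j for j in range(len(p)) if p[j] <= p_max]
        out = []
        while remaining:
            best = min(remaining, key=lambda j: (p[j], j))
            out.append(best)
            keep = []
            for j in remaining:
                r = np.corrcoef(D[:, best], D[:, j])[0, 1]
                if j != best and r**2 <= r2_max:
                    keep.append(j)
            remaining = keep
        return out

    def test_single_significant_snp(self, small_panel):
        gwas = gs.run_gwas(small_panel, np.random.default_rng(1).standard_normal(2000))
        pmin = gwas["p"].min()
        idx = gs.ld_clump(gwas, small_panel, 0.05, p_max=pmin)
        assert list(idx) == [int(gwas["p"].idxmin())]

    def test_perfectly_correlated_snps_collapse(self):
        col = np.random.default_rng(2).binomial(2, 0.3, 500).astype(float)
        panel = gs.GenotypePanel(
            dosages=np.column_stack([col, col, col]),
            snp_ids=["a", "b", "c"],
            positions=np.arange(3),
            effect_alleles=["A"] * 3,
            allele_freqs=np.full(3, 0.3),
        )
        gwas = pd.DataFrame(
            {"p": [0.01, 0.001, 0.5], "monomorphic": False, "beta": 0.1, "se": 1.0}
        )
        idx = gs.ld_clump(gwas, panel, 0.05, 1.0)
        assert list(idx) == [1]

    def test_matches_brute_force_oracle(self, small_panel):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.uniform(size=small_panel.n_snps)
            gwas = pd.DataFrame({"p": p, "monomorphic": False})
            got = list(gs.ld_clump(gwas, small_panel, 0.1, 0.8))
            want = self.brute_force_clump(p, small_panel.dosages, 0.1, 0.8)
            assert got == want


class TestLasso:
    def test_lambda_max_gives_zero_solution(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((100, 10))
        y = X[:, 0] + rng.standard_normal(100)
        Xs = (X - X.mean(0)) / X.std(0)
        lam_max = np.abs(Xs.T @ (y - y.mean())).max() / 100
        path = fit_lasso_path(X, y, lambda_grid=np.array([lam_max * 1.01, lam_max]))
        assert np.all(path.betas_std == 0)

    def test_orthonormal_design_soft_threshold(self):
        H = hadamard(64).astype(float)
        X = H[:, 1:17]  # mean-0, sd-1, mutually orthogonal columns
        rng = np.random.default_rng(5)
        beta = np.zeros(16)
        beta[:5] = [3, -2, 1, 0.5, 0.2]
        y = X @ beta + 0.05 * rng.standard_normal(64)
        ols = X.T @ (y - y.mean()) / 64
        for lam in (1.0, 0.4, 0.1, 0.01):
            path = fit_lasso_path(X, y, lambda_grid=np.array([lam]))
            soft = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
            assert np.abs(path.betas_std[0] - soft).max() < 1e-6

    def test_kkt_conditions_hold(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((150, 30))
        y = X[:, :4] @ [1, -1, 0.5, 2] + rng.standard_normal(150)
        path = fit_lasso_path(X, y, n_lambda=20)
        assert np.all(path.kkt_residuals < 1e-6)

    def test_solution_beats_random_perturbations(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((120, 15))
        y = X[:, 0] * 2 + rng.standard_normal(120)
        lam = 0.1
        path = fit_lasso_path(X, y, lambda_grid=np.array([lam]))
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()

        def objective(b):
            r = yc - Xs @ b
            return r @ r / (2 * len(y)) + lam * np.abs(b).sum()

        star = objective(path.betas_std[0])
        for _ in range(1000):
            perturbed = path.betas_std[0] + rng.normal(0, 0.01, 15)
            assert objective(perturbed) >= star - 1e-12

    def test_agrees_with_independent_solver(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(8)
        X = rng.standard_normal((200, 25))
        y = X[:, :3] @ [1.5, -0.7, 0.3] + rng.standard_normal(200)
        lam = 0.2
        path = fit_lasso_path(X, y, lambda_grid=np.array([lam]))
        Xs = (X - X.mean(0)) / X.std(0)
        sk = Lasso(alpha=lam, tol=1e-10).fit(Xs, y)
        assert np.abs(path.betas_std[0] - sk.coef_).max() < 1e-5

    def test_grid_validation_and_nonconvergence(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((50, 5))
        y = rng.standard_normal(50)
        with pytest.raises(ValueError, match="decreasing"):
            fit_lasso_path(X, y, lambda_grid=np.array([0.1, 0.2]))
        with pytest.raises(ConvergenceError):
            fit_lasso_path(X, y, lambda_grid=np.array([0.01]), max_sweeps=1)


def _make_candidate(indices, weights, thr=1.0, lam=0.1):
    k = len(indices)
    return PrsCandidate(
        p_threshold=thr,
        lam=lam,
        snp_indices=np.asarray(indices),
        snp_ids=[f"rs{j}" for j in indices],
        effect_alleles=["A"] * k,
        weights=np.asarray(weights, dtype=float),
        intercept=0.0,
    )


class TestSelectModel:
    def test_true_score_wins_over_noise(self, small_panel):
        rng = np.random.default_rng(10)
        sos, _, truth = gs.simulate_phenotypes(small_panel, 20, 0.5, seed=11)
        X = small_panel.dosages
        # generative score rescaled to the phenotype scale (weights sqrt(h2)
        # per standardized-score unit), the RMSE-optimal genetic predictor
        g_raw = X[:, truth.causal_indices] @ truth.causal_effects
        scale = np.sqrt(0.5) / g_raw.std()
        good = _make_candidate(truth.causal_indices, truth.causal_effects * scale, lam=0.2)
        good.intercept = -scale * g_raw.mean()
        noise = [
            _make_candidate(
                rng.choice(small_panel.n_snps, 20, replace=False),
                rng.standard_normal(20) * scale,
                lam=0.1 * (i + 1),
            )
            for i in range(5)
        ]
        model = select_model([good, *noise], X, sos)
        assert model.lam == 0.2

    def test_tie_breaks_sparser_then_larger_lambda(self):
        X = np.zeros((20, 3))
        y = np.zeros(20)
        dense = _make_candidate([0, 1], [0.0, 0.0], lam=0.1)
        sparse_small = _make_candidate([0], [0.0], lam=0.1)
        sparse_large = _make_candidate([0], [0.0], lam=0.5)
        # all predict 0 exactly -> RMSE ties; sparser wins, then larger lambda
        model = select_model([dense, sparse_small, sparse_large], X, y)
        assert model.lam == 0.5

    def test_single_candidate_returned(self):
        cand = _make_candidate([0], [0.3])
        model = select_model([cand], np.ones((15, 1)), np.ones(15))
        assert model.weights.tolist() == [0.3]
        with pytest.raises(ValueError):
            select_model([], np.ones((15, 1)), np.ones(15))


class TestTraditionalAndScoring:
    def test_single_snp_score(self, small_panel):
        rng = np.random.default_rng(12)
        y = 0.5 * small_panel.dosages[:, 3] + 0.1 * rng.standard_normal(2000)
        gwas = gs.run_gwas(small_panel, y)
        model = gs.traditional_prs(gwas, small_panel, p_threshold=gwas["p"].min())
        assert model.n_snps == 1
        raw = small_panel.dosages[:, 3] * model.weights[0]
        score = gs.score_and_standardize(model, small_panel, reference_idx=np.arange(2000))
        assert np.allclose(score, (raw - raw.mean()) / raw.std())

    def test_tighter_threshold_never_more_snps(self, small_panel):
        rng = np.random.default_rng(13)
        y = small_panel.dosages[:, :5] @ np.full(5, 0.2) + rng.standard_normal(2000)
        gwas = gs.run_gwas(small_panel, y)
        counts = [
            gs.traditional_prs(gwas, small_panel, thr).n_snps for thr in (1e-4, 1e-2, 0.5, 1.0)
        ]
        assert counts == sorted(counts)

    def test_score_equals_independent_loop(self, small_panel):
        rng = np.random.default_rng(14)
        y = small_panel.dosages[:, :5] @ np.full(5, 0.3) + rng.standard_normal(2000)
        gwas = gs.run_gwas(small_panel, y)
        model = gs.traditional_prs(gwas, small_panel, 0.01)
        score = gs.score_and_standardize(model, small_panel, reference_idx=np.arange(2000))
        col = {s: j for j, s in enumerate(small_panel.snp_ids)}
        raw = np.zeros(2000)
        for snp, w in zip(model.snp_ids, model.weights):
            raw += w * small_panel.dosages[:, col[snp]]
        assert np.allclose(score, (raw - raw.mean()) / raw.std())

    def test_standardization_on_reference(self, small_panel):
        model = gs.PrsModel(
            snp_ids=small_panel.snp_ids[:3],
            effect_alleles=small_panel.effect_alleles[:3],
            weights=np.array([0.1, -0.2, 0.3]),
        )
        ref = np.arange(1000)
        score = gs.score_and_standardize(model, small_panel, reference_idx=ref)
        assert abs(score[ref].mean()) < 1e-10
        assert score[ref].std() == pytest.approx(1.0, abs=1e-10)
        # stored constants are reused without reference_idx
        again = gs.score_and_standardize(model, small_panel)
        assert np.array_equal(score, again)

    def test_allele_flip_and_missing_snp(self, small_panel):
        model = gs.PrsModel(
            snp_ids=[small_panel.snp_ids[0]],
            effect_alleles=["Z"],  # disagrees with the panel -> flip
            weights=np.array([1.0]),
        )
        score = gs.score_and_standardize(model, small_panel, reference_idx=np.arange(2000))
        d = 2.0 - small_panel.dosages[:, 0]
        assert np.allclose(score, (d - d.mean()) / d.std())
        bad = gs.PrsModel(snp_ids=["rs_absent"], effect_alleles=["A"], weights=np.array([1.0]))
        with pytest.raises(KeyError, match="rs_absent"):
            gs.score_and_standardize(bad, small_panel, reference_idx=np.arange(10))

    def test_zero_weight_model_fails_standardization(self, small_panel):
        model = gs.PrsModel(
            snp_ids=small_panel.snp_ids[:2],
            effect_alleles=small_panel.effect_alleles[:2],
            weights=np.zeros(2),
        )
        with pytest.raises(ValueError, match="variance"):
            gs.score_and_standardize(model, small_panel, reference_idx=np.arange(100))


class TestVarianceExplained:
    def test_perfect_prediction(self):
        x = np.random.default_rng(15).standard_normal(100)
        r2, (lo, hi) = gs.variance_explained(x, x, n_boot=50, seed=0)
        assert r2 == pytest.approx(1.0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_independent_inputs_near_zero(self):
        rng = np.random.default_rng(16)
        x, y = rng.standard_normal(100_000), rng.standard_normal(100_000)
        r2, (lo, hi) = gs.variance_explained(x, y, n_boot=100, seed=1)
        assert r2 < 1e-4 and lo < 1e-4

    def test_invariant_to_linear_transform(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(500)
        y = 0.5 * x + rng.standard_normal(500)
        r2a, _ = gs.variance_explained(x, y, n_boot=10, seed=2)
        r2b, _ = gs.variance_explained(3 * x - 7, y, n_boot=10, seed=2)
        assert r2a == pytest.approx(r2b, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            gs.variance_explained(np.ones(50), np.arange(50.0))
        with pytest.raises(ValueError):
            gs.variance_explained(np.arange(5.0), np.arange(5.0))


class TestIncrementalR2:
    def test_outcome_as_covariate_gives_one(self, screening_cohort):
        r2b, r2f = gs.incremental_r2(
            screening_cohort, "sos_std", ["age", "sex"], ["sos_std"]
        )
        assert r2f == pytest.approx(1.0)
        assert r2f >= r2b

    def test_noise_covariate_adds_nothing(self):
        rng = np.random.default_rng(18)
        df = pd.DataFrame(
            {
                "age": rng.uniform(50, 80, 50_000),
                "sex": rng.choice(["female", "male"], 50_000),
                "noise": rng.standard_normal(50_000),
                "y": rng.standard_normal(50_000),
            }
        )
        df["y"] += 0.02 * df["age"]
        r2b, r2f = gs.incremental_r2(df, "y", ["age", "sex"], ["noise"])
        assert r2f >= r2b
        assert r2f - r2b < 1e-3

    def test_collinear_rejected(self, screening_cohort):
        c = screening_cohort.assign(age2=screening_cohort["age"])
        with pytest.raises(ValueError, match="collinear"):
            gs.incremental_r2(c, "sos_std", ["age"], ["age2"])


class TestEndToEndProperties:
    def test_noiseless_gwas_recovers_effect_signs(self):
        # every SNP causal, near-noiseless phenotype: the scan must recover
        # the sign of every effect estimated at > 4 standard errors
        panel = gs.simulate_genotypes(3000, 40, block_rho=0.3, seed=19)
        sos, _, truth = gs.simulate_phenotypes(panel, 40, 0.95, seed=20)
        table = gs.run_gwas(panel, sos)
        strong = table["beta"].abs() > 4 * table["se"]
        est_sign = np.sign(table["beta"].to_numpy())
        true_sign = np.zeros(40)
        true_sign[truth.causal_indices] = np.sign(truth.causal_effects)
        agree = est_sign[strong.to_numpy()] == true_sign[strong.to_numpy()]
        assert strong.sum() > 10
        assert agree.mean() > 0.95

    def test_lasso_weights_attenuated_vs_gwas(self):
        # joint penalized weights of activated SNPs are shrunken relative to
        # the marginal association estimates: correlated with them, but with
        # aggregate slope < 1.  (Per-SNP attenuation is exact only for
        # orthogonal designs -- covered by the soft-threshold test -- since
        # LD lets the penalty split weight unevenly within a block.)
        panel = gs.simulate_genotypes(4000, 100, block_rho=0.5, seed=21)
        sos, _, _ = gs.simulate_phenotypes(panel, 30, 0.4, seed=22)
        split = gs.split_cohort(4000, (0.8, 0.1, 0.1), seed=23)
        model, gwas, _ = gs.train_gsos(
            panel, sos, None, split.training_idx, split.selection_idx,
            p_thresholds=(5e-4, 5e-2, 1.0), n_lambda=25,
        )
        sd = panel.dosages[split.training_idx].std(axis=0)
        col = {s: j for j, s in enumerate(panel.snp_ids)}
        idx = np.array([col[s] for s in model.snp_ids])
        w_std = model.weights * sd[idx]
        b_std = gwas["beta"].to_numpy()[idx] * sd[idx]
        slope = (w_std @ b_std) / (b_std @ b_std)
        assert 0.0 < slope < 1.0
        assert np.corrcoef(w_std, b_std)[0, 1] > 0.5
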