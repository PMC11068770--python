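"""Mixed-model null fits and single-SNP scans against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metagwas import (
    KinshipMatrix,
    ModelError,
    SimConfig,
    aggregate_replicates,
    compute_kinship,
    fit_null_lmm,
    run_context_gwas,
    scan_snps,
    simulate_genotypes,
    simulate_phenotypes,
)

from conftest import make_genotypes


def simulate_context(cfg):
    G = simulate_genotypes(cfg)
    table, truth = simulate_phenotypes(G, cfg)
    ctxs = aggregate_replicates(table, accession_ids=G.accession_ids)
    return G, ctxs, truth


def dense_gls_oracle(y, x, K, lam):
    """Brute-force GLS with an explicit covariance inverse (small n only)."""
    n = len(y)
    Sigma = lam * K + np.eye(n)
    W = np.linalg.inv(Sigma)
    X = np.column_stack([np.ones(n), x])
    XtWX = X.T @ W @ X
    XtWy = X.T @ W @ y
    coef = np.linalg.solve(XtWX, XtWy)
    resid = y - X @ coef
    sigma2 = float(resid @ W @ resid) / (n - 2)
    cov = sigma2 * np.linalg.inv(XtWX)
    return coef[1], float(np.sqrt(cov[1, 1]))


class TestNullFit:
    def test_h2_recovery_on_own_kinship(self):
        # median over a few replicates: per-fit sampling error is ~0.15
        estimates = []
        for seed in range(5):
            cfg = SimConfig(n_accessions=500, n_snps=1000, n_environments=1,
                            n_qtl=0, polygenic_h2=0.5, genotype_missing_rate=0.0,
                            phenotype_missing_rate=0.0, seed=seed)
            G, ctxs, _ = simulate_context(cfg)
            K = compute_kinship(G)
            estimates.append(fit_null_lmm(next(iter(ctxs.values())), K).h2)
        assert np.median(estimates) == pytest.approx(0.5, abs=0.15)

    def test_lambda_collapses_without_polygenic_signal(self):
        small = 0
        for seed in range(20):
            cfg = SimConfig(n_accessions=200, n_snps=500, n_environments=1,
                            n_qtl=0, polygenic_h2=0.0, genotype_missing_rate=0.0,
                            phenotype_missing_rate=0.0, seed=100 + seed)
            G, ctxs, _ = simulate_context(cfg)
            K = compute_kinship(G)
            if fit_null_lmm(next(iter(ctxs.values())), K).lambda_ < 0.05:
                small += 1
        assert small > 10  # majority of replicates at the boundary

    def test_identity_kinship_reduces_to_iid_normal_likelihood(self, rng):
        n = 80
        y = pd.Series(rng.normal(2.0, 1.5, n),
                      index=[f"A{i}" for i in range(n)])
        K = KinshipMatrix(np.eye(n), list(y.index))
        fit = fit_null_lmm(y, K)
        mu, sd = y.mean(), y.std(ddof=0)
        iid_ll = float(np.sum(stats.norm.logpdf(y, mu, sd)))
        assert fit.loglik == pytest.approx(iid_ll, abs=1e-6)
        assert fit.intercept == pytest.approx(mu, abs=1e-8)

    def test_duplicate_accessions_rejected(self, rng):
        y = pd.Series(rng.normal(size=40), index=["A1"] * 2 + [f"B{i}" for i in range(38)])
        K = KinshipMatrix(np.eye(40), [f"C{i}" for i in range(40)])
        with pytest.raises(ModelError, match="duplicate"):
            fit_null_lmm(y, K)

    def test_constant_phenotype_rejected(self):
        y = pd.Series(np.ones(40), index=[f"A{i}" for i in range(40)])
        K = KinshipMatrix(np.eye(40), list(y.index))
        with pytest.raises(ModelError, match="variance"):
            fit_null_lmm(y, K)


@pytest.fixture(scope="module")
def small_instance():
    cfg = SimConfig(n_accessions=50, n_snps=30, n_environments=1, n_qtl=2,
                    qtl_variance_fraction=0.1, polygenic_h2=0.3,
                    genotype_missing_rate=0.0, phenotype_missing_rate=0.0,
                    seed=5)
    G, ctxs, _ = simulate_context(cfg)
    K = compute_kinship(G)
    y = next(iter(ctxs.values()))
    return G, y, K


class TestScan:
    def test_matches_dense_gls_oracle(self, small_instance):
        G, y, K = small_instance
        null = fit_null_lmm(y, K)
        result = scan_snps(G, null)
        Ksub = K.restrict(null.accession_ids).values
        yv = y.values.dropna().to_numpy()
        for j in range(G.n_snps):
            x = G.dosage[:, j]
            if np.var(x) == 0:
                continue
            b, se = dense_gls_oracle(yv, x, Ksub, null.lambda_)
            assert result["beta"].iloc[j] == pytest.approx(b, abs=1e-6)
            assert result["se"].iloc[j] == pytest.approx(se, abs=1e-6)

    def test_identity_kinship_at_zero_lambda_is_ols(self, rng):
        n = 40
        x = rng.integers(0, 3, n).astype(float)
        y = pd.Series(0.5 * x + rng.normal(size=n),
                      index=[f"A{i}" for i in range(n)])
        G = make_genotypes(x.reshape(-1, 1), accession_ids=list(y.index))
        null = fit_null_lmm(y, KinshipMatrix(np.eye(n), list(y.index)))
        null.lambda_ = 0.0  # force the OLS limit
        res = scan_snps(G, null)
        X = np.column_stack([np.ones(n), x])
        coef, rss, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
        sigma2 = float(rss[0]) / (n - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        assert res["beta"].iloc[0] == pytest.approx(coef[1], abs=1e-8)
        assert res["se"].iloc[0] == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-8)

    def test_constant_snp_gets_missing_result(self, rng):
        n = 40
        dosage = np.column_stack([np.ones(n), rng.integers(0, 3, n)])
        y = pd.Series(rng.normal(size=n), index=[f"A{i}" for i in range(n)])
        G = make_genotypes(dosage, accession_ids=list(y.index))
        null = fit_null_lmm(y, KinshipMatrix(np.eye(n), list(y.index)))
        res = scan_snps(G, null)
        assert np.isnan(res["p"].iloc[0])
        assert np.isfinite(res["p"].iloc[1])

    def test_type_one_error_calibrated_under_null(self):
        cfg = SimConfig(n_accessions=300, n_snps=2000, n_environments=1,
                        n_qtl=0, polygenic_h2=0.0, genotype_missing_rate=0.0,
                        phenotype_missing_rate=0.0, seed=42)
        G, ctxs, _ = simulate_context(cfg)
        K = compute_kinship(G)
        res = run_context_gwas(G, next(iter(ctxs.values())), K)
        frac = float((res["p"] < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_t_invariant_under_affine_phenotype_transform(self, small_instance):
        G, y, K = small_instance
        base = run_context_gwas(G, y, K)
        shifted = y.values * -3.0 + 7.0
        from metagwas import ContextVector
        y2 = ContextVector(y.environment, y.treatment, y.trait, shifted)
        other = run_context_gwas(G, y2, K)
        np.testing.assert_allclose(np.abs(base["t"]), np.abs(other["t"]),
                                   rtol=1e-6)
        # sign flips with the scale factor's sign
        np.testing.assert_allclose(base["t"], -other["t"], rtol=1e-6)

    def test_p_monotone_in_abs_t(self, small_instance):
        G, y, K = small_instance
        res = run_context_gwas(G, y, K).dropna(subset=["t"])
        order = res["t"].abs().sort_values().index
        p_sorted = res.loc[order, "p"].to_numpy()
        assert (np.diff(p_sorted) <= 1e-12).all()


class TestPower:
    def test_planted_qtl_attains_minimum_p(self):
        wins = 0
        for seed in range(12):
            cfg = SimConfig(n_accessions=400, n_snps=500, n_environments=1,
                            n_qtl=1, qtl_variance_fraction=0.10,
                            polygenic_h2=0.2, genotype_missing_rate=0.0,
                            phenotype_missing_rate=0.0, seed=200 + seed)
            G, ctxs, truth = simulate_context(cfg)
            K = compute_kinship(G)
            res = run_context_gwas(G, next(iter(ctxs.values())), K)
            top = res.loc[res["p"].idxmin(), "snp_id"]
            wins += top == truth.qtl_snp_ids[0]
        assert wins >= 10

    def test_permuted_phenotype_loses_the_signal(self, rng):
        cfg = SimConfig(n_accessions=300, n_snps=400, n_environments=1,
                        n_qtl=1, qtl_variance_fraction=0.15, polygenic_h2=0.0,
                        genotype_missing_rate=0.0, phenotype_missing_rate=0.0,
                        seed=9)
        G, ctxs, truth = simulate_context(cfg)
        K = compute_kinship(G)
        y = next(iter(ctxs.values()))
        from metagwas import ContextVector
        perm = pd.Series(rng.permutation(y.values.to_numpy()),
                         index=y.values.index)
        res = run_context_gwas(G, ContextVector("E", "t", "Y", perm), K)
        p = res["p"].dropna().to_numpy()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01
        planted = res.set_index("snp_id").loc[truth.qtl_snp_ids[0], "p"]
        assert planted > 1e-4
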