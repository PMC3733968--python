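"""REML variance components, per-SNP mixed-model tests, QTL correction."""

import numpy as np
import pandas as pd
import pytest

from pathsetassoc import (KinshipSpectral, PedigreeMixedLM, association_scan,
                          build_A, correct_phenotype_for_qtl,
                          estimate_variance_components)
from pathsetassoc.mixed_model import test_snp as snp_test
from pathsetassoc.simulate import (SimulationConfig, generate_pedigree,
                                   simulate_genotypes, simulate_traits)

from oracles import dense_gls, dense_reml_loglik


@pytest.fixture(scope="module")
def fixture50(rng_mod=np.random.default_rng(515)):
    """50-animal panel with a known relationship structure and genotypes."""
    cfg = SimulationConfig(n_founders=12, n_generations=3, n_animals=50,
                           n_chromosomes=1, chrom_length_bp=2_000_000,
                           n_snps=30, n_genes=2, seed=15)
    ped = generate_pedigree(cfg)
    geno, _ = simulate_genotypes(ped, cfg)
    A = build_A(ped)
    pheno = simulate_traits(ped, geno, A, cfg)
    return ped, geno, A, pheno


class TestAgainstDenseOracles:
    def test_gls_matches_explicit_inversion_to_1e8_relative(self, fixture50):
        ped, geno, A, pheno = fixture50
        y = pheno["milk_yield"].to_numpy()
        x = geno.iloc[:, 4].to_numpy(float)
        X = np.column_stack([np.ones(50), x])
        sigma_a2, sigma_e2 = 0.4, 0.6
        V = sigma_a2 * A.values + sigma_e2 * np.eye(50)
        beta_o, se_o, f_o, p_o = dense_gls(y, X, V)

        model = PedigreeMixedLM(pheno["milk_yield"], x[:, None], A, exog_names=["snp"])
        res = model.fit_fixed(sigma_a2, sigma_e2)
        assert res.params["snp"] == pytest.approx(beta_o[1], rel=1e-8)
        assert res.bse["snp"] == pytest.approx(se_o[1], rel=1e-8)
        assert res.pvalues["snp"] == pytest.approx(p_o[1], rel=1e-8)

    def test_spectral_loglik_equals_dense_formula(self, fixture50):
        ped, geno, A, pheno = fixture50
        y = pheno["fat_pct"]
        model = PedigreeMixedLM(y, None, A)
        for delta in (0.01, 0.5, 1.0, 7.3, 120.0):
            dense = dense_reml_loglik(y.to_numpy(), np.ones((50, 1)), A.values, delta)
            assert model.loglike_reml(delta) == pytest.approx(dense, rel=1e-8)

    def test_reml_optimum_beats_40_point_delta_grid(self, fixture50):
        ped, geno, A, pheno = fixture50
        y = pheno["fertility"]
        model = PedigreeMixedLM(y, None, A)
        res = model.fit()
        grid = np.logspace(-3, 3, 40)
        dense_vals = [dense_reml_loglik(y.to_numpy(), np.ones((50, 1)), A.values, d)
                      for d in grid]
        assert res.loglik_reml >= max(dense_vals) - 1e-8

    def test_exact_mode_test_snp_agrees_with_dense_per_snp_reml(self, fixture50):
        ped, geno, A, pheno = fixture50
        y = pheno["protein_pct"]
        x = geno.iloc[:, 7]
        r = snp_test(y, x, A, mode="exact")
        # dense re-optimisation over the same delta range
        X = np.column_stack([np.ones(50), x.to_numpy(float)])
        from scipy import optimize
        obj = lambda t: -dense_reml_loglik(y.to_numpy(), X, A.values, np.exp(t))
        opt = optimize.minimize_scalar(obj, bounds=(np.log(1e-6), np.log(1e6)),
                                       method="bounded", options={"xatol": 1e-8})
        delta = np.exp(opt.x)
        H = A.values + delta * np.eye(50)
        Hi = np.linalg.inv(H)
        xhx = X.T @ Hi @ X
        beta = np.linalg.solve(xhx, X.T @ Hi @ y.to_numpy())
        resid = y.to_numpy() - X @ beta
        sigma = float(resid @ Hi @ resid) / 48
        se = np.sqrt(sigma * np.linalg.inv(xhx)[1, 1])
        assert r.beta == pytest.approx(beta[1], rel=1e-6)
        assert r.se == pytest.approx(se, rel=1e-6)


class TestLimitsAndInvariances:
    def test_sigma_a2_zero_equals_ols_exactly(self, fixture50):
        import statsmodels.api as sm

        ped, geno, A, pheno = fixture50
        y = pheno["protein_yield"]
        x = geno.iloc[:, 2].to_numpy(float)
        res = PedigreeMixedLM(y, x[:, None], A, exog_names=["snp"]).fit_fixed(0.0)
        ols = sm.OLS(y.to_numpy(), sm.add_constant(x)).fit()
        assert res.params["snp"] == pytest.approx(ols.params[1], rel=1e-10)
        assert res.bse["snp"] == pytest.approx(ols.bse[1], rel=1e-10)

    def test_monomorphic_snp_flagged_and_excluded(self, fixture50):
        ped, geno, A, pheno = fixture50
        y = pheno["milk_yield"]
        r = snp_test(y, pd.Series(np.ones(50), index=y.index, name="mono"), A)
        assert r.is_monomorphic and np.isnan(r.p_value)

    def test_missing_genotypes_drop_animals(self, fixture50):
        ped, geno, A, pheno = fixture50
        y = pheno["milk_yield"]
        x = geno.iloc[:, 3].astype(float).copy()
        x.iloc[[1, 5, 9]] = np.nan
        r = snp_test(y, x, A, mode="exact")
        assert r.n_used == 47
        assert np.isfinite(r.p_value)

    def test_scaling_y_scales_components_not_delta_or_p(self, fixture50):
        ped, geno, A, pheno = fixture50
        y = pheno["fat_yield"]
        vc1 = estimate_variance_components(y, A)
        vc2 = estimate_variance_components(y * 3, A)
        assert vc2.sigma_a2 == pytest.approx(9 * vc1.sigma_a2, rel=1e-4)
        assert vc2.sigma_e2 == pytest.approx(9 * vc1.sigma_e2, rel=1e-4)
        assert vc2.delta == pytest.approx(vc1.delta, rel=1e-3)
        x = geno.iloc[:, 6]
        p1 = snp_test(y, x, A, mode="exact").p_value
        p2 = snp_test(y * 3 + 11.0, x, A, mode="exact").p_value
        assert p1 == pytest.approx(p2, abs=1e-6)

    def test_allele_flip_negates_beta_keeps_p(self, fixture50):
        ped, geno, A, pheno = fixture50
        y = pheno["fertility"]
        x = geno.iloc[:, 8]
        r1 = snp_test(y, x, A, mode="exact")
        r2 = snp_test(y, 2 - x, A, mode="exact")
        assert r2.beta == pytest.approx(-r1.beta, rel=1e-6)
        assert r2.p_value == pytest.approx(r1.p_value, abs=1e-6)

    def test_modes_agree_for_typical_null_snps(self):
        cfg = SimulationConfig(n_founders=60, n_generations=4, n_animals=300,
                               n_chromosomes=3, chrom_length_bp=10_000_000,
                               n_snps=200, n_genes=5, seed=21)
        ped = generate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        A = build_A(ped)
        pheno = simulate_traits(ped, geno, A, cfg)
        ex = association_scan(pheno[["milk_yield"]], geno, A, mode="exact")
        nr = association_scan(pheno[["milk_yield"]], geno, A, mode="null-reuse")
        d = (ex.p_value - nr.p_value).abs().dropna()
        # typical agreement is tight; per-SNP REML noise leaves a small tail
        assert d.median() <= 0.01
        same_call = ((ex.p_value <= 0.05) == (nr.p_value <= 0.05)).mean()
        assert same_call >= 0.95


class TestVarianceComponents:
    def test_zero_heritability_recovered(self):
        h2 = []
        for seed in range(5):
            cfg = SimulationConfig(n_founders=80, n_generations=4, n_animals=400,
                                   n_chromosomes=1, n_snps=10, n_genes=1,
                                   sigma_a2=0.0, sigma_e2=1.0, seed=seed)
            ped = generate_pedigree(cfg)
            geno, _ = simulate_genotypes(ped, cfg)
            A = build_A(ped)
            y = simulate_traits(ped, geno, A, cfg)["milk_yield"]
            h2.append(estimate_variance_components(y, A).h2)
        assert np.mean(h2) < 0.1

    def test_results_summary_prints_components(self, fixture50):
        ped, geno, A, pheno = fixture50
        res = PedigreeMixedLM(pheno["milk_yield"], None, A).fit()
        text = res.summary()
        assert "sigma_a2" in text and "REML" in text


class TestQtlCorrection:
    def test_zero_effect_or_zero_genotype_leaves_y_unchanged(self, fixture50):
        ped, geno, A, pheno = fixture50
        y = pheno["fat_pct"]
        g = geno.iloc[:, 0]
        assert correct_phenotype_for_qtl(y, g, 0.0).equals(y + 0.0)
        zeros = pd.Series(0.0, index=y.index)
        assert np.allclose(correct_phenotype_for_qtl(y, zeros, 1.3), y)

    def test_missing_qtl_genotype_warns_and_sets_missing(self, fixture50):
        ped, geno, A, pheno = fixture50
        y = pheno["fat_pct"]
        g = geno.iloc[:, 0].astype(float).copy()
        g.iloc[0] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            yc = correct_phenotype_for_qtl(y, g, 0.5)
        assert np.isnan(yc.iloc[0]) and np.isfinite(yc.iloc[1:]).all()

    def test_correcting_with_estimated_effect_removes_the_signal(self):
        cfg = SimulationConfig(n_founders=80, n_generations=4, n_animals=500,
                               n_chromosomes=1, chrom_length_bp=5_000_000,
                               n_snps=50, n_genes=2, seed=33,
                               qtl_snp="SNP000025",
                               qtl_effect_sizes=np.array([0.8, 0, 0, 0, 0, 0]))
        ped = generate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        A = build_A(ped)
        pheno = simulate_traits(ped, geno, A, cfg)
        y = pheno["protein_pct"]
        g = geno["SNP000025"]
        before = snp_test(y, g, A, mode="exact")
        assert before.p_value < 1e-6  # the QTL is very visible
        corrected = correct_phenotype_for_qtl(y, g, before.beta)
        after = snp_test(corrected, g, A, mode="exact")
        assert abs(after.beta) < 2 * after.se
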