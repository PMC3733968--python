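"""The synthetic data generator: pedigrees, LD genotypes, correlated traits."""

import numpy as np
import pandas as pd
import pytest

from pathsetassoc import build_A, estimate_variance_components
from pathsetassoc.simulate import (ConfigurationError, SimulationConfig,
                                   embed_pathway_effects, generate_genes,
                                   generate_pedigree, simulate_genotypes,
                                   simulate_traits, write_dataset)

from oracles import gene_drop_alleles, gene_drop_inbreeding


def small_cfg(**kw):
    base = dict(n_founders=20, n_generations=3, n_animals=80, n_chromosomes=2,
                chrom_length_bp=5_000_000, n_snps=120, n_genes=10, seed=3)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(maf_range=(0.0, 0.5)), dict(maf_range=(0.1, 0.6)),
        dict(sigma_a2=-0.1), dict(ld_decay_rho=1.0),
        dict(n_snps=1, n_chromosomes=2), dict(n_animals=10, n_founders=20),
        dict(n_founders=1, n_generations=3),
        dict(genetic_corr=np.full((6, 6), 0.99) + 0.5 * np.eye(6)),
    ])
    def test_invalid_settings_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            small_cfg(**kw)

    def test_asymmetric_correlation_rejected(self):
        R = np.eye(6)
        R[0, 1] = 0.5
        with pytest.raises(ConfigurationError):
            small_cfg(genetic_corr=R)


class TestPedigreeGeneration:
    def test_single_generation_is_all_founders(self):
        p = generate_pedigree(small_cfg(n_generations=1, n_animals=20))
        assert p.is_founder.all()

    def test_same_seed_reproduces_pedigree(self):
        p1 = generate_pedigree(small_cfg(seed=7))
        p2 = generate_pedigree(small_cfg(seed=7))
        assert p1.ids == p2.ids
        assert np.array_equal(p1.sire, p2.sire) and np.array_equal(p1.dam, p2.dam)

    def test_parents_precede_offspring(self):
        p = generate_pedigree(small_cfg())
        assert np.all(p.sire < np.arange(p.n)) and np.all(p.dam < np.arange(p.n))

    def test_unknown_parent_probability(self):
        p = generate_pedigree(small_cfg(unknown_parent_prob=1.0))
        assert p.is_founder.all()

    def test_mean_inbreeding_matches_gene_drop_oracle(self, rng):
        cfg = SimulationConfig(n_founders=10, n_generations=4, n_animals=70,
                               n_chromosomes=1, n_snps=10, n_genes=1, seed=5)
        p = generate_pedigree(cfg)
        A = build_A(p)
        alleles = gene_drop_alleles(p, 10_000, rng)
        f_mc, f_se = gene_drop_inbreeding(alleles)
        mean_se = np.sqrt(np.sum(f_se**2)) / p.n  # conservative for the mean
        assert abs(A.inbreeding.mean() - f_mc.mean()) < max(3 * mean_se, 3e-3)


class TestGenotypes:
    def test_values_and_animals(self, demo_data):
        g = demo_data["genotypes"]
        assert set(np.unique(g.to_numpy())) <= {0, 1, 2}
        assert list(g.index) == demo_data["pedigree"].ids

    def test_snpmap_positions_strictly_increasing_per_chromosome(self, demo_data):
        for _, sub in demo_data["snpmap"].groupby("chrom"):
            assert (np.diff(sub["pos"]) > 0).all()
            assert sub["pos"].min() >= 1

    def test_same_seed_bit_identical(self):
        cfg = small_cfg(seed=9)
        p = generate_pedigree(cfg)
        g1, m1 = simulate_genotypes(p, cfg)
        g2, m2 = simulate_genotypes(p, cfg)
        assert g1.equals(g2) and m1.equals(m2)

    def test_zero_ld_gives_independent_adjacent_founder_snps(self):
        cfg = SimulationConfig(n_founders=400, n_generations=1, n_animals=400,
                               n_chromosomes=1, chrom_length_bp=10_000_000,
                               n_snps=60, n_genes=1, ld_decay_rho=0.0, seed=2)
        p = generate_pedigree(cfg)
        g, _ = simulate_genotypes(p, cfg)
        X = g.to_numpy(float)
        rs = [np.corrcoef(X[:, j], X[:, j + 1])[0, 1] for j in range(X.shape[1] - 1)]
        assert abs(np.mean(rs)) < 3 / np.sqrt(2 * cfg.n_founders)

    def test_positive_ld_parameter_induces_adjacent_correlation(self):
        cfg = SimulationConfig(n_founders=400, n_generations=1, n_animals=400,
                               n_chromosomes=1, chrom_length_bp=10_000_000,
                               n_snps=60, n_genes=1, ld_decay_rho=0.95, seed=2)
        g, _ = simulate_genotypes(generate_pedigree(cfg), cfg)
        X = g.to_numpy(float)
        rs = [np.corrcoef(X[:, j], X[:, j + 1])[0, 1] for j in range(X.shape[1] - 1)]
        assert np.mean(rs) > 0.3

    def test_fixed_maf_half_single_snp_mean_near_one(self):
        cfg = SimulationConfig(n_founders=1500, n_generations=1, n_animals=1500,
                               n_chromosomes=1, chrom_length_bp=1_000_000,
                               n_snps=1, n_genes=1, maf_range=(0.5, 0.5), seed=4)
        g, _ = simulate_genotypes(generate_pedigree(cfg), cfg)
        assert abs(g.to_numpy().mean() - 1.0) < 3 * np.sqrt(0.5 / 1500)

    def test_parent_offspring_correlation_near_half(self):
        cfg = SimulationConfig(n_founders=60, n_generations=2, n_animals=260,
                               n_chromosomes=2, chrom_length_bp=5_000_000,
                               n_snps=400, n_genes=1, ld_decay_rho=0.0, seed=6)
        p = generate_pedigree(cfg)
        g, _ = simulate_genotypes(p, cfg)
        X = g.to_numpy(float)
        # standardise per SNP (GRM-style) so allele-frequency spread across
        # markers does not inflate the between-animal covariance
        freq = X.mean(axis=0) / 2
        Z = (X - 2 * freq) / np.sqrt(2 * freq * (1 - freq))
        rs = []
        for i in np.flatnonzero(~p.is_founder):
            for parent in (p.sire[i], p.dam[i]):
                if parent >= 0:
                    rs.append(np.mean(Z[i] * Z[parent]))
        # Mendelian transmission: expected standardised relationship 1/2
        assert abs(np.mean(rs) - 0.5) < 0.06


class TestTraits:
    def test_degenerate_all_zero_variance_returns_the_mean(self, ):
        cfg = small_cfg(sigma_a2=0.0, sigma_e2=0.0, trait_means=[5.0] * 6)
        p = generate_pedigree(cfg)
        g, _ = simulate_genotypes(p, cfg)
        y = simulate_traits(p, g, build_A(p), cfg)
        assert np.allclose(y.to_numpy(), 5.0)

    def test_pure_residual_limit(self):
        cfg = SimulationConfig(n_founders=100, n_generations=3, n_animals=600,
                               n_chromosomes=1, n_snps=10, n_genes=1,
                               sigma_a2=0.0, sigma_e2=1.0, seed=8)
        p = generate_pedigree(cfg)
        g, _ = simulate_genotypes(p, cfg)
        A = build_A(p)
        y = simulate_traits(p, g, A, cfg)
        v = y.var(axis=0)
        assert np.all((v > 0.8) & (v < 1.25))
        # no polygenic signal: related animals no more alike than unrelated
        iu = np.triu_indices(p.n, k=1)
        rel = A.values[iu]
        y0 = y.iloc[:, 0].to_numpy()
        prod = np.outer(y0 - y0.mean(), y0 - y0.mean())[iu]
        assert abs(np.corrcoef(rel, prod)[0, 1]) < 0.05

    def test_same_seed_bit_identical_traits(self, demo_data):
        cfg = demo_data["config"]
        y1 = simulate_traits(demo_data["pedigree"], demo_data["genotypes"], demo_data["A"], cfg)
        y2 = simulate_traits(demo_data["pedigree"], demo_data["genotypes"], demo_data["A"], cfg)
        assert y1.equals(y2)

    def test_singular_genetic_corr_falls_back_with_warning(self):
        R = np.ones((2, 2))  # perfectly correlated traits
        cfg = small_cfg(n_traits=2, genetic_corr=R, sigma_a2=[0.5, 0.5],
                        sigma_e2=[0.01, 0.01])
        p = generate_pedigree(cfg)
        g, _ = simulate_genotypes(p, cfg)
        with pytest.warns(UserWarning, match="clipped"):
            y = simulate_traits(p, g, build_A(p), cfg)
        assert np.corrcoef(y.iloc[:, 0], y.iloc[:, 1])[0, 1] > 0.9

    def test_effect_snp_must_exist(self):
        cfg = small_cfg()
        cfg.pathway_effect_sizes = {"NOPE": np.ones(6)}
        p = generate_pedigree(cfg)
        g, _ = simulate_genotypes(p, cfg)
        with pytest.raises(ConfigurationError, match="NOPE"):
            simulate_traits(p, g, build_A(p), cfg)

    def test_genetic_correlation_transmits_to_polygenic_values(self):
        cfg = SimulationConfig(n_founders=500, n_generations=1, n_animals=500,
                               n_chromosomes=1, n_snps=10, n_genes=1, n_traits=2,
                               genetic_corr=np.array([[1.0, 0.9], [0.9, 1.0]]),
                               sigma_a2=1.0, sigma_e2=0.001, seed=12)
        p = generate_pedigree(cfg)
        g, _ = simulate_genotypes(p, cfg)
        y = simulate_traits(p, g, build_A(p), cfg)
        assert np.corrcoef(y.iloc[:, 0], y.iloc[:, 1])[0, 1] > 0.8


class TestEmbeddedEffects:
    def test_requested_variance_fraction_realised(self, demo_data):
        genes = demo_data["genes"][:5]
        eff = embed_pathway_effects(genes, demo_data["snpmap"], demo_data["genotypes"],
                                    0.10, seed=1, n_traits=6)
        assert eff
        var = sum(demo_data["genotypes"][s].to_numpy(float).var() * np.asarray(b)[0] ** 2
                  for s, b in eff.items())
        total = var + 1.0  # baseline sigma_a2 + sigma_e2 = 1
        assert var / total == pytest.approx(0.10, abs=0.01)


class TestDatasetWriting:
    def test_roundtrip_files(self, tmp_path, demo_data):
        from pathsetassoc.io import read_genotypes_tsv, read_phenotypes_tsv
        from pathsetassoc.windows import read_genes_tsv, read_genes_bed, read_snpmap_tsv
        from pathsetassoc import Pedigree

        paths = write_dataset(tmp_path, demo_data["pedigree"], demo_data["genotypes"],
                              demo_data["snpmap"], demo_data["genes"],
                              demo_data["phenotypes"], demo_data["config"],
                              A=demo_data["A"])
        assert Pedigree.read_tsv(paths["pedigree"]).ids == demo_data["pedigree"].ids
        g = read_genotypes_tsv(paths["genotypes"])
        assert np.array_equal(g.to_numpy(), demo_data["genotypes"].to_numpy())
        assert read_snpmap_tsv(paths["snpmap"]).equals(demo_data["snpmap"])
        tsv_genes = read_genes_tsv(paths["genes"])
        bed_genes = read_genes_bed(paths["genes_bed"])
        assert tsv_genes == demo_data["genes"]
        assert bed_genes == demo_data["genes"]  # BED 0-based half-open converts back
        ph = read_phenotypes_tsv(paths["phenotypes"])
        assert np.allclose(ph.to_numpy(), demo_data["phenotypes"].to_numpy())
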