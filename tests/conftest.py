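import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from pathsetassoc import build_A
from pathsetassoc.simulate import (SimulationConfig, generate_genes,
                                   generate_pedigree, simulate_genotypes,
                                   simulate_traits)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_config():
    """A small but structured panel reused by most integration-level tests."""
    return SimulationConfig(
        n_founders=40, n_generations=4, n_animals=250, n_chromosomes=3,
        chrom_length_bp=10_000_000, n_snps=600, n_genes=40,
        gene_length_range=(5_000, 50_000), seed=11,
    )


@pytest.fixture(scope="session")
def demo_data(demo_config):
    ped = generate_pedigree(demo_config)
    genes = generate_genes(demo_config)
    geno, snpmap = simulate_genotypes(ped, demo_config)
    A = build_A(ped)
    pheno = simulate_traits(ped, geno, A, demo_config)
    return dict(config=demo_config, pedigree=ped, genes=genes, genotypes=geno,
                snpmap=snpmap, A=A, phenotypes=pheno)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
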