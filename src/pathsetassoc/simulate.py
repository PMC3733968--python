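"""Synthetic pedigree, genotype, annotation and trait generator.

Emulates the statistical structure of a progeny-tested dairy bull panel:
a multi-generation pedigree, a genome-wide medium-density SNP panel with
local linkage disequilibrium, a gene annotation to sample windows from,
and several genetically correlated traits composed of a pedigree polygenic
term and iid residual, optionally with true per-allele SNP effects placed
inside candidate-pathway gene windows and one large-effect QTL.

Default configuration
---------------------
The defaults mirror the target data set: 2,154 genotyped bulls in an
8-generation pedigree, 43,115 SNPs over 29 autosomes, 23,022 annotated
genes, and six traits (protein %, protein yield, fertility, fat %, fat
yield, milk yield) with unit phenotypic variance, heritability 0.3 each and
a realistic dairy genetic-correlation structure. Trait records play the
role of daughter trait deviations: one pre-corrected record per bull, so
the residual is iid and the design matrix linking records to animals is
the identity.

Model components
----------------
* **Pedigree** — discrete generations; each non-founder draws a sire from
  the males and a dam from the females of earlier generations.
* **Genotypes** — founder haplotypes follow a latent Gaussian AR(1) chain
  along each chromosome (parameter ``ld_decay_rho``) thresholded at the
  per-SNP allele frequency (drawn from ``maf_range``), giving local LD
  that decays with marker distance; descendants receive gametes by
  Mendelian transmission with one uniformly placed crossover per
  chromosome per meiosis.
* **Traits** — ``y_t = mu_t + sum_j x_j beta_jt + u_t + e_t`` with
  ``vec(u)`` drawn from the Kronecker covariance (trait genetic covariance)
  ⊗ A and independent residuals.

All randomness flows from ``SimulationConfig.seed`` through fixed named
substreams, so the same seed reproduces every output bit for bit and
adding one stage never perturbs another.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree, NumeratorRelationshipMatrix, build_A
from .windows import GeneAnnotation, build_windows, assign_snps, DEFAULT_FLANK

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "generate_pedigree",
    "generate_genes",
    "simulate_genotypes",
    "simulate_traits",
    "embed_pathway_effects",
    "write_dataset",
]

TRAIT_NAMES = ["protein_pct", "protein_yield", "fertility", "fat_pct", "fat_yield", "milk_yield"]

# Realistic dairy-trait genetic correlation structure (milk volume strongly
# positive with protein yield, negative with the percentage traits); checked
# positive definite.
DEFAULT_GENETIC_CORR = np.array([
    [1.000, 0.126, -0.116, 0.571, 0.195, -0.421],
    [0.126, 1.000, 0.244, -0.419, 0.538, 0.845],
    [-0.116, 0.244, 1.000, -0.121, 0.210, 0.286],
    [0.571, -0.419, -0.121, 1.000, 0.397, -0.692],
    [0.195, 0.538, 0.210, 0.397, 1.000, 0.383],
    [-0.421, 0.845, 0.286, -0.692, 0.383, 1.000],
])

_STREAMS = {"pedigree": 0, "genotypes": 1, "traits": 2, "genes": 3, "effects": 4}


class ConfigurationError(ValueError):
    """Raised for impossible or inconsistent simulation settings."""


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stage],)))


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the target bull panel."""

    n_founders: int = 200
    n_generations: int = 8
    n_animals: int = 2154
    n_chromosomes: int = 29
    chrom_length_bp: int = 90_000_000
    n_snps: int = 43_115
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay_rho: float = 0.9
    n_genes: int = 23_022
    gene_length_range: tuple[int, int] = (2_000, 100_000)
    n_traits: int = 6
    trait_names: list[str] = field(default_factory=lambda: list(TRAIT_NAMES))
    trait_means: np.ndarray | None = None
    sigma_a2: np.ndarray | float = 0.3
    sigma_e2: np.ndarray | float = 0.7
    genetic_corr: np.ndarray | None = None
    pathway_gene_ids: list[str] = field(default_factory=list)
    pathway_effect_sizes: dict[str, np.ndarray] = field(default_factory=dict)
    qtl_snp: str | None = None
    qtl_effect_sizes: np.ndarray | None = None
    unknown_parent_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_traits != len(self.trait_names):
            self.trait_names = [f"trait{t+1}" for t in range(self.n_traits)]
        self.trait_means = (np.zeros(self.n_traits) if self.trait_means is None
                            else np.asarray(self.trait_means, dtype=float))
        self.sigma_a2 = np.broadcast_to(np.asarray(self.sigma_a2, dtype=float),
                                        (self.n_traits,)).copy()
        self.sigma_e2 = np.broadcast_to(np.asarray(self.sigma_e2, dtype=float),
                                        (self.n_traits,)).copy()
        if self.genetic_corr is None:
            self.genetic_corr = (DEFAULT_GENETIC_CORR[: self.n_traits, : self.n_traits]
                                 if self.n_traits <= 6 else np.eye(self.n_traits))
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)

        if self.trait_means.shape != (self.n_traits,):
            raise ConfigurationError("trait_means length must equal n_traits")
        if np.any(self.sigma_a2 < 0) or np.any(self.sigma_e2 < 0):
            raise ConfigurationError("variance components must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_decay_rho < 1):
            raise ConfigurationError("ld_decay_rho must be in [0, 1)")
        R = self.genetic_corr
        if R.shape != (self.n_traits, self.n_traits):
            raise ConfigurationError("genetic_corr must be n_traits x n_traits")
        if not np.allclose(R, R.T, atol=1e-10) or not np.allclose(np.diag(R), 1.0):
            raise ConfigurationError("genetic_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ConfigurationError("genetic_corr must be positive semi-definite")
        if self.n_snps < self.n_chromosomes:
            raise ConfigurationError("n_snps must be at least n_chromosomes")
        if self.n_founders < 1 or self.n_generations < 1:
            raise ConfigurationError("need at least one founder and one generation")
        if self.n_generations > 1 and self.n_founders < 2:
            raise ConfigurationError("multi-generation pedigrees need >= 2 founders")
        if self.n_animals < self.n_founders:
            raise ConfigurationError("n_animals must be >= n_founders")
        if not (0 <= self.unknown_parent_prob <= 1):
            raise ConfigurationError("unknown_parent_prob must be a probability")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def to_jsonable(self) -> dict:
        out = asdict(self)
        for k, v in out.items():
            if isinstance(v, np.ndarray):
                out[k] = v.tolist()
        out["pathway_effect_sizes"] = {
            k: np.asarray(v).tolist() for k, v in self.pathway_effect_sizes.items()
        }
        return out


def generate_pedigree(config: SimulationConfig) -> Pedigree:
    """Discrete-generation pedigree with parents drawn from earlier generations.

    Founders form generation 0; the remaining animals are split as evenly
    as possible over generations 1..n_generations-1. Each animal is
    assigned a sex at birth (the founder cohort always contains both);
    every non-founder draws its sire uniformly from earlier males and its
    dam from earlier females, with each link independently set unknown
    with probability ``unknown_parent_prob``. Ids come out in generation
    order, hence topologically sorted.
    """
    rng = _rng(config.seed, "pedigree")
    n_off = config.n_animals - config.n_founders
    if config.n_generations == 1:
        if n_off:
            raise ConfigurationError("one generation implies n_animals == n_founders")
        sizes = [config.n_founders]
    else:
        per = n_off // (config.n_generations - 1)
        sizes = [config.n_founders] + [per] * (config.n_generations - 1)
        sizes[-1] += n_off - per * (config.n_generations - 1)

    ids = [f"A{k:05d}" for k in range(config.n_animals)]
    sex = rng.integers(0, 2, size=config.n_animals)  # 0 = male, 1 = female
    if config.n_founders >= 2:
        sex[0], sex[1] = 0, 1  # guarantee both sexes among founders
    sire = np.full(config.n_animals, -1, dtype=np.int64)
    dam = np.full(config.n_animals, -1, dtype=np.int64)

    start = config.n_founders
    for g in range(1, len(sizes)):
        prev = np.arange(start)  # all earlier generations
        males = prev[sex[:start] == 0]
        females = prev[sex[:start] == 1]
        if males.size == 0 or females.size == 0:
            raise ConfigurationError("no candidate parents of one sex; impossible mating structure")
        stop = start + sizes[g]
        sire[start:stop] = rng.choice(males, size=sizes[g])
        dam[start:stop] = rng.choice(females, size=sizes[g])
        if config.unknown_parent_prob > 0:
            drop_s = rng.random(sizes[g]) < config.unknown_parent_prob
            drop_d = rng.random(sizes[g]) < config.unknown_parent_prob
            sire[start:stop][drop_s] = -1
            dam[start:stop][drop_d] = -1
        start = stop
    return Pedigree(ids, sire, dam)


def generate_genes(config: SimulationConfig) -> list[GeneAnnotation]:
    """Uniformly placed gene annotations, sorted by coordinate."""
    rng = _rng(config.seed, "genes")
    lo, hi = config.gene_length_range
    chrom = rng.integers(1, config.n_chromosomes + 1, size=config.n_genes)
    length = rng.integers(lo, hi + 1, size=config.n_genes)
    start = rng.integers(1, np.maximum(config.chrom_length_bp - length, 1) + 1)
    order = np.lexsort((start, chrom))
    return [
        GeneAnnotation(f"G{k:05d}", str(chrom[i]), int(start[i]), int(start[i] + length[i] - 1))
        for k, i in enumerate(order)
    ]


def _founder_haplotypes(rng, n_hap, freqs, rho):
    """Binary haplotypes from a thresholded latent Gaussian AR(1) chain."""
    m = freqs.size
    z = rng.standard_normal((n_hap, m))
    x = np.empty_like(z)
    x[:, 0] = z[:, 0]
    scale = np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        x[:, j] = rho * x[:, j - 1] + scale * z[:, j]
    return (x < stats.norm.ppf(freqs)).astype(np.int8)


def simulate_genotypes(pedigree: Pedigree, config: SimulationConfig):
    """Genotypes (animals x SNPs allele counts) and a SNP map.

    Returns ``(genotypes, snpmap)``: a DataFrame of 0/1/2 counts of the
    "1" allele indexed by animal id, and a map with strictly increasing
    1-based positions per chromosome. See the module docstring for the
    founder-LD and transmission models.
    """
    rng = _rng(config.seed, "genotypes")
    per_chrom = [len(a) for a in np.array_split(np.arange(config.n_snps), config.n_chromosomes)]

    chroms, positions = [], []
    for c, m in enumerate(per_chrom, start=1):
        # distinct 1-based positions: oversample, deduplicate, subsample
        pos = np.unique(rng.integers(1, config.chrom_length_bp + 1, size=m + max(10, m // 10)))
        while pos.size < m:
            extra = rng.integers(1, config.chrom_length_bp + 1, size=m)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.permutation(pos)[:m])
        chroms.append(np.full(m, c))
        positions.append(pos)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions)
    snp_ids = [f"SNP{k:06d}" for k in range(config.n_snps)]
    snpmap = pd.DataFrame({"snp_id": snp_ids, "chrom": chrom_arr.astype(str), "pos": pos_arr})

    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    bounds = np.concatenate([[0], np.cumsum(per_chrom)])

    n = pedigree.n
    hap = np.zeros((n, 2, config.n_snps), dtype=np.int8)
    founders = np.flatnonzero(pedigree.is_founder)
    # animals with one known parent transmit a random population haplotype
    # for the unknown side, drawn like a founder's
    for c in range(config.n_chromosomes):
        a, b = bounds[c], bounds[c + 1]
        fh = _founder_haplotypes(rng, 2 * founders.size, freqs[a:b], config.ld_decay_rho)
        hap[founders, 0, a:b] = fh[0::2]
        hap[founders, 1, a:b] = fh[1::2]

    chrom_pos = [pos_arr[bounds[c]:bounds[c + 1]] for c in range(config.n_chromosomes)]
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s < 0 and d < 0:
            continue
        for which, parent in ((0, s), (1, d)):
            if parent < 0:
                for c in range(config.n_chromosomes):
                    a, b = bounds[c], bounds[c + 1]
                    hap[i, which, a:b] = _founder_haplotypes(
                        rng, 1, freqs[a:b], config.ld_decay_rho
                    )[0]
                continue
            for c in range(config.n_chromosomes):
                a, b = bounds[c], bounds[c + 1]
                xover = rng.integers(1, config.chrom_length_bp + 1)
                k = int(np.searchsorted(chrom_pos[c], xover))
                first = rng.integers(0, 2)
                hap[i, which, a:a + k] = hap[parent, first, a:a + k]
                hap[i, which, a + k:b] = hap[parent, 1 - first, a + k:b]

    geno = pd.DataFrame(hap.sum(axis=1), index=pedigree.ids, columns=snp_ids, dtype=np.int8)
    return geno, snpmap


def simulate_traits(pedigree: Pedigree, genotypes: pd.DataFrame,
                    A: NumeratorRelationshipMatrix, config: SimulationConfig) -> pd.DataFrame:
    """Correlated polygenic traits: ``y_t = mu_t + sum_j x_j beta_jt + u_t + e_t``.

    ``vec(u)`` has the Kronecker covariance (D R D) ⊗ A with D =
    diag(sigma_a) and R the genetic correlation matrix; residuals are
    independent N(0, sigma_e2_t). One record per pedigree animal.
    """
    rng = _rng(config.seed, "traits")
    A_use = A.reindex(pedigree.ids) if list(A.ids) != list(pedigree.ids) else A
    n, t = pedigree.n, config.n_traits

    sd_a = np.sqrt(config.sigma_a2)
    G = sd_a[:, None] * config.genetic_corr * sd_a[None, :]
    if not G.any():
        LG = np.zeros_like(G)  # no polygenic variance at all
    else:
        try:
            LG = np.linalg.cholesky(G)
        except np.linalg.LinAlgError:
            warnings.warn("singular genetic covariance; using eigenvalue-clipped factor",
                          stacklevel=2)
            w, V = np.linalg.eigh(G)
            LG = V * np.sqrt(np.clip(w, 0.0, None))
    try:
        LA = np.linalg.cholesky(A_use.values)
    except np.linalg.LinAlgError:
        LA = np.linalg.cholesky(A_use.values + 1e-8 * np.eye(n))

    u = LA @ rng.standard_normal((n, t)) @ LG.T
    e = rng.standard_normal((n, t)) * np.sqrt(config.sigma_e2)[None, :]
    y = config.trait_means[None, :] + u + e

    effects = dict(config.pathway_effect_sizes)
    if config.qtl_snp is not None:
        if config.qtl_effect_sizes is not None:
            qtl_beta = config.qtl_effect_sizes
        elif t == 6:
            # large-effect milk-fat QTL analogue on unit-variance traits:
            # raises fat %, depresses milk volume
            qtl_beta = np.array([0.15, -0.10, 0.0, 0.40, 0.25, -0.30])
        else:
            raise ConfigurationError("qtl_effect_sizes required when qtl_snp is set "
                                     "and the trait panel is not the 6-trait default")
        effects[config.qtl_snp] = np.asarray(qtl_beta, dtype=float) + np.asarray(
            effects.get(config.qtl_snp, np.zeros(t)), dtype=float
        )
    for snp_id, beta in effects.items():
        if snp_id not in genotypes.columns:
            raise ConfigurationError(f"effect SNP {snp_id!r} absent from the genotype table")
        x = genotypes[snp_id].loc[pedigree.ids].to_numpy(dtype=float)
        y += x[:, None] * np.broadcast_to(np.asarray(beta, dtype=float), (t,))[None, :]

    return pd.DataFrame(y, index=pedigree.ids, columns=config.trait_names)


def embed_pathway_effects(pathway_genes, snpmap: pd.DataFrame, genotypes: pd.DataFrame,
                          variance_fraction: float, seed: int,
                          flank: int = DEFAULT_FLANK, n_causal_per_gene: int = 1,
                          traits=None, n_traits: int = 6,
                          baseline_variance: float = 1.0) -> dict[str, np.ndarray]:
    """Choose causal SNPs inside pathway gene windows and scale their effects.

    Picks ``n_causal_per_gene`` SNPs per flanked gene window (without
    replacement within a window; a SNP shared by overlapping windows is
    used once) and assigns equal-magnitude, random-sign per-allele effects
    such that the summed genic variance — using the realised genotype
    variance of each chosen SNP — makes up ``variance_fraction`` of the
    total trait variance ``baseline_variance / (1 - variance_fraction)``.

    Returns a ``pathway_effect_sizes`` mapping for :class:`SimulationConfig`;
    ``traits`` selects which trait columns receive the effect (default all).
    """
    if not (0 < variance_fraction < 1):
        raise ValueError("variance_fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS["effects"],)))
    windows = build_windows(pathway_genes, flank)
    chosen: list[str] = []
    for w in windows:
        inside = assign_snps([w], snpmap).snp_ids
        inside = [s for s in inside if s not in chosen]
        if not inside:
            continue
        take = min(n_causal_per_gene, len(inside))
        chosen.extend(rng.choice(np.array(inside), size=take, replace=False).tolist())
    if not chosen:
        raise ValueError("no SNPs available inside the pathway windows")

    var_x = genotypes[chosen].to_numpy(dtype=float).var(axis=0, ddof=0)
    var_x = np.maximum(var_x, 1e-12)
    target = variance_fraction * baseline_variance / (1.0 - variance_fraction)
    beta_mag = np.sqrt(target / var_x.sum())
    trait_mask = np.zeros(n_traits)
    if traits is None:
        trait_mask[:] = 1.0
    else:
        for t in traits:
            trait_mask[t] = 1.0
    return {
        s: float(beta_mag * rng.choice([-1.0, 1.0])) * trait_mask
        for s in chosen
    }


def write_dataset(out_dir, pedigree: Pedigree, genotypes: pd.DataFrame,
                  snpmap: pd.DataFrame, genes, phenotypes: pd.DataFrame,
                  config: SimulationConfig, A: NumeratorRelationshipMatrix | None = None,
                  vcf: bool = False) -> dict[str, Path]:
    """Write the full synthetic data set as plain-text files.

    Emits pedigree/genotype/map/annotation/phenotype TSVs, a BED version
    of the annotation (0-based half-open), a truth JSON with the
    generating parameters, and optionally an uncompressed VCF.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out / "pedigree.tsv",
        "genotypes": out / "genotypes.tsv",
        "snpmap": out / "snpmap.tsv",
        "genes": out / "genes.tsv",
        "genes_bed": out / "genes.bed",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.json",
    }
    pedigree.write_tsv(paths["pedigree"])
    genotypes.to_csv(paths["genotypes"], sep="\t", index_label="animal_id")
    snpmap.to_csv(paths["snpmap"], sep="\t", index=False)
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.stop) for g in genes],
        columns=["gene_id", "chrom", "start", "stop"],
    ).to_csv(paths["genes"], sep="\t", index=False)
    with open(paths["genes_bed"], "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.stop}\t{g.gene_id}\n")
    phenotypes.to_csv(paths["phenotypes"], sep="\t", index_label="animal_id")
    with open(paths["truth"], "w") as fh:
        json.dump(config.to_jsonable(), fh, indent=1, sort_keys=True)
    if A is not None:
        paths["A"] = out / "A.tsv"
        A.write_tsv(paths["A"])
    if vcf:
        from .io import write_vcf

        paths["vcf"] = out / "genotypes.vcf"
        write_vcf(paths["vcf"], genotypes, snpmap)
    return paths
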