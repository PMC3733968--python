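"""End-to-end pipeline: simulate → kinship → windows → scan → set test → pleiotropy.

One call produces, in a run directory:

* the synthetic data set (pedigree, genotypes, map, annotation, phenotypes,
  truth JSON) and its relationship matrix;
* the genome-wide per-SNP association table;
* per-trait pathway set-test JSONs, null-distribution TSVs and histogram
  figures with the observed proportion drawn as a vertical line;
* a per-gene significant-SNP count table with a deduplicated totals row,
  an m*P/S FDR table, pathway and genome effect-correlation matrices with
  their paired-t comparison;
* a machine-readable ``summary.json`` and a plain-text log with stage
  timings and the permutation redraw count.

All randomness flows from one root seed through named substreams, so
re-running the same configuration reproduces every number exactly and
changing the replicate count never perturbs the simulated data.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geneset import PathwaySetTest, fdr, proportion_significant
from .mixed_model import association_scan, correct_phenotype_for_qtl
from .pedigree import build_A
from .pleiotropy import effect_correlations, paired_t_compare
from .simulate import (SimulationConfig, embed_pathway_effects, generate_genes,
                       generate_pedigree, simulate_genotypes, simulate_traits,
                       write_dataset)
from .windows import assign_snps, build_windows, write_windows_tsv

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("pathsetassoc")


@dataclass
class RunConfig:
    """Flat configuration of a full synthetic-study run."""

    out_dir: str = "run"
    seed: int = 1
    # simulation scale
    n_animals: int = 300
    n_founders: int = 40
    n_generations: int = 4
    n_chromosomes: int = 5
    chrom_length_bp: int = 20_000_000
    n_snps: int = 2000
    n_genes: int = 60
    n_traits: int = 6
    ld_decay_rho: float = 0.9
    sigma_a2: float = 0.3
    sigma_e2: float = 0.7
    # analysis settings
    flank: int = 500_000
    alpha: float = 0.05
    n_reps: int = 500
    n_pathway_genes: int = 11
    vc_mode: str = "exact"
    traits: list[str] | None = None
    # optional true signal / QTL handling
    pathway_variance_fraction: float = 0.0
    use_qtl: bool = False
    correct_qtl: bool = False
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage_seed(root: int, key: int) -> int:
    """A derived 31-bit stage seed from the root seed."""
    return int(np.random.SeedSequence(entropy=root, spawn_key=(key,)).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole synthetic study; returns the summary dictionary."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings: dict[str, float] = {}

    def tick(stage: str) -> None:
        timings[stage] = time.perf_counter() - t0

    try:
        log.info("pathsetassoc %s, root seed %d", __version__, config.seed)

        # --- simulate -------------------------------------------------
        sim = SimulationConfig(
            n_founders=config.n_founders, n_generations=config.n_generations,
            n_animals=config.n_animals, n_chromosomes=config.n_chromosomes,
            chrom_length_bp=config.chrom_length_bp, n_snps=config.n_snps,
            ld_decay_rho=config.ld_decay_rho, n_genes=config.n_genes,
            n_traits=config.n_traits, sigma_a2=config.sigma_a2,
            sigma_e2=config.sigma_e2, seed=config.seed,
        )
        pedigree = generate_pedigree(sim)
        genes = generate_genes(sim)
        genotypes, snpmap = simulate_genotypes(pedigree, sim)
        A = build_A(pedigree)

        pick_rng = np.random.default_rng(_stage_seed(config.seed, 10))
        pathway_idx = np.sort(pick_rng.choice(len(genes), size=config.n_pathway_genes,
                                              replace=False))
        pathway = [genes[i] for i in pathway_idx]
        if config.pathway_variance_fraction > 0:
            sim.pathway_effect_sizes = embed_pathway_effects(
                pathway, snpmap, genotypes, config.pathway_variance_fraction,
                seed=config.seed, flank=config.flank, n_traits=config.n_traits,
                baseline_variance=float(np.mean(sim.sigma_a2 + sim.sigma_e2)),
            )
            sim.pathway_gene_ids = [g.gene_id for g in pathway]
        if config.use_qtl:
            # park the large-effect QTL inside the first pathway window
            qtl_candidates = assign_snps(build_windows(pathway[:1], config.flank), snpmap)
            if len(qtl_candidates):
                sim.qtl_snp = qtl_candidates.snp_ids[len(qtl_candidates) // 2]
        phenotypes = simulate_traits(pedigree, genotypes, A, sim)
        write_dataset(out / "data", pedigree, genotypes, snpmap, genes, phenotypes, sim, A=A)
        log.info("simulated %d animals, %d SNPs, %d genes; pathway: %s",
                 pedigree.n, len(snpmap), len(genes), ",".join(g.gene_id for g in pathway))
        tick("simulate")

        # --- windows --------------------------------------------------
        windows = build_windows(pathway, config.flank)
        write_windows_tsv(windows, out / "pathway_windows.tsv")
        snp_set = assign_snps(windows, snpmap)
        snp_set.write_tsv(out / "pathway_snpset.tsv")
        log.info("pathway windows hold %d unique SNPs", len(snp_set))
        tick("windows")

        # --- association scan ----------------------------------------
        traits = config.traits or list(phenotypes.columns)
        assoc = association_scan(phenotypes[traits], genotypes, A, snpmap=snpmap,
                                 mode=config.vc_mode)
        assoc.to_csv(out / "assoc.tsv", sep="\t", index=False)
        tick("scan")

        if config.correct_qtl and sim.qtl_snp is not None:
            g = genotypes[sim.qtl_snp]
            corrected = {}
            for t in traits:
                b = assoc.loc[(assoc.snp_id == sim.qtl_snp) & (assoc.trait == t), "beta"].iloc[0]
                corrected[t] = correct_phenotype_for_qtl(phenotypes[t], g, b)
            phenos_corr = pd.DataFrame(corrected).dropna()
            assoc_corr = association_scan(
                phenos_corr, genotypes.loc[phenos_corr.index],
                A.reindex(list(phenos_corr.index)), snpmap=snpmap, mode=config.vc_mode)
            assoc_corr.to_csv(out / "assoc_qtl_corrected.tsv", sep="\t", index=False)
            log.info("QTL-corrected scan done (QTL SNP %s)", sim.qtl_snp)
            tick("scan_qtl_corrected")

        # --- set tests per trait --------------------------------------
        set_results = {}
        per_gene = pd.DataFrame(index=[g.gene_id for g in pathway])
        per_gene["n_snps"] = pd.Series(snp_set.per_gene_counts)
        fdr_rows = []
        for k, t in enumerate(traits):
            pv = assoc.loc[assoc.trait == t].set_index("snp_id")["p_value"]
            test = PathwaySetTest(pv, snpmap, pathway, genes, flank=config.flank,
                                  alpha=config.alpha, trait=t)
            res = test.fit(n_reps=config.n_reps, seed=_stage_seed(config.seed, 100 + k))
            set_results[t] = res
            np.savetxt(out / f"null_{t}.tsv", res.null_proportions, fmt="%.6g")
            with open(out / f"set_test_{t}.json", "w") as fh:
                json.dump(res.to_dict(), fh, indent=1, sort_keys=True)
            if config.make_plots:
                import matplotlib
                matplotlib.use("Agg")
                import matplotlib.pyplot as plt
                ax = res.plot_null()
                ax.figure.savefig(out / f"null_{t}.png", dpi=120,
                                  bbox_inches="tight")
                plt.close(ax.figure)
            # per-gene significant counts (windows counted separately)
            counts = {}
            sig_ids = set(pv.index[(pv <= config.alpha).fillna(False)])
            for w, gene in zip(build_windows(pathway, config.flank), pathway):
                in_win = assign_snps([w], snpmap).snp_ids
                counts[gene.gene_id] = sum(s in sig_ids for s in in_win)
            per_gene[t] = pd.Series(counts)
            fdr_res = fdr(res.n_snps_tested, config.alpha, res.n_significant)
            fdr_rows.append({"trait": t, "fdr_raw_percent": fdr_res.raw_percent,
                             "fdr_percent": fdr_res.percent})
            log.info("%s: f=%.3f experiment-wise P=%.4f (redrawn %d)",
                     t, res.proportion_significant, res.experimentwise_p, res.n_redrawn)
        tick("set_tests")

        # totals row: deduplicated set-level counts, computed independently
        totals = {"n_snps": len(snp_set)}
        for t in traits:
            pv = assoc.loc[assoc.trait == t].set_index("snp_id")["p_value"]
            n_sig, _ = proportion_significant(pv.reindex(snp_set.snp_ids).dropna(), config.alpha)
            totals[t] = n_sig
        table1 = pd.concat([per_gene, pd.DataFrame([totals], index=["Total"])])
        table1.to_csv(out / "table_per_gene_counts.tsv", sep="\t", index_label="gene_id")
        pd.DataFrame(fdr_rows).to_csv(out / "table_fdr.tsv", sep="\t", index=False)

        # --- pleiotropy (needs at least one trait pair) ---------------
        tt = None
        if len(traits) >= 2:
            betas = assoc.pivot(index="snp_id", columns="trait", values="beta")[traits]
            pvals = assoc.pivot(index="snp_id", columns="trait", values="p_value")[traits]
            in_set = betas.index.isin(snp_set.snp_ids)
            corr_path = effect_correlations(betas[in_set].dropna(), pvalues=pvals[in_set].dropna())
            corr_genome = effect_correlations(betas.dropna(), pvalues=pvals.dropna())
            corr_path.values.to_csv(out / "corr_pathway.tsv", sep="\t")
            corr_genome.values.to_csv(out / "corr_genome.tsv", sep="\t")
            tt = paired_t_compare(corr_path, corr_genome)
        tick("pleiotropy")

        summary = {
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "n_animals": pedigree.n,
            "n_snps": len(snpmap),
            "pathway_genes": [g.gene_id for g in pathway],
            "pathway_n_snps": len(snp_set),
            "per_gene_counts": {c: table1[c].to_dict() for c in table1.columns},
            "set_tests": {t: r.to_dict() for t, r in set_results.items()},
            "fdr": {r["trait"]: r["fdr_percent"] for r in fdr_rows},
            "pleiotropy_paired_t": (None if tt is None else
                                    {"statistic": tt.statistic, "pvalue": tt.pvalue,
                                     "n_pairs": tt.n_pairs}),
            "qtl_snp": sim.qtl_snp,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        for stage, t_ in timings.items():
            log.info("stage %s finished at %.2f s", stage, t_)
        log.info("pipeline complete in %.2f s", time.perf_counter() - t0)
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
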