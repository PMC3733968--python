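"""Gene windows and SNP-set assignment.

A candidate-pathway SNP set is formed by flanking each gene of the pathway
(here, by default, 500 kb on either side — roughly the extent of useful
linkage disequilibrium in Holstein-Friesian cattle at 50k chip density) and
collecting every mapped SNP that falls inside any flanked window.

Coordinates are 1-based with inclusive ends throughout; BED input is
converted on read (0-based half-open start +1). Windows are clamped at
position 1 on the left and never merged: overlapping windows each count
their SNPs for per-gene reporting, while the set-level SNP list is
deduplicated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "GeneWindow",
    "SnpSet",
    "build_windows",
    "assign_snps",
    "read_genes_tsv",
    "read_genes_bed",
    "read_snpmap_tsv",
]

DEFAULT_FLANK = 500_000


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene (or merged multi-gene locus): 1-based inclusive bounds."""

    gene_id: str
    chrom: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"gene {self.gene_id!r}: empty chromosome label")
        if self.start > self.stop:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > stop {self.stop}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id!r}: 1-based start must be >= 1")


@dataclass(frozen=True)
class GeneWindow:
    """A flanked gene region; win_start is clamped at 1."""

    gene_id: str
    chrom: str
    win_start: int
    win_stop: int


@dataclass
class SnpSet:
    """Deduplicated SNP ids of a window set, plus per-gene (window) counts.

    ``snp_ids`` lists each SNP once, ordered by genomic position, even when
    it falls in several overlapping windows; ``per_gene_counts`` counts it
    for every window that contains it, so ``sum(per_gene_counts.values())``
    can exceed ``len(snp_ids)``.
    """

    snp_ids: list[str]
    per_gene_counts: dict[str, int]
    gene_ids_by_snp: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "gene_ids": [",".join(self.gene_ids_by_snp.get(s, [])) for s in self.snp_ids],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_windows(genes, flank: int = DEFAULT_FLANK) -> list[GeneWindow]:
    """Flank each gene by ``flank`` bp on both sides, clamping at position 1.

    Windows are returned one per gene, in input order; overlapping windows
    are kept as-is (no merging), matching per-gene reporting downstream.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    return [
        GeneWindow(g.gene_id, g.chrom, max(1, g.start - flank), g.stop + flank)
        for g in genes
    ]


def assign_snps(windows, snpmap: pd.DataFrame) -> SnpSet:
    """Assign mapped SNPs to gene windows (same chromosome, inclusive bounds).

    Parameters
    ----------
    windows : list of GeneWindow
    snpmap : DataFrame with columns snp_id, chrom, pos (1-based)

    A SNP lying in several windows appears once in ``snp_ids`` but is
    counted in every window's ``per_gene_counts`` entry. Chromosome labels
    present in the windows but absent from the map (or vice versa) trigger
    a warning listing them, since that usually signals an assembly or
    naming mismatch.
    """
    snpmap = snpmap.reset_index(drop=True)
    win_chroms = {w.chrom for w in windows}
    map_chroms = set(snpmap["chrom"].astype(str)) if len(snpmap) else set()
    unmatched = win_chroms - map_chroms
    if unmatched and len(snpmap):
        warnings.warn(
            "window chromosomes absent from the SNP map: " + ", ".join(sorted(unmatched)),
            stacklevel=2,
        )

    chrom = snpmap["chrom"].astype(str).to_numpy() if len(snpmap) else np.array([], dtype=str)
    pos = snpmap["pos"].to_numpy(dtype=np.int64) if len(snpmap) else np.array([], dtype=np.int64)
    snp_id = snpmap["snp_id"].astype(str).to_numpy() if len(snpmap) else np.array([], dtype=str)

    per_gene_counts: dict[str, int] = {}
    genes_by_snp: dict[str, list[str]] = {}
    hit_any = np.zeros(len(snpmap), dtype=bool)
    for w in windows:
        inside = (chrom == w.chrom) & (pos >= w.win_start) & (pos <= w.win_stop)
        per_gene_counts[w.gene_id] = per_gene_counts.get(w.gene_id, 0) + int(inside.sum())
        hit_any |= inside
        for s in snp_id[inside]:
            genes_by_snp.setdefault(s, []).append(w.gene_id)

    # order by genomic coordinate so the result is invariant to map row order
    hit_idx = np.flatnonzero(hit_any)
    order = hit_idx[np.lexsort((pos[hit_idx], chrom[hit_idx]))]
    return SnpSet(list(snp_id[order]), per_gene_counts, genes_by_snp)


def read_genes_tsv(path) -> list[GeneAnnotation]:
    """Gene annotation TSV: gene_id, chrom, start, stop (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return [
        GeneAnnotation(r.gene_id, r.chrom, int(r.start), int(r.stop))
        for r in df.itertuples(index=False)
    ]


def read_genes_bed(path) -> list[GeneAnnotation]:
    """BED gene annotation (0-based half-open): converted to 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    return [
        GeneAnnotation(str(r[3]), str(r[0]), int(r[1]) + 1, int(r[2]))
        for _, r in df.iterrows()
    ]


def read_snpmap_tsv(path) -> pd.DataFrame:
    """SNP map TSV: snp_id, chrom, pos (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    df["pos"] = df["pos"].astype(np.int64)
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id in map: {dup!r}")
    if (df["pos"] < 1).any():
        raise ValueError("SNP positions must be >= 1 (1-based)")
    return df[["snp_id", "chrom", "pos"]]


def write_windows_tsv(windows, path) -> None:
    pd.DataFrame(
        [(w.gene_id, w.chrom, w.win_start, w.win_stop) for w in windows],
        columns=["gene_id", "chrom", "win_start", "win_stop"],
    ).to_csv(path, sep="\t", index=False)
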