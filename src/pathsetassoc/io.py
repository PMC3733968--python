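"""Readers and writers for the tabular interchange formats.

Everything is plain text: TSVs for pedigree, genotypes, SNP map, gene
annotation and phenotypes (see the per-module readers), plus an optional
uncompressed VCF round-trip for the genotype matrix (written with pysam,
read with cyvcf2; both imported lazily so the core package has no
VCF dependency).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_genotypes_tsv",
    "read_phenotypes_tsv",
    "write_vcf",
    "read_genotypes_vcf",
]


def read_genotypes_tsv(path) -> pd.DataFrame:
    """Genotype TSV: rows = animals (column ``animal_id``), columns = SNP ids."""
    df = pd.read_csv(path, sep="\t", index_col="animal_id")
    df.index = df.index.astype(str)
    return df


def read_phenotypes_tsv(path) -> pd.DataFrame:
    """Phenotype TSV: ``animal_id`` plus one numeric column per trait."""
    df = pd.read_csv(path, sep="\t", index_col="animal_id")
    df.index = df.index.astype(str)
    return df


def write_vcf(path, genotypes: pd.DataFrame, snpmap: pd.DataFrame) -> None:
    """Write allele counts as an uncompressed diploid VCF.

    The counted ("1") allele is emitted as ALT, so the dosage of ALT in
    the VCF equals the stored 0/1/2 count. Allele labels are placeholders
    (REF=A, ALT=C); the map supplies CHROM/POS/ID.
    """
    import pysam

    header = pysam.VariantHeader()
    for chrom in pd.unique(snpmap["chrom"].astype(str)):
        sub = snpmap[snpmap["chrom"].astype(str) == chrom]
        header.contigs.add(chrom, length=int(sub["pos"].max()) + 1)
    header.formats.add("GT", 1, "String", "Genotype")
    samples = [str(a) for a in genotypes.index]
    for s in samples:
        header.add_sample(s)

    counts = genotypes.to_numpy()
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, row in enumerate(snpmap.itertuples(index=False)):
            rec = vcf.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1, stop=int(row.pos),
                id=str(row.snp_id), alleles=("A", "C"),
            )
            col = counts[:, j]
            for k, s in enumerate(samples):
                c = int(col[k])
                rec.samples[s]["GT"] = (0, 0) if c == 0 else ((0, 1) if c == 1 else (1, 1))
            vcf.write(rec)


def read_genotypes_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a biallelic VCF into (genotypes, snpmap): counts of the ALT allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids, chroms, poss = [], [], [], []
    for var in vcf:
        gts = np.asarray(var.genotypes, dtype=object)
        counts = np.array([int(g[0]) + int(g[1]) for g in gts], dtype=np.int8)
        rows.append(counts)
        ids.append(var.ID)
        chroms.append(var.CHROM)
        poss.append(var.POS)
    geno = pd.DataFrame(np.column_stack(rows) if rows else np.empty((len(samples), 0)),
                        index=samples, columns=ids, dtype=np.int8)
    snpmap = pd.DataFrame({"snp_id": ids, "chrom": [str(c) for c in chroms], "pos": poss})
    return geno, snpmap
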