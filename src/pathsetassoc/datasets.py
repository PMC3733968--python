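"""Published summary data for the RNASE5 candidate pathway in Holstein cattle.

A genome scan of 2,154 progeny-tested Holstein-Friesian bulls at 43,115
quality-controlled 50k-chip SNPs tested an 11-gene candidate pathway
centred on RNASE5 (angiogenin) against six daughter-trait-deviation
phenotypes. Each gene was flanked by 500 kb, giving windows of roughly
1 Mb that together contain 211 SNPs; per-window significant-SNP counts at
P <= 0.05 were reported per trait. These summary tables are bundled here
as worked inputs for the set-level arithmetic — proportion-significant
f-values, m*P/S false discovery rates, and effect-correlation comparisons
— without any access to the underlying animal-level data.

Gene coordinates are not restated independently of the windows; gene
bodies are recovered as window minus flank, which is exact wherever the
window was not clamped at the chromosome start.
"""

from __future__ import annotations

from io import StringIO

import numpy as np
import pandas as pd

from .windows import GeneAnnotation

__all__ = [
    "N_BULLS",
    "N_GENOME_SNPS",
    "PATHWAY_FLANK",
    "ALPHA",
    "TRAITS",
    "pathway_window_table",
    "pathway_genes",
    "pathway_correlations",
    "genome_correlations",
]

N_BULLS = 2154
N_GENOME_SNPS = 43_115
PATHWAY_FLANK = 500_000
ALPHA = 0.05

TRAITS = ["protein_yield", "protein_pct", "fertility", "fat_yield", "fat_pct", "milk_yield"]

# 11 flanked gene windows of the RNASE5 pathway: chromosome, window bounds
# (1-based inclusive), SNPs in the window, and significant-SNP counts per
# trait at P <= 0.05. RNASE4/5 is a single merged locus (shared promoter).
_WINDOW_TABLE = """\
gene_id	chrom	win_start	win_stop	n_snps	protein_yield	protein_pct	fertility	fat_yield	fat_pct	milk_yield
ACTA2	26	10578865	11592811	26	7	0	5	6	2	6
ACTN2	28	7393500	8441168	16	2	0	0	1	2	2
FBLN1	5	122206254	123286509	22	4	10	5	0	0	3
FSLP3	7	41906484	42911309	20	3	9	1	2	0	0
FST	20	26797134	27802564	13	2	8	0	1	4	1
HIF1A	10	75457880	76502552	17	1	1	2	0	0	3
PLEC2	14	190799	1212951	16	16	15	3	15	16	16
RFX7	10	54530392	55670964	25	2	2	0	0	1	0
RNASE4/5	10	25298775	26315348	23	5	0	0	1	0	4
RPL22L1	1	98326431	99330809	17	4	5	2	1	0	1
SP140	2	121890759	122935785	16	2	7	0	0	2	4
"""


def pathway_window_table() -> pd.DataFrame:
    """Per-gene windows with SNP counts and per-trait significant counts."""
    df = pd.read_csv(StringIO(_WINDOW_TABLE), sep="\t", dtype={"chrom": str})
    return df


def pathway_genes(flank: int = PATHWAY_FLANK) -> list[GeneAnnotation]:
    """Gene bodies recovered from the published windows (window minus flank)."""
    rows = pathway_window_table()
    return [
        GeneAnnotation(r.gene_id, r.chrom, int(r.win_start) + flank, int(r.win_stop) - flank)
        for r in rows.itertuples(index=False)
    ]


def _corr(text: str) -> pd.DataFrame:
    df = pd.read_csv(StringIO(text), sep="\t", index_col=0)
    full = df.to_numpy(dtype=float)
    iu = np.triu_indices_from(full, k=1)
    full[iu] = full.T[iu]
    return pd.DataFrame(full, index=df.index, columns=df.columns)


_PATHWAY_CORR = """\
trait	protein_pct	protein_yield	fertility	fat_pct	fat_yield	milk_yield
protein_pct	1.000
protein_yield	-0.352	1.000
fertility	-0.056	0.215	1.000
fat_pct	0.763	-0.761	-0.018	1.000
fat_yield	0.615	-0.356	0.212	0.838	1.000
milk_yield	-0.720	0.902	0.184	-0.915	-0.549	1.000
"""

_GENOME_CORR = """\
trait	protein_pct	protein_yield	fertility	fat_pct	fat_yield	milk_yield
protein_pct	1.000
protein_yield	0.126	1.000
fertility	-0.116	0.244	1.000
fat_pct	0.571	-0.419	-0.121	1.000
fat_yield	0.195	0.538	0.210	0.397	1.000
milk_yield	-0.421	0.845	0.286	-0.692	0.383	1.000
"""


def pathway_correlations() -> pd.DataFrame:
    """Reported SNP-effect correlations within the pathway set (N = 211)."""
    return _corr(_PATHWAY_CORR)


def genome_correlations() -> pd.DataFrame:
    """Reported SNP-effect correlations over the whole genome (N = 43,115)."""
    return _corr(_GENOME_CORR)
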