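"""Pleiotropy via correlations of per-SNP effect estimates across traits.

If many variants in a SNP set influence several traits, the per-SNP effect
estimates for those traits are correlated; the pairwise Pearson correlation
matrix of estimated allele effects is therefore a cheap proxy for shared
genetic control. Two such matrices — one for a candidate pathway set, one
for the whole genome — can be compared with a paired t-test over the
unique trait pairs to ask whether the pathway shows systematically more
(or less) pleiotropy than a random background.

Selection rules: ``all`` uses every common SNP; ``significant-any`` keeps,
per trait pair, SNPs significant in at least one of the two traits;
``significant-both`` requires both.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EffectCorrelationMatrix", "effect_correlations", "paired_t_compare", "PairedTResult"]

SELECTION_RULES = ("all", "significant-any", "significant-both")


@dataclass
class EffectCorrelationMatrix:
    """Trait-by-trait Pearson correlations of per-SNP effect estimates.

    ``values`` and ``counts`` are DataFrames over the trait panel; a pair
    with fewer than 3 selected SNPs is flagged missing (NaN) and its count
    kept for inspection.
    """

    trait_names: list[str]
    values: pd.DataFrame
    counts: pd.DataFrame
    selection_rule: str
    alpha: float | None = None

    @property
    def n_snps(self) -> int:
        """SNPs in the common set (the 'all' denominator)."""
        return int(self.counts.to_numpy().max())

    def off_diagonal(self) -> pd.Series:
        """The unique off-diagonal entries, indexed by trait pair."""
        pairs = list(combinations(self.trait_names, 2))
        if not pairs:
            return pd.Series([], dtype=float, name="r")
        return pd.Series(
            [self.values.loc[a, b] for a, b in pairs],
            index=pd.MultiIndex.from_tuples(pairs),
            name="r",
        )


def effect_correlations(betas: pd.DataFrame, pvalues: pd.DataFrame | None = None,
                        selection_rule: str = "all",
                        alpha: float = 0.05) -> EffectCorrelationMatrix:
    """Pairwise Pearson correlations of per-SNP effects between traits.

    Parameters
    ----------
    betas : DataFrame, SNPs x traits, of estimated per-allele effects over
        a common SNP set.
    pvalues : matching DataFrame of per-SNP p-values; required for the
        significance-based selection rules.
    selection_rule : "all" | "significant-any" | "significant-both",
        applied per trait pair.
    """
    if selection_rule not in SELECTION_RULES:
        raise ValueError(f"selection_rule must be one of {SELECTION_RULES}")
    if selection_rule != "all" and pvalues is None:
        raise ValueError("p-values are required for significance-based selection")
    traits = list(betas.columns)
    if len(betas) < 3:
        raise ValueError("need at least 3 SNPs")

    vals = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    counts = pd.DataFrame(0, index=traits, columns=traits, dtype=int)
    finite = np.isfinite(betas.to_numpy()).all(axis=1)
    for a, b in combinations(traits, 2):
        keep = finite.copy()
        if selection_rule == "significant-any":
            keep &= (pvalues[a].to_numpy() <= alpha) | (pvalues[b].to_numpy() <= alpha)
        elif selection_rule == "significant-both":
            keep &= (pvalues[a].to_numpy() <= alpha) & (pvalues[b].to_numpy() <= alpha)
        counts.loc[a, b] = counts.loc[b, a] = int(keep.sum())
        if keep.sum() < 3:
            vals.loc[a, b] = vals.loc[b, a] = np.nan
            continue
        r = stats.pearsonr(betas.loc[keep, a], betas.loc[keep, b]).statistic
        vals.loc[a, b] = vals.loc[b, a] = r
    for t in traits:
        counts.loc[t, t] = int(finite.sum())
    return EffectCorrelationMatrix(traits, vals, counts, selection_rule,
                                   alpha if selection_rule != "all" else None)


@dataclass(frozen=True)
class PairedTResult:
    statistic: float
    pvalue: float
    n_pairs: int


def paired_t_compare(corr_a: EffectCorrelationMatrix,
                     corr_b: EffectCorrelationMatrix,
                     fisher_z: bool = False) -> PairedTResult:
    """Paired t-test on the unique off-diagonal correlations of two matrices.

    For a 6-trait panel this is a t with 14 df over the 15 trait pairs.
    ``fisher_z`` applies atanh to both sets first (off by default). All-zero
    differences give t = 0, p = 1 by convention.
    """
    if corr_a.trait_names != corr_b.trait_names:
        raise ValueError("trait panels differ between the two correlation matrices")
    ra = corr_a.off_diagonal().to_numpy(dtype=float)
    rb = corr_b.off_diagonal().to_numpy(dtype=float)
    keep = np.isfinite(ra) & np.isfinite(rb)
    ra, rb = ra[keep], rb[keep]
    if np.allclose(ra, rb):
        return PairedTResult(0.0, 1.0, int(ra.size))
    if ra.size < 2:
        raise ValueError("fewer than 2 complete trait pairs")
    if fisher_z:
        ra, rb = np.arctanh(ra), np.arctanh(rb)
    t = stats.ttest_rel(ra, rb)
    return PairedTResult(float(t.statistic), float(t.pvalue), int(ra.size))
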