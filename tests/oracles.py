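"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different computational route from the
code under test: gene-dropping Monte Carlo and Wright-style path counting
for expected relationships, dense explicit-inverse GLS/REML formulas for
the mixed model, and exhaustive enumeration for the permutation null.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# ---------------------------------------------------------------- gene drop

def gene_drop_alleles(pedigree, n_drops: int, rng) -> np.ndarray:
    """Drop unique founder alleles through the pedigree ``n_drops`` times.

    Returns an (n_drops, n_animals, 2) array of allele identities; each
    unknown-parent slot founds a fresh allele lineage.
    """
    n = pedigree.n
    alleles = np.empty((n_drops, n, 2), dtype=np.int64)
    drops = np.arange(n_drops)
    next_allele = 0
    for i in range(n):
        for slot, parent in ((0, pedigree.sire[i]), (1, pedigree.dam[i])):
            if parent < 0:
                alleles[:, i, slot] = next_allele
                next_allele += 1
            else:
                pick = rng.integers(0, 2, size=n_drops)
                alleles[:, i, slot] = alleles[drops, parent, pick]
    return alleles


def gene_drop_relationship(alleles: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """Monte-Carlo additive relationship a_ij and its standard error.

    a_ij = 2 * kinship = half the mean number of IBD allele pairs among
    the four cross-comparisons; a_ii = 1 + P(the two alleles of i are IBD).
    """
    if i == j:
        ind = (alleles[:, i, 0] == alleles[:, i, 1]).astype(float)
        return 1.0 + ind.mean(), ind.std(ddof=1) / np.sqrt(ind.size)
    ind = np.zeros(alleles.shape[0])
    for k in range(2):
        for l in range(2):
            ind += (alleles[:, i, k] == alleles[:, j, l])
    ind *= 0.5
    return ind.mean(), ind.std(ddof=1) / np.sqrt(ind.size)


def gene_drop_inbreeding(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal Monte-Carlo inbreeding coefficients and standard errors."""
    ind = (alleles[:, :, 0] == alleles[:, :, 1]).astype(float)
    return ind.mean(axis=0), ind.std(axis=0, ddof=1) / np.sqrt(ind.shape[0])


# ----------------------------------------------------- Wright path counting

def wright_relationship_matrix(pedigree) -> np.ndarray:
    """Expected relationships by enumerating ascending path pairs.

    a_ij sums (1/2)^(n1+n2) (1 + F_A) over common ancestors A and pairs of
    ascending paths i->A, j->A sharing no animal but A; F_i is half the
    numerator of i's parents. Exponential in pedigree size — fixture
    pedigrees only.
    """
    n = pedigree.n
    parents = [[p for p in (pedigree.sire[i], pedigree.dam[i]) if p >= 0] for i in range(n)]

    paths_cache: dict[int, list[tuple[int, ...]]] = {}

    def ascending_paths(i: int) -> list[tuple[int, ...]]:
        if i not in paths_cache:
            out = [(i,)]
            for p in parents[i]:
                out.extend((i,) + q for q in ascending_paths(p))
            paths_cache[i] = out
        return paths_cache[i]

    F = np.zeros(n)

    def numerator(i: int, j: int) -> float:
        if i == j:
            return 1.0 + F[i]
        total = 0.0
        for p1 in ascending_paths(i):
            for p2 in ascending_paths(j):
                if p1[-1] == p2[-1] and len(set(p1) & set(p2)) == 1:
                    total += 0.5 ** (len(p1) + len(p2) - 2) * (1.0 + F[p1[-1]])
        return total

    a = np.zeros((n, n))
    for i in range(n):  # topological order: F of ancestors known first
        s, d = pedigree.sire[i], pedigree.dam[i]
        F[i] = 0.5 * numerator(s, d) if (s >= 0 and d >= 0) else 0.0
        for j in range(i):
            a[i, j] = a[j, i] = numerator(i, j)
        a[i, i] = 1.0 + F[i]
    return a


# ------------------------------------------------------- dense mixed model

def dense_gls(y, X, V):
    """GLS by explicit inversion: beta, se (V treated as known), F, p."""
    from scipy import stats

    Vi = np.linalg.inv(V)
    xvx = X.T @ Vi @ X
    beta = np.linalg.solve(xvx, X.T @ Vi @ y)
    cov = np.linalg.inv(xvx)
    se = np.sqrt(np.diag(cov))
    f = (beta / se) ** 2
    p = stats.f.sf(f, 1, y.size - X.shape[1])
    return beta, se, f, p


def dense_reml_loglik(y, X, A, delta) -> float:
    """Restricted log-likelihood at variance ratio delta, profiled scale,
    via dense determinants and inverses (no eigendecomposition)."""
    n, p = X.shape
    H = A + delta * np.eye(n)
    Hi = np.linalg.inv(H)
    xhx = X.T @ Hi @ X
    beta = np.linalg.solve(xhx, X.T @ Hi @ y)
    r = y - X @ beta
    sigma = float(r @ Hi @ r) / (n - p)
    _, ld_H = np.linalg.slogdet(H)
    _, ld_xhx = np.linalg.slogdet(xhx)
    _, ld_xtx = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * np.log(2 * np.pi * sigma) + ld_H + ld_xhx - ld_xtx + (n - p))


# --------------------------------------------------- exhaustive enumeration

def enumerate_null_proportions(gene_snp_ids: list[set], sig_ids: set, n_genes: int):
    """Exact distribution of the proportion-significant statistic over all
    gene subsets of size ``n_genes`` (empty SNP sets excluded)."""
    values = []
    for combo in combinations(range(len(gene_snp_ids)), n_genes):
        snps = set().union(*(gene_snp_ids[g] for g in combo))
        if snps:
            values.append(len(snps & sig_ids) / len(snps))
    return np.array(values)


def paired_t_formula(d: np.ndarray):
    """Textbook paired t on differences d: t = mean/(sd/sqrt(k)), df = k-1."""
    from scipy import stats

    k = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(k))
    p = 2 * stats.t.sf(abs(t), k - 1)
    return t, p
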