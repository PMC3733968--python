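# Methods

## Statistical model

For one trait the observation for animal *i* is modelled as

    y_i = mu + x_i * beta + u_i + e_i

with `x_i` the allele count (0/1/2) at the tested SNP, `u ~ N(0, A sigma_a2)`
a polygenic effect whose covariance is the pedigree numerator relationship
matrix **A**, and `e ~ N(0, I sigma_e2)`. One record per animal is assumed
(the design matrix linking records to animals is the identity): for
progeny-tested bulls the record is a daughter trait deviation, a
pre-corrected average of daughter performances, so fixed effects such as
herd-year-season are already absorbed and the residual is treated as iid.
Repeated records per animal are out of scope.

**A** is built by the tabular recurrence (`a_ii = 1 + a(s,d)/2`,
`a_ij = (a(j,s_i) + a(j,d_i))/2`, unknown-parent terms zero) after a
topological sort of the pedigree; unknown parents are accepted and give
founders a diagonal of exactly 1. Storage is dense — at a few thousand
animals neither the inverse nor sparse machinery is needed, and the
genomic relationship matrix is deliberately not offered: the method under
study controls structure through the pedigree.

### REML and the spectral shortcut

Variance components are estimated by REML in the single ratio
`delta = sigma_e2 / sigma_a2`. With `A = U diag(d) U'` computed once per
animal panel, rotating `y` and the fixed design by `U'` makes
`V = sigma_a2 (A + delta I)` diagonal, so one likelihood evaluation costs
O(n) and the whole scan reuses the same decomposition across SNPs and
traits. The restricted likelihood (Patterson–Thompson form, including the
`-log|X'X|` term and all constants) is profiled over `sigma_a2` and
maximised over `log delta` by bounded Brent search on [1e-6, 1e6] with
tolerance 1e-8 in log delta; the boundary candidates `sigma_a2 = 0`
(ordinary least squares) and `delta` at either bound are evaluated
explicitly and win if they score higher.

Two scanning modes:

* **exact** (default) — variance components re-estimated for every SNP
  with the SNP in the fixed design; this is what a per-SNP fit in a
  general-purpose REML package does, and is the default out of fidelity.
* **null-reuse** — components estimated once from the intercept-only
  model and reused for every marker as known (EMMAX-style generalised
  least squares), used where tens of thousands of permutation-scan
  evaluations matter. The two modes typically agree to a few thousandths
  in p-value at a few hundred animals; the per-SNP re-estimation noise
  leaves a small tail of larger differences that shrinks with panel size.

The per-SNP test is the 1-df Wald `F = (beta/se)^2` against
`F(1, n - p)` with `p` fixed effects (the denominator-df convention had
to be chosen; with hundreds of animals the choice is immaterial).
Monomorphic SNPs are flagged and excluded from set statistics rather
than tested; SNPs with missing genotypes are analysed complete-case (the
eigen-shortcut does not survive subsetting, so those markers take a dense
fallback; a mean-imputation path is not offered by default).

### Set statistic, permutation null, FDR

The pathway statistic for a trait is `f = S/m`: the number of set SNPs
with `P <= alpha` (inclusive threshold, alpha = 0.05 by default) over the
set size. Windows are gene body ± 500 kb, 1-based inclusive coordinates,
clamped at position 1, never merged; a SNP in several windows counts once
in the set but once per window in per-gene reporting. BED annotations are
converted on read (+1 on starts). The merged treatment of adjacent,
co-regulated genes (e.g. an RNASE4/RNASE5 locus sharing promoters) is
supported simply by letting an annotation row span both genes.

The permutation null draws gene sets of the pathway's size uniformly
without replacement from the annotated universe, builds the same windows,
deduplicates, and scores `f`. Per-SNP p-values do not depend on set
membership, so they are computed once per trait and reused across
replicates — numerically identical to re-fitting per set and orders of
magnitude cheaper; per-gene SNP membership is likewise resolved once and
replicates are unions of member sets. Replicates whose windows contain no
SNPs are redrawn and counted (the count is logged and reported), with a
hard error once attempts exceed 100× the requested replicates. The
experiment-wise P is the fraction of replicates with `f_null >= f_obs`;
ties count as exceeding, the conservative choice, with a strict `>`
option for the literal reading of "exceeded".

The FDR at threshold P is `m*P/S` — expected false positives among m
true nulls over observed discoveries — expressed as a percent and
truncated toward zero for table display (the raw value is always carried
alongside; truncation, not rounding, is the convention consistent with
the published table this arithmetic reproduces). `S = 0` leaves the rate
undefined rather than infinite.

### Pleiotropy

Pairwise Pearson correlations of per-SNP effect estimates between traits,
over a common SNP set. The default selection rule uses **all** SNPs of
the set: the published comparison reports N equal to the full set sizes,
implying no significance filter despite the surrounding text, so "all" is
the default and `significant-any` / `significant-both` are options.
Pathway and whole-genome correlation sets are compared by a paired t-test
over the unique trait pairs (15 pairs for six traits, df = 14); Fisher's
z transform is available but off by default, matching the published
analysis as far as it is described. Pairs with fewer than 3 selected SNPs
are flagged missing and dropped from the comparison.

## Synthetic data generator

The generator emulates the statistical structure of the motivating data
set; its defaults are the study conditions. 2,154 genotyped bulls in an
8-generation pedigree from 200 founders; 43,115 SNPs over 29 autosomes of
90 Mb; 23,022 annotated genes; six traits with unit phenotypic variance,
heritability 0.3 each, and a dairy-like genetic correlation structure
(milk volume strongly positive with protein yield, negative with the
percentage traits). Tests and the pipeline demo run the same generator at
reduced scale (hundreds of animals, a few thousand SNPs over 5
chromosomes, a 60-gene universe) so the full suite completes in about a
minute; the power study keeps the full 2,154-bull panel because set-level
power at ~5% explained variance genuinely needs it.

Component models, and what they do *not* capture:

* **Pedigree** — discrete generations; each non-founder draws its sire
  from males and its dam from females of all earlier generations
  (overlapping-generation sire use, as in cattle); parent links can be
  set unknown with a configurable probability (default 0 — the real
  pedigree's completeness is unknown). No selection, no assortative
  mating, no realistic family-size distribution.
* **Genotypes** — founder haplotypes from a latent Gaussian AR(1) chain
  (parameter `ld_decay_rho`, default 0.9) thresholded at per-SNP allele
  frequencies drawn from `maf_range` (default 0.05–0.5, mimicking
  post-QC chip data); transmission is Mendelian with exactly one
  uniformly placed crossover per chromosome per meiosis. LD therefore
  decays with marker distance, but there is no mutation, no coalescent
  demography, no genotyping error, and the first-order LD parameter is a
  latent correlation, not a target r². Positions are distinct, 1-based,
  strictly increasing per chromosome.
* **Traits** — `y = mu + X beta + u + e` run generatively: `vec(u)` from
  the Kronecker covariance (trait genetic covariance) ⊗ A via Cholesky
  factors (an eigenvalue-clipped factor with a warning if the trait
  covariance is singular), residuals independent. Daughter trait
  deviations are emulated as single unit-variance records per bull;
  reliability differences between bulls (daughter-group sizes) are not
  modelled. Optional true effects: a per-SNP, per-trait effect map;
  `embed_pathway_effects` places equal-magnitude random-sign effects on
  SNPs inside pathway windows scaled — using realised genotype variances
  — so they jointly explain a requested fraction of trait variance. A
  single large-effect QTL (a DGAT1-like milk-fat locus: raises fat %,
  depresses volume) can be placed on any SNP.

Because generated effects are placed on typed SNPs, a "causal" marker is
its own perfect tag; real pathways are tested through imperfect LD, so
the generator's power at a given explained-variance fraction is an upper
bound on field power. Passing the calibration tests shows the machinery
is statistically sound under the stated generative model, not that any
particular real pathway finding is right.

All randomness descends from one seed through named substreams (pedigree,
genotypes, traits, genes, effects), so a seed reproduces every output
byte-for-byte and enlarging one stage (e.g. more permutation replicates)
never perturbs another.

## Numerical and design choices

* Eigenvalues of **A** are clipped at zero below -1e-6 (rejected as
  non-PSD beyond that); Cholesky of A falls back to a 1e-8 jitter.
* Delta search space [1e-6, 1e6] with explicit boundary fits; the
  sigma_a2 = 0 candidate is evaluated as exact OLS, so that limit is
  reproduced to machine precision.
* Permutation replicates are drawn in batches with a redraw cap of 100×
  the requested replicates; the empirical null is returned raw (no
  smoothing, no +1 correction — the tie-as-exceeding rule already keeps
  the P conservative).
* FDR truncation toward zero after converting to percent (see above).
* Coordinates are 1-based inclusive everywhere internally; BED is the
  only 0-based surface and is converted at the boundary.
* The pipeline writes a deterministic `summary.json` (sorted keys, no
  timestamps); timings live in the log only, so two runs with one seed
  are byte-identical where it is promised.
* The per-run problem sizes used by the test-suite demos (250–300
  animals, 600–2,000 SNPs, 40–60 genes, 120–500 replicates) were chosen
  as the smallest panels at which the calibration statistics are stable;
  the power test uses the full default bull count.

## Known limitations

* Single-trait mixed model only; no multi-trait REML, no BLUP output,
  no genomic relationship matrix, no A-inverse.
* The FDR is the classical expected-false-positive form the method
  reports; no Benjamini–Hochberg or q-value machinery is included.
* Effect-estimate correlations are a proxy for pleiotropy, not bivariate
  genetic correlation estimates.
* The permutation universe treats genes as exchangeable units; gene
  length and SNP density enter only through window content, and no
  matching on gene size is attempted.
* Windows are not clamped at chromosome ends (lengths are often unknown
  in annotation-only inputs); a window may extend past the last SNP,
  which is harmless for membership queries.
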