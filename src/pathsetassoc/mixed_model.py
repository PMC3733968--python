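"""Single-marker linear mixed model with a pedigree polygenic effect.

For one trait the model is

    y = X b + u + e,    u ~ N(0, sigma_a2 * A),    e ~ N(0, sigma_e2 * I)

where ``y`` holds one phenotypic record per animal (for progeny-tested
bulls, a daughter trait deviation), ``X`` is the fixed design (intercept
plus, for an association test, one SNP allele-count column), ``u`` is the
polygenic effect with the pedigree numerator relationship matrix ``A`` as
its covariance structure, and ``e`` is iid residual. Fitting the polygenic
term absorbs family resemblance, so per-SNP tests are controlled for
population structure.

Estimation is REML over the single variance ratio ``delta = sigma_e2 /
sigma_a2``. Writing ``A = U diag(d) U'`` (one symmetric eigendecomposition,
reusable across every SNP and trait), ``V = sigma_a2 (A + delta I)`` is
diagonal in the rotated basis, so each evaluation of the restricted
likelihood costs O(n): the classic spectral trick of EMMA-family mixed-model
association methods. ``delta`` is optimised by bounded Brent search on a log
scale with explicit boundary candidates (``sigma_a2 = 0``, i.e. ordinary
least squares, and ``sigma_e2 -> 0``).

Two scanning modes are offered:

``exact``
    variance components re-estimated for every SNP with the SNP in the
    fixed design — what a per-SNP REML fit in a general mixed-model package
    does, made cheap by the shared eigendecomposition;
``null-reuse``
    variance components estimated once under the no-SNP model and reused
    for every marker (EMMAX-style), trading a little accuracy for speed in
    permutation-heavy workloads.

The per-SNP test is a 1-df Wald F, ``F = (beta/se)^2`` against
``F(1, n - p)`` with ``p`` the number of fixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import NumeratorRelationshipMatrix

__all__ = [
    "VarianceComponents",
    "SnpAssociation",
    "KinshipSpectral",
    "PedigreeMixedLM",
    "PedigreeMixedLMResults",
    "estimate_variance_components",
    "test_snp",
    "association_scan",
    "correct_phenotype_for_qtl",
]

DELTA_BOUNDS = (1e-6, 1e6)
LOG_DELTA_TOL = 1e-8


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components for one trait.

    ``delta = sigma_e2 / sigma_a2`` (``inf`` at the ``sigma_a2 = 0``
    boundary); ``loglik_reml`` is the restricted log-likelihood at the
    optimum, constants included.
    """

    sigma_a2: float
    sigma_e2: float
    loglik_reml: float
    delta: float

    @property
    def h2(self) -> float:
        """Narrow-sense heritability sigma_a2 / (sigma_a2 + sigma_e2)."""
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


@dataclass(frozen=True)
class SnpAssociation:
    """Per-SNP association result for one trait."""

    snp_id: str
    beta: float
    se: float
    f_stat: float
    p_value: float
    n_used: int
    flag: str = ""

    @property
    def is_monomorphic(self) -> bool:
        return self.flag == "monomorphic"


class KinshipSpectral:
    """Cached symmetric eigendecomposition of a relationship matrix.

    Built once per animal panel and shared across traits and SNPs; also
    rotates phenotype and genotype columns into the eigenbasis.
    """

    def __init__(self, kinship, ids=None):
        if isinstance(kinship, NumeratorRelationshipMatrix):
            if ids is not None:
                kinship = kinship.reindex(list(ids))
            self.ids = list(kinship.ids)
            matrix = kinship.values
        else:
            matrix = np.asarray(kinship, dtype=float)
            self.ids = list(ids) if ids is not None else list(range(matrix.shape[0]))
        if matrix.shape[0] != matrix.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(matrix, matrix.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        d, U = np.linalg.eigh(matrix)
        if d.min() < -1e-6:
            raise ValueError(f"kinship matrix is not PSD (min eigenvalue {d.min():.3g})")
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.matrix = matrix

    @property
    def n(self) -> int:
        return self.d.size

    def rotate(self, arr: np.ndarray) -> np.ndarray:
        """U' @ arr for a vector or column-stacked matrix."""
        return self.U.T @ arr


def _profile_reml(w, Xr, yr, logdet_xtx):
    """Profiled restricted log-likelihood pieces at eigenvalue weights ``w``.

    Returns (loglik, beta, xwx_inv, sigma_profiled) where sigma_profiled is
    the REML estimate of the scale in V = sigma * H, H having eigenvalues w.
    """
    n, p = Xr.shape
    Xw = Xr / w[:, None]
    xwx = Xr.T @ Xw
    xwy = Xw.T @ yr
    beta = np.linalg.solve(xwx, xwy)
    resid = yr - Xr @ beta
    rss = float(resid @ (resid / w))
    if rss <= 0:
        rss = np.finfo(float).tiny
    sigma = rss / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(xwx)
    loglik = -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma)
        + np.sum(np.log(w))
        + logdet_xwx
        - logdet_xtx
        + (n - p)
    )
    return loglik, beta, np.linalg.inv(xwx), sigma


class PedigreeMixedLM:
    """Linear mixed model ``y = Xb + u + e`` with polygenic covariance ``A``.

    Parameters
    ----------
    endog : array-like or Series
        Phenotype, one record per animal. A Series index gives animal ids.
    exog : array-like, optional
        Fixed-effect design. Defaults to an intercept; an intercept column
        is prepended when absent.
    kinship : NumeratorRelationshipMatrix, ndarray or KinshipSpectral
        Additive relationship structure, aligned to ``endog``'s animals.
    """

    def __init__(self, endog, exog=None, kinship=None, exog_names=None):
        if kinship is None:
            raise ValueError("kinship (relationship matrix) is required")
        ids = list(endog.index) if isinstance(endog, pd.Series) else None
        y = np.asarray(endog, dtype=float).ravel()
        if not np.all(np.isfinite(y)):
            raise ValueError("phenotype contains non-finite values")

        if exog is None:
            X = np.ones((y.size, 1))
            names = ["intercept"]
        else:
            X = np.atleast_2d(np.asarray(exog, dtype=float))
            if X.shape[0] != y.size:
                X = X.T
            names = list(exog_names) if exog_names else [f"x{j}" for j in range(X.shape[1])]
            if not any(np.ptp(col) == 0 for col in X.T):
                X = np.column_stack([np.ones(y.size), X])
                names = ["intercept"] + names
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        if y.size < 3:
            raise ValueError("at least 3 records are required")

        self.spectral = kinship if isinstance(kinship, KinshipSpectral) else KinshipSpectral(kinship, ids)
        if self.spectral.n != y.size:
            raise ValueError("kinship dimension does not match the number of records")
        if ids is not None and list(self.spectral.ids) != ids:
            raise ValueError("kinship animal order does not match the phenotype index")

        self.endog, self.exog, self.exog_names = y, X, names
        self.ids = ids if ids is not None else list(self.spectral.ids)
        self.nobs, self.k_fe = X.shape
        self._yr = self.spectral.rotate(y)
        self._Xr = self.spectral.rotate(X)
        sign, self._logdet_xtx = np.linalg.slogdet(X.T @ X)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str, kinship, snp=None, covariates=()):
        """Build from a phenotype DataFrame indexed by animal id.

        ``snp`` may name a column of ``data`` or be an aligned Series of
        allele counts; ``covariates`` name further fixed-effect columns.
        """
        y = data[trait]
        cols, names = [], []
        for c in covariates:
            cols.append(data[c].to_numpy(dtype=float))
            names.append(c)
        if snp is not None:
            if isinstance(snp, str):
                cols.append(data[snp].to_numpy(dtype=float))
                names.append(snp)
            else:
                aligned = pd.Series(snp).reindex(data.index)
                cols.append(aligned.to_numpy(dtype=float))
                names.append(getattr(snp, "name", None) or "snp")
        exog = np.column_stack(cols) if cols else None
        return cls(y, exog, kinship, exog_names=names or None)

    def loglike_reml(self, delta: float) -> float:
        """Restricted log-likelihood profiled over sigma_a2, at a given delta."""
        if np.isinf(delta):
            w = np.ones(self.nobs)  # OLS limit: V = sigma_e2 * I
        else:
            w = self.spectral.d + delta
            if w.min() <= 0:
                return -np.inf
        return _profile_reml(w, self._Xr, self._yr, self._logdet_xtx)[0]

    def fit(self, delta_bounds=DELTA_BOUNDS, tol=LOG_DELTA_TOL) -> "PedigreeMixedLMResults":
        """REML fit: bounded Brent search on log(delta) plus boundary candidates."""
        lo, hi = np.log(delta_bounds[0]), np.log(delta_bounds[1])
        res = optimize.minimize_scalar(
            lambda t: -self.loglike_reml(np.exp(t)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol},
        )
        candidates = [np.exp(res.x), delta_bounds[0], delta_bounds[1], np.inf]
        scores = [self.loglike_reml(c) for c in candidates]
        best = int(np.argmax(scores))
        return self._results_at(candidates[best])

    def fit_fixed(self, sigma_a2: float, sigma_e2: float | None = None) -> "PedigreeMixedLMResults":
        """GLS at fixed variance components.

        With ``sigma_a2 = 0`` and ``sigma_e2 = None`` (profiled) this is
        exactly ordinary least squares with the usual residual-variance
        estimate. When both components are given, standard errors use them
        as known quantities.
        """
        if sigma_a2 < 0 or (sigma_e2 is not None and sigma_e2 < 0):
            raise ValueError("variance components must be non-negative")
        if sigma_a2 == 0:
            return self._results_at(np.inf, fixed_sigma=sigma_e2)
        delta = np.inf if sigma_e2 is None else (sigma_e2 / sigma_a2)
        if sigma_e2 is None:
            raise ValueError("sigma_e2 must be given when sigma_a2 > 0")
        return self._results_at(delta, fixed_sigma=sigma_a2)

    def _results_at(self, delta: float, fixed_sigma: float | None = None) -> "PedigreeMixedLMResults":
        w = np.ones(self.nobs) if np.isinf(delta) else self.spectral.d + delta
        loglik, beta, xwx_inv, sigma_prof = _profile_reml(w, self._Xr, self._yr, self._logdet_xtx)
        sigma = sigma_prof if fixed_sigma is None else fixed_sigma
        if np.isinf(delta):
            sigma_a2, sigma_e2 = 0.0, sigma
        else:
            sigma_a2, sigma_e2 = sigma, delta * sigma
        cov = sigma * xwx_inv
        return PedigreeMixedLMResults(self, beta, cov, VarianceComponents(sigma_a2, sigma_e2, loglik, delta))


class PedigreeMixedLMResults:
    """Results of a :class:`PedigreeMixedLM` fit.

    Exposes ``params``, ``bse``, ``fvalues`` (1-df Wald F per coefficient),
    ``pvalues`` against F(1, n - p), the variance components and a
    ``summary()`` table.
    """

    def __init__(self, model, params, cov_params, vc: VarianceComponents):
        self.model = model
        self.params = pd.Series(params, index=model.exog_names)
        self.cov_params = cov_params
        self.vc = vc
        self.nobs = model.nobs
        self.df_resid = model.nobs - model.k_fe

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.model.exog_names)

    @property
    def fvalues(self) -> pd.Series:
        return (self.params / self.bse) ** 2

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            stats.f.sf(self.fvalues, 1, self.df_resid), index=self.model.exog_names
        )

    @property
    def sigma_a2(self) -> float:
        return self.vc.sigma_a2

    @property
    def sigma_e2(self) -> float:
        return self.vc.sigma_e2

    @property
    def h2(self) -> float:
        return self.vc.h2

    @property
    def loglik_reml(self) -> float:
        return self.vc.loglik_reml

    def summary(self) -> str:
        lines = [
            "Pedigree mixed linear model (REML)",
            "=" * 58,
            f"No. records:   {self.nobs:>8d}    sigma_a2: {self.sigma_a2:>10.4f}",
            f"Df resid:      {self.df_resid:>8d}    sigma_e2: {self.sigma_e2:>10.4f}",
            f"REML loglik: {self.loglik_reml:>10.3f}    h2:       {self.h2:>10.4f}",
            "-" * 58,
            f"{'':<14}{'coef':>10}{'se':>10}{'F':>10}{'P>F':>10}",
        ]
        for name in self.model.exog_names:
            lines.append(
                f"{name:<14}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.fvalues[name]:>10.3f}{self.pvalues[name]:>10.4g}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)


def estimate_variance_components(y, kinship, exog=None) -> VarianceComponents:
    """REML additive and residual variance for one trait (see module docs)."""
    return PedigreeMixedLM(y, exog, kinship).fit().vc


def _monomorphic_result(snp_id: str, n_used: int) -> SnpAssociation:
    return SnpAssociation(snp_id, np.nan, np.nan, np.nan, np.nan, n_used, "monomorphic")


def test_snp(y, x, kinship, mode: str = "exact", null_vc: VarianceComponents | None = None,
             snp_id: str | None = None) -> SnpAssociation:
    """Test one SNP against one trait under the pedigree mixed model.

    Parameters
    ----------
    y : Series (indexed by animal id) or array
    x : aligned allele-count vector (0/1/2; NaN allowed, dropped per SNP)
    kinship : NumeratorRelationshipMatrix / ndarray / KinshipSpectral
    mode : "exact" (per-SNP REML) or "null-reuse" (GLS at ``null_vc``,
        estimated here from the no-SNP model when not supplied)
    """
    snp_id = snp_id or getattr(x, "name", None) or "snp"
    y_ser = y if isinstance(y, pd.Series) else pd.Series(np.asarray(y, dtype=float))
    x_arr = np.asarray(pd.Series(x).reindex(y_ser.index) if isinstance(x, pd.Series) and isinstance(y, pd.Series) else x, dtype=float)
    keep = np.isfinite(x_arr) & np.isfinite(y_ser.to_numpy(dtype=float))
    n_used = int(keep.sum())
    if n_used < 3:
        return _monomorphic_result(snp_id, n_used)
    x_used = x_arr[keep]
    if np.ptp(x_used) == 0:
        return _monomorphic_result(snp_id, n_used)

    if not keep.all():
        # complete-case per SNP: the shared eigenbasis no longer applies,
        # so rebuild the (small) kinship submatrix for the kept animals
        if isinstance(kinship, KinshipSpectral):
            sub = kinship.matrix[np.ix_(keep.nonzero()[0], keep.nonzero()[0])]
        elif isinstance(kinship, NumeratorRelationshipMatrix):
            sub = kinship.values[np.ix_(keep.nonzero()[0], keep.nonzero()[0])]
        else:
            sub = np.asarray(kinship, dtype=float)[np.ix_(keep.nonzero()[0], keep.nonzero()[0])]
        kin_used = KinshipSpectral(sub, ids=list(np.asarray(y_ser.index)[keep]))
        null_vc = None  # refit on the reduced panel
    else:
        kin_used = kinship

    if isinstance(y, pd.Series):
        y_used = pd.Series(y_ser.to_numpy(dtype=float)[keep],
                           index=np.asarray(y_ser.index)[keep])
    else:
        y_used = y_ser.to_numpy(dtype=float)[keep]
    model = PedigreeMixedLM(y_used, x_used[:, None], kin_used, exog_names=[snp_id])
    if mode == "exact":
        res = model.fit()
    elif mode == "null-reuse":
        if null_vc is None:
            null_vc = PedigreeMixedLM(y_used, None, kin_used).fit().vc
        res = model.fit_fixed(null_vc.sigma_a2, null_vc.sigma_e2) if null_vc.sigma_a2 > 0 \
            else model.fit_fixed(0.0, None)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SnpAssociation(
        snp_id,
        float(res.params[snp_id]),
        float(res.bse[snp_id]),
        float(res.fvalues[snp_id]),
        float(res.pvalues[snp_id]),
        n_used,
    )


def association_scan(pheno: pd.DataFrame, geno: pd.DataFrame, kinship,
                     snpmap: pd.DataFrame | None = None, traits=None,
                     mode: str = "exact") -> pd.DataFrame:
    """Per-SNP mixed-model scan across traits.

    ``pheno`` is indexed by animal id with one column per trait; ``geno``
    is animals x SNPs allele counts on the same ids. Returns a tidy frame
    with columns snp_id, (chrom, pos when ``snpmap`` given), trait, n_used,
    beta, se, f_stat, p_value, flag.

    The A eigendecomposition is computed once; in ``null-reuse`` mode the
    per-SNP GLS is fully vectorised across markers.
    """
    if traits is None:
        traits = list(pheno.columns)
    ids = list(pheno.index)
    geno = geno.loc[ids]
    spectral = kinship if isinstance(kinship, KinshipSpectral) else KinshipSpectral(kinship, ids)

    G = geno.to_numpy(dtype=float)
    snp_ids = [str(c) for c in geno.columns]
    has_missing = np.isnan(G).any(axis=0)
    mono = np.zeros(len(snp_ids), dtype=bool)
    with np.errstate(invalid="ignore"):
        mono[~has_missing] = np.ptp(G[:, ~has_missing], axis=0) == 0
    clean = ~has_missing & ~mono
    Gr = spectral.rotate(np.nan_to_num(G[:, clean]))  # rotated clean genotypes
    ones_r = spectral.rotate(np.ones(len(ids)))

    rows: list[dict] = []
    for trait in traits:
        y = pheno[trait]
        yr = spectral.rotate(y.to_numpy(dtype=float))
        null_vc = PedigreeMixedLM(y, None, spectral).fit().vc

        if mode == "null-reuse":
            beta, se, fstat, pval = _vectorised_gls(
                spectral.d, ones_r, Gr, yr, null_vc
            )
        elif mode == "exact":
            beta = np.empty(clean.sum())
            se = np.empty_like(beta)
            fstat = np.empty_like(beta)
            pval = np.empty_like(beta)
            for k in range(clean.sum()):
                beta[k], se[k], fstat[k], pval[k] = _exact_snp_rotated(
                    spectral.d, ones_r, Gr[:, k], yr
                )
        else:
            raise ValueError(f"unknown mode {mode!r}")

        res_clean = iter(zip(beta, se, fstat, pval))
        for j, sid in enumerate(snp_ids):
            if clean[j]:
                b, s, f_, p_ = next(res_clean)
                rows.append(dict(snp_id=sid, trait=trait, n_used=len(ids),
                                 beta=b, se=s, f_stat=f_, p_value=p_, flag=""))
            elif has_missing[j]:
                r = test_snp(y, geno[sid], spectral, mode=mode, null_vc=null_vc, snp_id=sid)
                rows.append(dict(snp_id=sid, trait=trait, n_used=r.n_used, beta=r.beta,
                                 se=r.se, f_stat=r.f_stat, p_value=r.p_value, flag=r.flag))
            else:
                rows.append(dict(snp_id=sid, trait=trait, n_used=len(ids),
                                 beta=np.nan, se=np.nan, f_stat=np.nan,
                                 p_value=np.nan, flag="monomorphic"))

    out = pd.DataFrame(rows)
    if snpmap is not None:
        out = out.merge(snpmap[["snp_id", "chrom", "pos"]], on="snp_id", how="left")
        out = out[["snp_id", "chrom", "pos", "trait", "n_used", "beta", "se",
                   "f_stat", "p_value", "flag"]]
    return out


def _vectorised_gls(d, ones_r, Gr, yr, vc: VarianceComponents):
    """GLS for all SNPs at once at fixed variance components (null-reuse)."""
    n = d.size
    if vc.sigma_a2 > 0:
        w = vc.sigma_a2 * d + vc.sigma_e2
    else:
        w = np.full(n, vc.sigma_e2)
    iw = 1.0 / w
    a11 = float(ones_r**2 @ iw)
    a12 = (ones_r * iw) @ Gr
    a22 = iw @ Gr**2
    b1 = float((ones_r * iw) @ yr)
    b2 = (yr * iw) @ Gr
    det = a11 * a22 - a12**2
    beta = (a11 * b2 - a12 * b1) / det
    var_beta = a11 / det
    se = np.sqrt(var_beta)
    fstat = (beta / se) ** 2
    pval = stats.f.sf(fstat, 1, n - 2)
    return beta, se, fstat, pval


def _exact_snp_rotated(d, ones_r, xr, yr):
    """Per-SNP REML (SNP in the design) in the shared eigenbasis.

    The rotation is orthogonal, so X'X computed from rotated columns equals
    the original Gram matrix.
    """
    n = d.size
    X = np.column_stack([ones_r, xr])
    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)

    def neg_ll(t):
        w = d + np.exp(t)
        return -_profile_reml(w, X, yr, logdet_xtx)[0]

    lo, hi = np.log(DELTA_BOUNDS[0]), np.log(DELTA_BOUNDS[1])
    res = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": LOG_DELTA_TOL})
    cands = [np.exp(res.x), DELTA_BOUNDS[0], DELTA_BOUNDS[1], np.inf]
    best_ll, best_w = -np.inf, None
    for c in cands:
        w = np.ones(n) if np.isinf(c) else d + c
        ll = _profile_reml(w, X, yr, logdet_xtx)[0]
        if ll > best_ll:
            best_ll, best_w = ll, w
    _, beta, xwx_inv, sigma = _profile_reml(best_w, X, yr, logdet_xtx)
    se = np.sqrt(sigma * xwx_inv[1, 1])
    fstat = (beta[1] / se) ** 2
    return beta[1], se, fstat, stats.f.sf(fstat, 1, n - 2)


def correct_phenotype_for_qtl(y: pd.Series, g: pd.Series, beta_hat: float) -> pd.Series:
    """Subtract a known QTL effect from phenotypes: ``y_i' = y_i - g_i * beta_hat``.

    ``g`` counts copies of the effect allele at the tag SNP of the QTL (the
    strategy used to strip a large known milk-fat QTL such as DGAT1 out of
    phenotypes before re-testing nearby genes). Animals with a missing
    genotype at the QTL get a missing corrected phenotype and a warning.
    """
    if not np.isfinite(beta_hat):
        raise ValueError("beta_hat must be finite")
    g = g.reindex(y.index)
    missing = ~np.isfinite(g.to_numpy(dtype=float))
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} animals lack a genotype at the QTL SNP; "
            "their corrected phenotypes are set missing",
            stacklevel=2,
        )
    corrected = y - g * beta_hat
    corrected.name = y.name
    return corrected
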