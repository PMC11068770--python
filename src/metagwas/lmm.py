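"""Per-context mixed-linear-model association scan.

Model: ``y = mu + x b + g + e`` with a polygenic random effect
``g ~ N(0, sigma_g^2 K)`` structured by the genomic relationship matrix and
iid residuals ``e ~ N(0, sigma_e^2 I)``.  The variance ratio
``lambda = sigma_g^2 / sigma_e^2`` is estimated once per context on the null
model (no SNP) by restricted maximum likelihood and reused for every SNP —
the standard single-eigendecomposition approximation: rotate everything by
the eigenvectors of K, after which the covariance is diagonal with weights
``lambda * s_i + 1`` and each SNP test is a weighted two-column regression.

Per SNP the scan reports the allele2 substitution effect ``b``, its standard
error from the GLS normal equations (residual variance re-estimated per SNP
with n - 2 degrees of freedom), the signed Wald statistic ``t = b / se`` with
a standard-normal reference, and the two-sided p-value.  The standard-normal
reference makes ``t^2`` a 1-df chi-square, which is what the downstream
meta-combination assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.base import BaseEstimator

from .errors import ModelError
from .genotype import GenotypeMatrix, KinshipMatrix
from .phenotype import MIN_CONTEXT_SAMPLES, ContextVector

logger = logging.getLogger(__name__)

__all__ = [
    "NullModelFit",
    "MixedModelGWAS",
    "fit_null_lmm",
    "scan_snps",
    "run_context_gwas",
]

_LAMBDA_BOUNDS = (1e-5, 1e5)


@dataclass
class NullModelFit:
    """REML fit of the no-SNP mixed model for one context.

    ``loglik`` is the maximised (ML) log-likelihood of the marginal normal
    model at ``lambda_``; ``reml_loglik`` is the restricted criterion that
    was optimised.
    """

    context_id: object
    lambda_: float
    sigma2_e: float
    intercept: float
    loglik: float
    reml_loglik: float
    n: int
    accession_ids: list[str]
    eigenvalues: np.ndarray = field(repr=False)
    rotation: np.ndarray = field(repr=False)  # U with K = U diag(s) U'
    rotated_y: np.ndarray = field(repr=False)
    rotated_intercept: np.ndarray = field(repr=False)

    @property
    def h2(self) -> float:
        """Narrow-sense heritability implied by the variance ratio."""
        return self.lambda_ / (1.0 + self.lambda_)


def _reml_parts(lam: float, s: np.ndarray, ystar: np.ndarray, xstar: np.ndarray):
    """Profiled pieces shared by the REML criterion and the final fit."""
    d = lam * s + 1.0
    sxx = float(np.sum(xstar * xstar / d))
    sxy = float(np.sum(xstar * ystar / d))
    beta = sxy / sxx
    r = ystar - xstar * beta
    rss = float(np.sum(r * r / d))
    return d, beta, rss, sxx


def _neg_reml(log_lam: float, s, ystar, xstar, n: int) -> float:
    lam = float(np.exp(log_lam))
    d, _, rss, sxx = _reml_parts(lam, s, ystar, xstar)
    # constants dropped; p = 1 fixed effect (intercept)
    return 0.5 * ((n - 1) * np.log(rss) + float(np.sum(np.log(d))) + np.log(sxx))


def fit_null_lmm(
    y: ContextVector | pd.Series,
    K: KinshipMatrix,
    min_samples: int = MIN_CONTEXT_SAMPLES,
    context_id: object = None,
    n_grid: int = 61,
) -> NullModelFit:
    """REML estimate of the variance ratio on the intercept-only model.

    The one-dimensional profile criterion is evaluated on a log-spaced
    lambda grid spanning [1e-5, 1e5] and refined by bounded scalar search
    around the grid optimum; the procedure is deterministic.
    """
    if isinstance(y, ContextVector):
        if context_id is None:
            context_id = y.context_id
        y = y.values
    if y.index.duplicated().any():
        raise ModelError("duplicate accession ids in phenotype vector")
    y = y.dropna()
    n = len(y)
    if n < min_samples:
        raise ModelError(f"context has {n} phenotyped accessions; need >= {min_samples}")
    if float(np.var(y.to_numpy())) <= 0.0:
        raise ModelError("zero phenotypic variance in context")
    ids = [str(a) for a in y.index]
    Ksub = K.restrict(ids).values
    s, U = np.linalg.eigh(Ksub)
    scale = max(float(s[-1]), 1.0)
    if s[0] < -1e-8 * scale:
        raise ModelError(f"kinship not PSD (min eigenvalue {s[0]:.3g})")
    s = np.clip(s, 0.0, None)
    yv = y.to_numpy(dtype=float)
    ystar = U.T @ yv
    xstar = U.T @ np.ones(n)

    lo, hi = np.log(_LAMBDA_BOUNDS[0]), np.log(_LAMBDA_BOUNDS[1])
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([_neg_reml(g, s, ystar, xstar, n) for g in grid])
    k = int(np.argmin(vals))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        _neg_reml, bounds=(a, b), args=(s, ystar, xstar, n), method="bounded",
        options={"xatol": 1e-8},
    )
    best_log = res.x if res.fun <= vals[k] else grid[k]
    lam = float(np.exp(best_log))

    d, beta, rss, sxx = _reml_parts(lam, s, ystar, xstar)
    sigma2_e = rss / (n - 1)
    # restricted likelihood with its usual constants
    reml_ll = 0.5 * (
        (n - 1) * np.log((n - 1) / (2.0 * np.pi))
        - (n - 1)
        - (n - 1) * np.log(rss)
        - float(np.sum(np.log(d)))
        - np.log(sxx)
        + np.log(n)  # log det(X'X) for the intercept column
    )
    # ML log-likelihood at lambda-hat (sigma2 profiled with n, not n-1)
    sigma2_ml = rss / n
    ml_ll = -0.5 * (
        n * np.log(2.0 * np.pi * sigma2_ml) + float(np.sum(np.log(d))) + n
    )
    return NullModelFit(
        context_id=context_id,
        lambda_=lam,
        sigma2_e=float(sigma2_e),
        intercept=float(beta),
        loglik=float(ml_ll),
        reml_loglik=float(reml_ll),
        n=n,
        accession_ids=ids,
        eigenvalues=s,
        rotation=U,
        rotated_y=ystar,
        rotated_intercept=xstar,
    )


def scan_snps(G: GenotypeMatrix, null: NullModelFit) -> pd.DataFrame:
    """Weighted single-SNP regressions at the null model's variance ratio.

    Missing dosages are mean-imputed within the context; SNPs monomorphic
    within the context get NaN results (counted in the log).  Returns one
    row per SNP: snp_id, chrom, pos, n_used, maf, beta, se, t, p.
    """
    Gsub = G.subset_accessions(null.accession_ids)
    dos = Gsub.dosage
    n, m = dos.shape
    called = ~np.isnan(dos)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(dos, axis=0) / (2.0 * n_called)
    maf = np.minimum(freq, 1.0 - freq)
    X = np.where(called, dos, 2.0 * freq)  # per-SNP mean imputation

    c = 1.0 / (null.lambda_ * null.eigenvalues + 1.0)  # GLS weights
    u1 = null.rotated_intercept
    ystar = null.rotated_y
    Xr = null.rotation.T @ X  # n x m rotated dosages

    s11 = float(np.sum(c * u1 * u1))
    s1y = float(np.sum(c * u1 * ystar))
    syy = float(np.sum(c * ystar * ystar))
    s1x = (c * u1) @ Xr
    sxy = (c * ystar) @ Xr
    sxx = c @ (Xr * Xr)

    det = s11 * sxx - s1x**2
    # variance of the dosage after projecting out the intercept; ~0 means
    # the SNP is monomorphic within this context
    resid_var = sxx - s1x**2 / s11
    mono = resid_var <= 1e-10 * max(s11, 1.0)
    det = np.where(mono, np.nan, det)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = (s11 * sxy - s1x * s1y) / det
        mu = (sxx * s1y - s1x * sxy) / det
        rss = syy - (mu * s1y + b * sxy)
        rss = np.clip(rss, 0.0, None)
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 * s11 / det)
        t = b / se
    p = special.erfc(np.abs(t) / np.sqrt(2.0))  # two-sided standard normal
    n_mono = int(np.count_nonzero(mono))
    if n_mono:
        logger.info("scan %s: %d SNPs monomorphic in context", null.context_id, n_mono)
    out = pd.DataFrame(
        {
            "snp_id": Gsub.snp_ids,
            "chrom": Gsub.snp_map["chrom"].to_numpy(),
            "pos": Gsub.snp_map["pos"].to_numpy(),
            "n_used": n_called,
            "maf": maf,
            "beta": b,
            "se": se,
            "t": t,
            "p": p,
        }
    )
    out.loc[mono, ["beta", "se", "t", "p"]] = np.nan
    return out


class MixedModelGWAS(BaseEstimator):
    """Estimator wrapper: fit the null model, then scan SNPs.

    Parameters
    ----------
    min_samples:
        Minimum non-missing phenotypes for a context to be fitted.

    Attributes (after :meth:`fit`)
    ------------------------------
    null_ : :class:`NullModelFit`
    lambda_, h2_ : variance ratio and implied heritability
    """

    def __init__(self, min_samples: int = MIN_CONTEXT_SAMPLES):
        self.min_samples = min_samples

    def fit(self, y: ContextVector | pd.Series, K: KinshipMatrix) -> "MixedModelGWAS":
        self.null_ = fit_null_lmm(y, K, min_samples=self.min_samples)
        self.lambda_ = self.null_.lambda_
        self.h2_ = self.null_.h2
        return self

    def scan(self, G: GenotypeMatrix) -> pd.DataFrame:
        return scan_snps(G, self.null_)


def run_context_gwas(
    G: GenotypeMatrix,
    y: ContextVector | pd.Series,
    K: KinshipMatrix,
    min_samples: int = MIN_CONTEXT_SAMPLES,
) -> pd.DataFrame:
    """Null fit + scan for one context; logs context, n, and lambda-hat."""
    model = MixedModelGWAS(min_samples=min_samples).fit(y, K)
    logger.info(
        "context %s: n=%d lambda=%.4g h2=%.3f",
        model.null_.context_id, model.null_.n, model.lambda_, model.h2_,
    )
    return model.scan(G)
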