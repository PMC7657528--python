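"""Fisher combination of dependent marginal p-values (Brown-type gamma null).

Given one pathway's marginal p-values p_1..p_k (one per phenotype), the
combined statistic is T = sum_i -2 log p_i.  Independence gives T ~ chi^2_2k;
under dependence the null is moment-matched to a gamma with mean
mu = E[T] = 2k and variance

    sigma^2 = 4k + 2 sum_{i<j} cov(-2 log p_i, -2 log p_j),

where each pairwise covariance is the Kost-McDermott cubic polynomial in the
correlation r_ij of the covariate-adjusted phenotypes:

    c(r) = r (3.263 + 0.710 r + 0.027 r^2),  r >= 0,

extended to negative r by the odd continuation c(-r) = -c(r) and clipped to
[-4, 4] (the perfect-dependence bound).  The global p-value is the upper tail
of Gamma(shape = mu^2/sigma^2, scale = sigma^2/mu), which reduces exactly to
the chi^2_2k Fisher p when the correlation is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .msku import _repair_correlation
from .synthdata import CovariateMatrix, PhenotypeMatrix

__all__ = [
    "FCResult",
    "PhenotypeCorrelation",
    "phenotype_correlation",
    "brown_moments",
    "fc_combine",
]

logger = logging.getLogger("fcmsku")


@dataclass
class PhenotypeCorrelation:
    """k x k correlation of covariate-adjusted phenotypes."""

    values: np.ndarray
    method: str = "pearson-residual"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        k = self.values.shape[0]
        if self.values.shape != (k, k):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if (np.abs(self.values) > 1 + 1e-10).any():
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @classmethod
    def identity(cls, k: int) -> "PhenotypeCorrelation":
        return cls(values=np.eye(k), method="identity")


@dataclass
class FCResult:
    marginal_pvalues: np.ndarray
    t_stat: float
    mu: float
    sigma2: float
    alpha_scale: float     # gamma scale / 2
    beta_shape_times2: float  # gamma shape * 2
    global_p: float
    pheno_correlation: np.ndarray


def phenotype_correlation(
    phenotypes: PhenotypeMatrix, covariates: CovariateMatrix
) -> PhenotypeCorrelation:
    """Pearson correlation of phenotype columns after OLS covariate removal."""
    Y = phenotypes.values
    n, k = Y.shape
    Z = covariates.values
    if Z.shape[0] != n:
        raise ValueError("phenotypes and covariates must share sample count")
    if n <= k + Z.shape[1] + 1:
        raise ValueError("too few samples to estimate the correlation")
    design = np.column_stack([np.ones(n), Z])
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ coef
    sd = resid.std(axis=0)
    if (sd == 0).any():
        bad = [phenotypes.names[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant (fully explained) phenotype columns: {bad}")
    corr = np.corrcoef(resid, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return PhenotypeCorrelation(values=_repair_correlation(corr))


def _kost_mcdermott(r: np.ndarray) -> np.ndarray:
    """cov(-2 log p_i, -2 log p_j) as a cubic in the correlation r."""
    a = np.abs(r)
    c = a * (3.263 + 0.710 * a + 0.027 * a * a)
    return np.clip(np.sign(r) * c, -4.0, 4.0)


def brown_moments(k: int, correlation: PhenotypeCorrelation) -> tuple[float, float]:
    """Mean and variance of T = sum -2 log p_i under dependence.

    mu = 2k always; sigma^2 adds twice the Kost-McDermott pairwise
    covariances to the independence value 4k, floored at 2k so the matched
    gamma stays well-defined under pathological negative correlation.
    """
    if correlation.k != k:
        raise ValueError("correlation dimension must equal k")
    mu = 2.0 * k
    r = correlation.values
    iu = np.triu_indices(k, 1)
    sigma2 = 4.0 * k + 2.0 * float(_kost_mcdermott(r[iu]).sum())
    sigma2 = max(sigma2, 2.0 * k)
    return mu, sigma2


def fc_combine(
    marginal_pvalues: np.ndarray, correlation: PhenotypeCorrelation
) -> FCResult:
    """Combine k marginal p-values into a global dependence-adjusted p.

    T = sum -2 log p_i is referred to Gamma(shape = mu^2/sigma^2,
    scale = sigma^2/mu); the mean/variance identity shape*scale = mu,
    shape*scale^2 = sigma^2 holds by construction.  Exact zeros are floored
    at the smallest positive float with a warning.
    """
    p = np.asarray(marginal_pvalues, dtype=float).ravel()
    k = p.size
    if k < 1:
        raise ValueError("need at least one marginal p-value")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("marginal p-values must lie in (0, 1]")
    if (p == 0).any():
        logger.warning("marginal p-value of 0 floored at float tiny")
        p = np.maximum(p, np.finfo(float).tiny)
    if correlation.k != k:
        raise ValueError("correlation dimension must equal number of p-values")
    t_stat = float(-2.0 * np.log(p).sum())
    mu, sigma2 = brown_moments(k, correlation)
    shape = mu * mu / sigma2   # beta / 2
    scale = sigma2 / mu        # 2 alpha
    global_p = float(stats.gamma.sf(t_stat, a=shape, scale=scale))
    return FCResult(
        marginal_pvalues=p,
        t_stat=t_stat,
        mu=mu,
        sigma2=sigma2,
        alpha_scale=scale / 2.0,
        beta_shape_times2=2.0 * shape,
        global_p=global_p,
        pheno_correlation=correlation.values,
    )
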