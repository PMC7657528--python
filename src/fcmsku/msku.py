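"""Semi-supervised maximum kernel-based U-statistic (mSKU) test.

Tests association between one pathway (a SNP set) and one quantitative
phenotype.  For each candidate kernel m the centred kernel matrix K~ and the
covariate-adjusted phenotype residuals e give a degenerate second-order
U-statistic

    T_m = [1 / (n(n-1))] sum_{i != j} K~_ij e_i e_j

with plug-in variance

    V_m = [2 / (n^2 (n-1)^2)] sum_{i != j} K~_ij^2 e_i^2 e_j^2 ,

standardised as Q_m = T_m / sqrt(V_m).  Under the null the vector
(Q_1, ..., Q_M) is asymptotically N(0, Omega); the test statistic is
Q_max = max_m Q_m and its upper-tail p-value is 1 - P(Z <= q_max 1_M) for
Z ~ N(0, Omega_hat), evaluated by the Genz multivariate-normal rectangle
algorithm.  Large positive Q_max rejects (one-sided).

The "semi-supervised" screening step optionally discards pathway SNPs whose
single-SNP regression on an auxiliary label (never the phenotype under test)
has p >= alpha_m, before any kernel is built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.correlation_tools import corr_clipped

from .kernels import KernelMatrix, KernelSpec, center_kernel, kernel_matrix
from .synthdata import CovariateMatrix, GenotypeMatrix

__all__ = [
    "ScreeningResult",
    "SingleKernelStat",
    "MaxKernelResult",
    "ResidualVector",
    "DegenerateStatisticError",
    "screen_snps",
    "residualize",
    "ku_statistic",
    "kernel_correlation",
    "max_statistic_pvalue",
    "msku_test",
]

logger = logging.getLogger("fcmsku")

# fixed integration seed so the QMC rectangle probability is reproducible
_MVN_SEED = 20201111
_MVN_ABSEPS = 1e-5


class DegenerateStatisticError(ValueError):
    """Raised when a kernel carries no usable pairwise information."""


@dataclass
class ScreeningResult:
    kept_snp_ids: list[str]
    per_snp_pvalues: dict[str, float]
    threshold: float
    label_type: str  # "binary", "quantitative" or "none"
    fallback: bool = False  # True when empty screen fell back to full pathway


@dataclass
class SingleKernelStat:
    t_n: float
    v_hat: float
    q: float
    spec: KernelSpec


@dataclass
class MaxKernelResult:
    per_kernel: list[SingleKernelStat]
    omega_hat: np.ndarray
    q_max: float
    p_value: float
    n_used: int
    snps_used: int
    screening: Optional[ScreeningResult] = None

    @property
    def q_values(self) -> np.ndarray:
        return np.array([s.q for s in self.per_kernel])

    def to_record(self, pathway_id: str, phenotype_name: str,
                  snps_in_pathway: int) -> dict:
        """Flat per-test record (one TSV row per pathway x phenotype)."""
        rec = {
            "pathway": pathway_id,
            "phenotype": phenotype_name,
            "n": self.n_used,
            "snps_in_pathway": snps_in_pathway,
            "snps_used": self.snps_used,
            "n_kernels": len(self.per_kernel),
        }
        for s in self.per_kernel:
            rec[f"q_{s.spec.family}"] = s.q
        rec["q_max"] = self.q_max
        rec["p_value"] = self.p_value
        rec["screening_fallback"] = bool(self.screening and self.screening.fallback)
        return rec


@dataclass
class ResidualVector:
    values: np.ndarray
    phenotype_name: str = "phenotype"
    covariate_names: list[str] = field(default_factory=list)


def _ols_pvalues_vectorized(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-value for the slope of y ~ 1 + x_j, per column j."""
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    out = np.ones(X.shape[1])
    ok = sxx > 0
    beta = np.zeros_like(out)
    beta[ok] = (xc[:, ok] * yc[:, None]).sum(axis=0) / sxx[ok]
    rss = (yc**2).sum() - beta**2 * sxx
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof / sxx)
        tval = np.where(ok & (se > 0), beta / se, 0.0)
    out[ok] = 2.0 * stats.t.sf(np.abs(tval[ok]), dof)
    return out


def _logistic_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Wald p for the slope of a single-SNP logistic fit; 1.0 on failure."""
    import statsmodels.api as sm

    design = sm.add_constant(x.astype(float))
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
        p = float(fit.pvalues[1])
        if not np.isfinite(p):
            raise ValueError("non-finite p")
        return p
    except Exception:  # separation / non-convergence
        logger.warning("logistic screen failed for a SNP; assigned p = 1")
        return 1.0


def screen_snps(
    genotypes: GenotypeMatrix,
    label: np.ndarray,
    alpha_m: float = 0.05,
) -> ScreeningResult:
    """Per-SNP screening against an auxiliary label.

    Fits a single-predictor regression of the label on each SNP (logistic for
    a binary label, least squares otherwise) and keeps SNPs with two-sided
    coefficient p-value below ``alpha_m``.  Monomorphic SNPs get p = 1.  An
    empty kept set falls back to the full pathway and flags the result.
    """
    if not 0 < alpha_m <= 1:
        raise ValueError("alpha_m must lie in (0, 1]")
    label = np.asarray(label, dtype=float).ravel()
    if label.shape[0] != genotypes.n_samples:
        raise ValueError("label length must match sample count")
    X = genotypes.values.astype(float)
    uniq = np.unique(label)
    binary = uniq.size == 2 and set(uniq) <= {0.0, 1.0}
    mono = X.std(axis=0) == 0
    if binary:
        pvals = np.ones(X.shape[1])
        for j in np.flatnonzero(~mono):
            pvals[j] = _logistic_pvalue(X[:, j], label)
        label_type = "binary"
    else:
        pvals = _ols_pvalues_vectorized(X, label)
        pvals[mono] = 1.0
        label_type = "quantitative"
    if mono.any():
        logger.info("screening: %d monomorphic SNPs assigned p = 1", mono.sum())
    kept = [s for s, p in zip(genotypes.snp_ids, pvals) if p < alpha_m]
    fallback = False
    if not kept:
        logger.warning("screening kept no SNPs; falling back to full pathway")
        kept = list(genotypes.snp_ids)
        fallback = True
    return ScreeningResult(
        kept_snp_ids=kept,
        per_snp_pvalues=dict(zip(genotypes.snp_ids, map(float, pvals))),
        threshold=alpha_m,
        label_type=label_type,
        fallback=fallback,
    )


def residualize(phenotype: np.ndarray, covariates: CovariateMatrix) -> ResidualVector:
    """OLS residuals of the phenotype on an intercept plus covariates."""
    y = np.asarray(phenotype, dtype=float).ravel()
    Z = covariates.values
    if Z.shape[0] != y.shape[0]:
        raise ValueError("phenotype and covariates must share sample count")
    design = np.column_stack([np.ones(len(y)), Z])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "rank-deficient covariate design (collinear among intercept and "
            f"{covariates.names})"
        )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return ResidualVector(values=resid, covariate_names=list(covariates.names))


# ---------------------------------------------------------------------------
# U-statistic machinery.  _KernelEnsemble is the shared fast path: it holds
# the centred kernels with zeroed diagonals plus their elementwise squares so
# that Q_m, V_m and the inter-kernel correlation reduce to matrix products.
# The simulation harness reuses one ensemble across all t phenotypes.
# ---------------------------------------------------------------------------


class _KernelEnsemble:
    def __init__(self, centered: Sequence[KernelMatrix]):
        if not centered:
            raise ValueError("empty kernel list")
        n = centered[0].values.shape[0]
        for K in centered:
            if K.values.shape[0] != n:
                raise ValueError("kernels must share sample count")
            if not K.centered:
                raise ValueError("kernels must be centred first")
        self.n = n
        self.specs = [K.spec for K in centered]
        self.K_od = []
        self.K_od_sq = []
        for K in centered:
            V = K.values.copy()
            np.fill_diagonal(V, 0.0)
            self.K_od.append(V)
            self.K_od_sq.append(V * V)
        self._pairs: dict[tuple[int, int], np.ndarray] = {}

    def _pair(self, k: int, l: int) -> np.ndarray:
        """Elementwise product of kernels k and l (cached across calls)."""
        if k == l:
            return self.K_od_sq[k]
        key = (min(k, l), max(k, l))
        if key not in self._pairs:
            self._pairs[key] = self.K_od[key[0]] * self.K_od[key[1]]
        return self._pairs[key]

    def stats(self, E: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-kernel (T, V, Q) for each residual column of E (n x t)."""
        n = self.n
        E = E.reshape(n, -1)
        U = E * E
        M, t = len(self.K_od), E.shape[1]
        T = np.empty((M, t))
        V = np.empty((M, t))
        for m, (Kod, Ksq) in enumerate(zip(self.K_od, self.K_od_sq)):
            T[m] = np.einsum("it,it->t", E, Kod @ E) / (n * (n - 1))
            V[m] = 2.0 * np.einsum("it,it->t", U, Ksq @ U) / (n * (n - 1)) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            Q = np.where(V > 0, T / np.sqrt(V), np.nan)
        return T, V, Q

    def correlation(self, e: np.ndarray) -> np.ndarray:
        """Plug-in inter-kernel correlation Omega_hat for residuals e."""
        u = (e * e).reshape(self.n, 1)
        M = len(self.K_od)
        ss = np.empty((M, M))
        for k in range(M):
            for l in range(k, M):
                ss[k, l] = ss[l, k] = (u.T @ self._pair(k, l) @ u).item()
        d = np.sqrt(np.diag(ss))
        if (d == 0).any():
            raise DegenerateStatisticError("a kernel has zero plug-in variance")
        omega = ss / np.outer(d, d)
        np.fill_diagonal(omega, 1.0)
        return _repair_correlation(omega)


def _repair_correlation(omega: np.ndarray) -> np.ndarray:
    """Clip tiny negative eigenvalues and restore the unit diagonal."""
    omega = (omega + omega.T) / 2.0
    if np.linalg.eigvalsh(omega).min() < 1e-8:
        omega = corr_clipped(omega, threshold=1e-7)
        np.fill_diagonal(omega, 1.0)
    return omega


def ku_statistic(K: KernelMatrix, residuals: ResidualVector) -> SingleKernelStat:
    """Standardised kernel U-statistic for one centred kernel.

    Q is invariant to positive rescaling of either the kernel or the
    residuals.  Raises ``DegenerateStatisticError`` when the plug-in variance
    vanishes (no off-diagonal kernel signal or fewer than two nonzero
    residuals).
    """
    e = np.asarray(residuals.values, dtype=float).ravel()
    n = e.shape[0]
    if n < 4:
        raise ValueError("need n >= 4 samples")
    if K.values.shape[0] != n:
        raise ValueError("kernel and residuals must share sample count")
    if not np.any(e):
        raise DegenerateStatisticError("residuals are all zero")
    ens = _KernelEnsemble([K if K.centered else center_kernel(K)])
    T, V, Q = ens.stats(e[:, None])
    if V[0, 0] <= 0:
        raise DegenerateStatisticError("plug-in variance is zero")
    return SingleKernelStat(t_n=float(T[0, 0]), v_hat=float(V[0, 0]),
                            q=float(Q[0, 0]), spec=K.spec)


def kernel_correlation(
    kernels: Sequence[KernelMatrix], residuals: ResidualVector
) -> np.ndarray:
    """Estimated correlation Omega_hat among the M standardised statistics."""
    ens = _KernelEnsemble(
        [K if K.centered else center_kernel(K) for K in kernels]
    )
    return ens.correlation(np.asarray(residuals.values, dtype=float))


def max_statistic_pvalue(q_max: float, omega_hat: np.ndarray) -> float:
    """Upper-tail probability P(max_m Z_m > q_max) with Z ~ N(0, Omega_hat)."""
    omega = np.atleast_2d(np.asarray(omega_hat, dtype=float))
    M = omega.shape[0]
    if omega.shape != (M, M):
        raise ValueError("omega_hat must be square")
    if not np.allclose(np.diag(omega), 1.0, atol=1e-6):
        raise ValueError("omega_hat must have unit diagonal")
    omega = _repair_correlation(omega)
    if np.linalg.eigvalsh(omega).min() < -1e-8:
        raise ValueError("omega_hat is not positive semidefinite after repair")
    if M == 1:
        return float(stats.norm.sf(q_max))
    rect = stats.multivariate_normal.cdf(
        np.full(M, q_max),
        mean=np.zeros(M),
        cov=omega,
        allow_singular=True,
        abseps=_MVN_ABSEPS,
        releps=0.0,
        rng=np.random.default_rng(_MVN_SEED),
    )
    return float(min(1.0, max(0.0, 1.0 - rect)))


def msku_test(
    genotypes: GenotypeMatrix,
    pathway_snp_ids: Sequence[str],
    phenotype: np.ndarray,
    covariates: CovariateMatrix,
    kernel_bundle: Sequence[KernelSpec],
    screening_label: Optional[np.ndarray] = None,
    alpha_m: float = 0.05,
) -> MaxKernelResult:
    """Full mSKU pipeline for one pathway and one quantitative phenotype.

    Subsets the pathway SNPs, optionally screens them against the auxiliary
    label, residualises the phenotype on covariates, builds the centred
    candidate kernels, and returns Q_max with its asymptotic p-value.
    """
    sub = genotypes.subset(list(pathway_snp_ids))
    # monomorphic SNPs carry no similarity information
    poly = sub.values.std(axis=0) > 0
    if not poly.all():
        logger.info("dropping %d monomorphic pathway SNPs", (~poly).sum())
        keep = [s for s, ok in zip(sub.snp_ids, poly) if ok]
        if not keep:
            raise ValueError("pathway has no polymorphic SNPs")
        sub = sub.subset(keep)
    screening = None
    if screening_label is not None:
        screening = screen_snps(sub, screening_label, alpha_m)
        sub = sub.subset(screening.kept_snp_ids)
    resid = residualize(phenotype, covariates)
    X = sub.values.astype(float)
    centered = [center_kernel(kernel_matrix(X, spec)) for spec in kernel_bundle]
    ens = _KernelEnsemble(centered)
    T, V, Q = ens.stats(resid.values[:, None])
    if not (V[:, 0] > 0).all():
        raise DegenerateStatisticError("a candidate kernel is degenerate")
    omega = ens.correlation(resid.values)
    q_max = float(Q[:, 0].max())
    p = max_statistic_pvalue(q_max, omega)
    per_kernel = [
        SingleKernelStat(t_n=float(T[m, 0]), v_hat=float(V[m, 0]),
                         q=float(Q[m, 0]), spec=spec)
        for m, spec in enumerate(ens.specs)
    ]
    return MaxKernelResult(
        per_kernel=per_kernel,
        omega_hat=omega,
        q_max=q_max,
        p_value=p,
        n_used=sub.n_samples,
        snps_used=sub.n_snps,
        screening=screening,
    )
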