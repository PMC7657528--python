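"""Synthetic genotype / covariate / phenotype generator for the simulation study.

Emulates a single-pathway GWAS design: Hardy-Weinberg genotypes with
configurable minor-allele frequencies and adjacent-SNP linkage
disequilibrium, two independent covariates (Z1 ~ N(2, 1), Z2 ~ Bernoulli(0.6)),
and t quantitative phenotypes sharing an exchangeably correlated Gaussian
error.  Genetic effects enter through a scenario function h(X):

* ``null`` — h = 0 (type-I error studies)
* ``M``    — sparse nonlinear: 0.27(x5 - x10) + cos(x10) exp(-x10^2 / 5)
* ``N``    — sparse linear: 0.37 x5 + 0.62 x10 - 0.06 x15
* ``P``/``Q`` — polygenic main effects over 60 SNPs plus 90 pairwise
  interactions with Unif(0, 0.02) coefficients, scaled by (b_P, b_Q);
  (0.07, 2.3) for P (interaction-dominated) and (3.8, 0) for Q (pure main).

SNP indices in scenarios M/N are 1-based (x5 is the fifth SNP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "GenotypeMatrix",
    "CovariateMatrix",
    "PhenotypeMatrix",
    "SimulationConfig",
    "ScenarioPQCoefficients",
    "simulate_genotypes",
    "simulate_covariates",
    "scenario_h",
    "simulate_phenotypes",
    "make_scenario_pq_coefficients",
    "SCENARIOS",
]

SCENARIOS = ("null", "M", "N", "P", "Q")

# (b_P, b_Q) pairs for the polygenic scenarios: P mixes a weak main effect
# with strong interactions, Q is a pure main effect.
SCENARIO_PQ_SCALES = {"P": (0.07, 2.3), "Q": (3.8, 0.0)}


@dataclass
class GenotypeMatrix:
    """n x p additive-coded genotypes (minor-allele counts in {0, 1, 2})."""

    values: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    mafs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if len(self.snp_ids) != p:
            raise ValueError(f"{len(self.snp_ids)} SNP ids for {p} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.snp_ids)) != p:
            raise ValueError("SNP ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("genotype entries must be 0, 1 or 2")
        if self.mafs is not None:
            self.mafs = np.asarray(self.mafs, dtype=float)
            if self.mafs.shape != (p,):
                raise ValueError("mafs length must equal SNP count")
            if ((self.mafs <= 0) | (self.mafs > 0.5)).any():
                raise ValueError("MAFs must lie in (0, 0.5]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """Column subset in the given SNP order; unknown ids raise KeyError."""
        index = {s: j for j, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in index]
        if missing:
            raise KeyError(f"SNPs absent from genotype matrix: {missing[:5]}")
        cols = [index[s] for s in snp_ids]
        return GenotypeMatrix(
            values=self.values[:, cols],
            snp_ids=list(snp_ids),
            sample_ids=self.sample_ids,
            mafs=None if self.mafs is None else self.mafs[cols],
        )


@dataclass
class CovariateMatrix:
    """n x c real covariates; c may be zero."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("covariates must be a 2-d array")
        if self.values.shape[1] != len(self.names):
            raise ValueError("covariate names do not match column count")
        if not np.isfinite(self.values).all():
            raise ValueError("covariates contain missing/non-finite values")

    @classmethod
    def empty(cls, n: int) -> "CovariateMatrix":
        return cls(values=np.empty((n, 0)), names=[])


@dataclass
class PhenotypeMatrix:
    """n x t quantitative phenotypes."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("phenotypes must be n x t with t >= 1")
        if self.values.shape[1] != len(self.names):
            raise ValueError("phenotype names do not match column count")
        if not np.isfinite(self.values).all():
            raise ValueError("phenotypes contain missing/non-finite values")


@dataclass
class ScenarioPQCoefficients:
    """Frozen effect sets for the polygenic scenarios P and Q.

    ``hp_indices`` are 0-based positions of the 60 main-effect SNPs (H_P);
    ``hq_pairs`` are 90 distinct 0-based index pairs (H_Q).  Coefficients are
    drawn once from Unif(0, 0.02) and reused across simulation replicates.
    """

    hp_indices: np.ndarray
    hq_pairs: np.ndarray
    alpha_m: np.ndarray
    beta_mm: np.ndarray
    b_p: float = 0.0
    b_q: float = 0.0

    def __post_init__(self) -> None:
        self.hp_indices = np.asarray(self.hp_indices, dtype=int)
        self.hq_pairs = np.asarray(self.hq_pairs, dtype=int)
        self.alpha_m = np.asarray(self.alpha_m, dtype=float)
        self.beta_mm = np.asarray(self.beta_mm, dtype=float)
        if self.hq_pairs.ndim != 2 or self.hq_pairs.shape[1] != 2:
            raise ValueError("hq_pairs must have shape (n_pairs, 2)")
        if len(self.hp_indices) != len(self.alpha_m):
            raise ValueError("alpha_m length must match hp_indices")
        if len(self.hq_pairs) != len(self.beta_mm):
            raise ValueError("beta_mm length must match hq_pairs")


@dataclass
class SimulationConfig:
    """Settings of one simulation-study cell.

    Defaults follow the study design: t = 5 correlated quantitative
    phenotypes, 1000 replicates at nominal level 0.05, unit error scale,
    MAFs uniform on (0.05, 0.5) and moderate adjacent-SNP LD.
    """

    n: int = 200
    p: int = 400
    t: int = 5
    rho: float = 0.2
    scenario: str = "null"
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_r: float = 0.5
    error_sd: float = 1.0
    n_replicates: int = 1000
    alpha_level: float = 0.05
    seed: int = 0
    b_p: Optional[float] = None
    b_q: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if self.error_sd <= 0:
            raise ValueError("error_sd must be positive")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if not 0 <= self.ld_r < 1:
            raise ValueError("ld_r must lie in [0, 1)")


def _latent_ar1(rng: np.random.Generator, n: int, p: int, r: float) -> np.ndarray:
    """n x p standard-normal draws with AR(1) correlation r along columns."""
    z = rng.standard_normal((n, p))
    if r == 0 or p == 1:
        return z
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    s = np.sqrt(1.0 - r * r)
    for j in range(1, p):
        out[:, j] = r * out[:, j - 1] + s * z[:, j]
    return out


def simulate_genotypes(
    n: int,
    p: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    ld_r: float = 0.5,
    seed: int = 0,
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes with AR(1)-style linkage disequilibrium.

    Per SNP j a MAF is drawn uniformly from [maf_low, maf_high].  Each of the
    two haplotypes per sample is a latent Gaussian AR(1) process (adjacent-SNP
    correlation ``ld_r``) thresholded at the MAF quantile; summing the two
    independent haplotypes yields genotype frequencies (1-q)^2, 2q(1-q), q^2.
    """
    if n < 2 or p < 1:
        raise ValueError("need n >= 2 samples and p >= 1 SNPs")
    if not 0 < maf_low <= maf_high <= 0.5:
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if not 0 <= ld_r < 1:
        raise ValueError("ld_r must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_low, maf_high, size=p)
    cuts = norm.ppf(mafs)  # latent < cut  <=>  minor allele present
    hap1 = _latent_ar1(rng, n, p, ld_r) < cuts
    hap2 = _latent_ar1(rng, n, p, ld_r) < cuts
    geno = (hap1.astype(np.int8) + hap2.astype(np.int8))
    return GenotypeMatrix(
        values=geno,
        snp_ids=[f"snp{j + 1}" for j in range(p)],
        sample_ids=[f"s{i + 1}" for i in range(n)],
        mafs=mafs,
    )


def simulate_covariates(n: int, seed: int = 0) -> CovariateMatrix:
    """Two independent covariates: Z1 ~ N(2, 1) and Z2 ~ Bernoulli(0.6)."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    z1 = rng.normal(2.0, 1.0, size=n)
    z2 = rng.binomial(1, 0.6, size=n).astype(float)
    return CovariateMatrix(values=np.column_stack([z1, z2]), names=["Z1", "Z2"])


def make_scenario_pq_coefficients(p: int, seed: int = 0) -> ScenarioPQCoefficients:
    """Draw the frozen H_P / H_Q effect sets for scenarios P and Q.

    60 main-effect SNPs and 90 interaction pairs are sampled without
    replacement; all coefficients are Unif(0, 0.02).  Call once per study and
    reuse across replicates.
    """
    n_main, n_pairs = 60, 90
    if p < 150:  # enough distinct SNPs for 60 mains plus 90 pairs
        raise ValueError(f"p = {p} too small for 60 mains + 90 pairs")
    rng = np.random.default_rng(seed)
    hp = rng.choice(p, size=n_main, replace=False)
    # distinct unordered pairs, sampled without replacement
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < n_pairs:
        a, b = rng.choice(p, size=2, replace=False)
        pairs.add((min(a, b), max(a, b)))
    hq = np.array(sorted(pairs))
    return ScenarioPQCoefficients(
        hp_indices=hp,
        hq_pairs=hq,
        alpha_m=rng.uniform(0.0, 0.02, size=n_main),
        beta_mm=rng.uniform(0.0, 0.02, size=n_pairs),
    )


def scenario_h(
    genotypes: GenotypeMatrix,
    scenario: str,
    coefficients: Optional[ScenarioPQCoefficients] = None,
    b_p: Optional[float] = None,
    b_q: Optional[float] = None,
) -> np.ndarray:
    """Evaluate the genetic-effect function h(X) for one scenario.

    Deterministic given genotypes and coefficients.  SNP subscripts in the
    sparse scenarios are 1-based, so x5 is column index 4.
    """
    X = genotypes.values.astype(float)
    n, p = X.shape
    if scenario == "null":
        return np.zeros(n)
    if scenario == "M":
        if p < 10:
            raise ValueError("scenario M needs p >= 10")
        x5, x10 = X[:, 4], X[:, 9]
        return 0.27 * (x5 - x10) + np.cos(x10) * np.exp(-(x10**2) / 5.0)
    if scenario == "N":
        if p < 15:
            raise ValueError("scenario N needs p >= 15")
        return 0.37 * X[:, 4] + 0.62 * X[:, 9] - 0.06 * X[:, 14]
    if scenario in ("P", "Q"):
        if coefficients is None:
            raise ValueError(f"scenario {scenario} requires frozen coefficients")
        if b_p is None or b_q is None:
            b_p, b_q = SCENARIO_PQ_SCALES[scenario]
        hp, hq = coefficients.hp_indices, coefficients.hq_pairs
        if (hp >= p).any() or (len(hq) and (hq >= p).any()):
            raise IndexError("coefficient SNP index out of range")
        main = X[:, hp] @ coefficients.alpha_m
        inter = (X[:, hq[:, 0]] * X[:, hq[:, 1]]) @ coefficients.beta_mm
        return b_p * main + b_q * inter
    raise ValueError(f"unknown scenario {scenario!r}")


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    covariates: CovariateMatrix,
    h: np.ndarray,
    t: int = 5,
    rho: float = 0.2,
    error_sd: float = 1.0,
    seed: int = 0,
) -> PhenotypeMatrix:
    """t phenotypes Y_k = 0.02 Z1 + 0.6 Z2 + h(X) + eps_k.

    The per-sample error vector (eps_1, ..., eps_t) is mean-zero multivariate
    normal with exchangeable covariance error_sd^2 [(1 - rho) I + rho J];
    rows (samples) are independent.
    """
    n = genotypes.n_samples
    h = np.asarray(h, dtype=float)
    if covariates.values.shape[0] != n or h.shape != (n,):
        raise ValueError("genotypes, covariates and h must share sample count")
    if t < 1:
        raise ValueError("t must be >= 1")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    if error_sd <= 0:
        raise ValueError("error_sd must be positive")
    rng = np.random.default_rng(seed)
    # exchangeable errors: sqrt(1-rho) idiosyncratic + sqrt(rho) shared factor
    eps = np.sqrt(1.0 - rho) * rng.standard_normal((n, t))
    eps += np.sqrt(rho) * rng.standard_normal((n, 1))
    eps *= error_sd
    if covariates.values.shape[1] >= 2:
        fixed = 0.02 * covariates.values[:, 0] + 0.6 * covariates.values[:, 1]
    elif covariates.values.shape[1] == 1:
        fixed = 0.02 * covariates.values[:, 0]
    else:
        fixed = np.zeros(n)
    y = (fixed + h)[:, None] + eps
    return PhenotypeMatrix(values=y, names=[f"Y{k + 1}" for k in range(t)])
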