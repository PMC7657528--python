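# Methods

## Problem

A biological pathway maps to a set of SNPs; complex traits are usually
measured as several correlated quantitative phenotypes.  `fcmsku` tests, for
each pathway, whether its SNP set is associated with the phenotype vector as
a whole, in two stages:

1. **mSKU** — for one phenotype, a maximum kernel-based U-statistic over a
   bundle of candidate kernels, with an asymptotic multivariate-normal null
   for the maximum (no permutation needed).
2. **FC** — the per-phenotype p-values for a pathway are combined with the
   Fisher statistic, whose null under phenotype dependence is moment-matched
   to a gamma distribution (Brown's method).

## The kernel U-statistic

For a pathway submatrix X (n samples × s SNPs, additive 0/1/2 coding) and a
kernel K_m from the candidate bundle, let K̃ be the doubly centred kernel
matrix (HKH, H = I − 11ᵀ/n) and let e be the OLS residuals of the phenotype
on an intercept plus covariates.  The statistic is the degenerate
second-order U-statistic

    T_m = 1/(n(n−1)) Σ_{i≠j} K̃_ij e_i e_j,

with plug-in variance V_m = 2/(n²(n−1)²) Σ_{i≠j} K̃_ij² e_i² e_j², and
Q_m = T_m/√V_m.  Q_m is exactly invariant to positive rescaling of the
kernel or residuals, to adding a constant to the phenotype, and to affine
transformation of the covariate columns.  Under the null and with enough
SNPs in the pathway (so the centred kernel's eigenvalue spectrum is spread),
Q_m is asymptotically standard normal.

The test statistic is Q_max = max_m Q_m.  The correlation of (Q_1,…,Q_M)
under the null is estimated by the same plug-in device,

    ρ̂_kl = Σ_{i≠j} K̃⁽ᵏ⁾_ij K̃⁽ˡ⁾_ij e_i² e_j² / √(·√·),

repaired to the nearest correlation matrix (eigenvalue clipping) if
numerically indefinite.  The p-value is the equicoordinate upper tail
1 − P(Z ≤ q_max 1_M), Z ~ N(0, Ω̂), computed with the Genz quasi-Monte-Carlo
rectangle algorithm at absolute tolerance 1e−5 with a fixed internal seed,
so repeated calls agree to reported precision.  The test is one-sided:
large positive Q_max rejects.

**Candidate bundle (M = 3 by default):** linear (c = 0), Gaussian with the
median-heuristic bandwidth (σ² = median pairwise squared distance / 2, ties
at zero excluded), and polynomial of degree 2 (α = 1, c = 1).  Genotypes
enter as-is; per-SNP standardization is available as an option.

**Screening.**  The "semi-supervised" step regresses an auxiliary label
(binary → logistic, quantitative → least squares) on each pathway SNP and
keeps SNPs with coefficient p < α_m (default 0.05).  The label must be
distinct from the phenotype under test — screening on the tested phenotype
would invalidate the null.  With no label supplied, screening is skipped;
an empty screened set falls back to the full pathway and is flagged rather
than silently returning p = 1.  Monomorphic SNPs get screening p = 1 and
are dropped before kernel construction.

## Combining phenotypes

With k marginal p-values, T = Σ −2 log p_i has mean μ = 2k.  Its variance is
4k plus twice the sum of pairwise covariances cov(−2 log p_i, −2 log p_j),
approximated by the Kost–McDermott cubic c(r) = r(3.263 + 0.710r + 0.027r²)
in the correlation r of the covariate-adjusted phenotypes (odd continuation
for r < 0; each term clipped to [−4, 4], σ² floored at 2k).  The global
p-value is the upper tail of Gamma(shape μ²/σ², scale σ²/μ).  With identity
correlation this is exactly the Fisher χ²_{2k} p-value; with k = 1 it
returns the marginal p.

The phenotype correlation (not the test-statistic correlation) is used as
the dependence input.  Under the null the kernel statistics for two
phenotypes with residual correlation r have correlation ≈ r², so this
choice overstates the dependence slightly and is mildly conservative; in
calibration runs it compensates the mild anti-conservativeness of the
normal approximation to Q_max, and the combined test holds its level (see
the acceptance checks).

## Synthetic data generator

The generator emulates a single-pathway quantitative-trait study:

- **Genotypes.**  Per SNP a MAF q ~ Uniform(maf_low, maf_high), default
  (0.05, 0.5).  Each of two haplotypes per sample is a latent standard
  Gaussian AR(1) process across SNPs (adjacent correlation `ld_r`, default
  0.5) thresholded at Φ⁻¹(q); the sum of the two haplotype indicators gives
  genotype frequencies (1−q)², 2q(1−q), q² — Hardy–Weinberg marginals at
  any LD level.  The AR(1) + thresholding device reproduces the two
  features the test is sensitive to (marginal MAFs and local LD); it does
  not model recombination hot-spots, population structure or relatedness.
- **Covariates.**  Z1 ~ N(2, 1), Z2 ~ Bernoulli(0.6), independent.
- **Phenotypes.**  Y_ki = 0.02 Z_i1 + 0.6 Z_i2 + h(X_i) + ε_ki with t = 5
  phenotypes by default and exchangeable errors
  cov = error_sd²[(1−ρ)I + ρJ], error_sd = 1, ρ ∈ {0.2, 0.7} in the study.
- **Genetic effects h(·).**  `null`: 0.  `M` (sparse nonlinear):
  0.27(x₅−x₁₀) + cos(x₁₀)exp(−x₁₀²/5).  `N` (sparse linear):
  0.37x₅ + 0.62x₁₀ − 0.06x₁₅.  `P`/`Q` (polygenic): b_P Σ_{H_P} α_m x_m +
  b_Q Σ_{H_Q} β_mm' x_m x_m' with 60 main-effect SNPs, 90 interaction
  pairs, coefficients Uniform(0, 0.02) drawn once per study and frozen
  across replicates; (b_P, b_Q) = (0.07, 2.3) for P and (3.8, 0) for Q.
  SNP subscripts are 1-based.

Replicate seeds derive from (master seed, replicate index) through a
`SeedSequence`, so any subset of replicates reproduces independently.

## Simulation harness and problem sizes

`simulation_study` runs B fresh replicates of one study cell, treats the
whole simulated SNP block as one pathway, tests each phenotype with mSKU
(screening off — the generator has no auxiliary label) and FC-combines the
marginals; it reports the rejection proportion with its binomial standard
error.  The phenotype correlation fed to FC is re-estimated within each
replicate.

The packaged checks use: 1000 replicates per type-I-error cell (the study's
own replicate count) for (p, n, ρ) ∈ {(400, 200, 0.2), (400, 200, 0.7),
(400, 400, 0.2), (800, 200, 0.2), (800, 200, 0.7)}; 300 replicates for the
sample-size power ordering under scenario N and 150 per scenario for the
power-vs-null margins at n = 800; 1000 null studies for p-value uniformity;
50 datasets × 2000 permutations for the permutation cross-check; and
200,000 Monte-Carlo draws for the multivariate-normal tail oracle.

## Numerical choices and edge cases

- Kernel matrices are symmetrized exactly ((K + Kᵀ)/2) after evaluation;
  centring is idempotent by construction.
- V̂ = 0 (no off-diagonal kernel signal, or fewer than two nonzero
  residuals) raises a degenerate-statistic error instead of returning a
  p-value.
- Correlation matrices (Ω̂ and the phenotype correlation) are repaired by
  eigenvalue clipping at ~1e−8 followed by rescaling to unit diagonal.
- Marginal p-values of exactly 0 (the MVN rectangle saturating at 1) are
  floored at the smallest positive float before taking logs, with a
  warning.
- Rank-deficient covariate designs and constant phenotype columns raise
  errors naming the offending columns.
- Missing genotypes on file input are imputed to the SNP's rounded mean
  (count logged); real-data QC beyond that (MAF/HWE filters) is out of
  scope of the readers.

## Known limitations

- The normal limit of Q needs pathways with enough polymorphic SNPs;
  for very small SNP sets (≲ 20) the asymptotic p-value is conservative in
  the bulk and the test should be interpreted cautiously.  The right tail
  of Q is mildly heavier than normal (spectral skewness ~ 1/√rank), and
  covariate-estimated residuals give Q a small positive mean, making the
  marginal test slightly anti-conservative at level 0.05 for moderate
  pathway sizes.  The combined test holds its level at 0.05 as noted
  above, but the *bulk* distribution of the combined null p-value is not
  exactly uniform: Fisher's −2 Σ log pᵢ accumulates the marginal
  approximation error across phenotypes, so combined p-values should be
  read as test decisions at conventional levels rather than as exact
  tail probabilities.  An exact finite-sample null for T under covariate
  adjustment would remove this; it is not available in closed form here.
- Binary phenotypes, rare-variant weighting and exact small-sample nulls
  are not supported.
- The Kost–McDermott polynomial is an approximation fitted for p-values
  from normal test statistics; `brown_moments` isolates it so an exact
  covariance could be substituted.
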