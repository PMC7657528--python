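"""The max-kernel U-statistic test: brute-force oracles for T, V and the
inter-kernel correlation, screening behaviour, invariances, and the
asymptotic p-value reductions."""

import numpy as np
import pytest
from scipy import stats

from fcmsku import (
    CovariateMatrix,
    GenotypeMatrix,
    KernelMatrix,
    KernelSpec,
    DegenerateStatisticError,
    ResidualVector,
    center_kernel,
    default_kernel_bundle,
    kernel_correlation,
    kernel_matrix,
    ku_statistic,
    max_statistic_pvalue,
    msku_test,
    residualize,
    screen_snps,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotypes,
)


def _centered(values):
    K = KernelMatrix(values=np.asarray(values, float), spec=KernelSpec("linear"))
    K.centered = True  # treat as already centred for oracle tests
    return K


def _brute_force_tvq(K, e):
    n = len(e)
    T = sum(K[i, j] * e[i] * e[j] for i in range(n) for j in range(n) if i != j)
    T /= n * (n - 1)
    V = sum(K[i, j] ** 2 * e[i] ** 2 * e[j] ** 2
            for i in range(n) for j in range(n) if i != j)
    V *= 2.0 / (n * (n - 1)) ** 2
    return T, V, T / np.sqrt(V)


class TestKuStatistic:
    def test_frozen_four_sample_example(self):
        """Off-diagonal-ones kernel with e = (1,-1,1,-1): T = -1/3,
        V = 1/6, Q = -1/sqrt(6)/ (1/3)... computed by the double loop."""
        K = np.ones((4, 4)) - np.eye(4)
        e = np.array([1.0, -1.0, 1.0, -1.0])
        s = ku_statistic(_centered(K), ResidualVector(e))
        assert s.t_n == pytest.approx(-1 / 3)
        assert s.v_hat == pytest.approx(1 / 6)
        assert s.q == pytest.approx(-(1 / 3) / np.sqrt(1 / 6))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 20)
        X = rng.integers(0, 3, size=(n, 4)).astype(float)
        e = rng.standard_normal(n)
        K = center_kernel(kernel_matrix(X, KernelSpec("gaussian")))
        s = ku_statistic(K, ResidualVector(e))
        T, V, Q = _brute_force_tvq(K.values, e)
        assert s.t_n == pytest.approx(T, abs=1e-10)
        assert s.v_hat == pytest.approx(V, abs=1e-10)
        assert s.q == pytest.approx(Q, abs=1e-10)

    def test_scale_invariance(self, rng):
        K = np.ones((6, 6)) + np.diag(np.arange(6.0))
        e = rng.standard_normal(6)
        q1 = ku_statistic(_centered(K), ResidualVector(e)).q
        q2 = ku_statistic(_centered(10.0 * K), ResidualVector(3.0 * e)).q
        assert q2 == pytest.approx(q1, abs=1e-12)

    def test_degenerate_inputs(self):
        diag_only = np.diag(np.arange(1.0, 5.0))
        with pytest.raises(DegenerateStatisticError):
            ku_statistic(_centered(diag_only), ResidualVector(np.ones(4)))
        K = np.ones((4, 4))
        with pytest.raises(DegenerateStatisticError):
            ku_statistic(_centered(K), ResidualVector(np.zeros(4)))


class TestKernelCorrelation:
    def test_identical_and_scaled_kernels(self, rng):
        X = rng.integers(0, 3, size=(10, 5)).astype(float)
        e = ResidualVector(rng.standard_normal(10))
        K = center_kernel(kernel_matrix(X, KernelSpec("linear")))
        K2 = KernelMatrix(values=2.5 * K.values, spec=K.spec, centered=True)
        om = kernel_correlation([K, K, K2], e)
        assert om == pytest.approx(np.ones((3, 3)))

    def test_disjoint_support_gives_zero(self):
        """Off-diagonal supports that never overlap give rho = 0."""
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        B = np.zeros((4, 4))
        B[2, 3] = B[3, 2] = 1.0
        e = ResidualVector(np.array([1.0, 2.0, -1.0, 0.5]))
        om = kernel_correlation([_centered(A), _centered(B)], e)
        assert om[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.diag(om) == pytest.approx([1.0, 1.0])

    def test_correlation_matches_direct_summation(self, rng):
        X = rng.integers(0, 3, size=(12, 6)).astype(float)
        e = rng.standard_normal(12)
        Ks = [center_kernel(kernel_matrix(X, s)) for s in default_kernel_bundle()]
        om = kernel_correlation(Ks, ResidualVector(e))
        u = e**2
        for a in range(3):
            for b in range(3):
                Ka, Kb = Ks[a].values.copy(), Ks[b].values.copy()
                np.fill_diagonal(Ka, 0)
                np.fill_diagonal(Kb, 0)
                num = ((Ka * Kb) * np.outer(u, u)).sum()
                den = np.sqrt(((Ka**2) * np.outer(u, u)).sum()
                              * ((Kb**2) * np.outer(u, u)).sum())
                assert om[a, b] == pytest.approx(num / den, abs=1e-8)
        assert np.abs(om[np.triu_indices(3, 1)]).max() <= 1 + 1e-10
        assert np.diag(om) == pytest.approx([1.0, 1.0, 1.0])


class TestMaxStatisticPvalue:
    def test_single_kernel_is_normal_tail(self):
        assert max_statistic_pvalue(1.6449, np.eye(1)) == pytest.approx(
            0.05, abs=1e-4
        )
        assert max_statistic_pvalue(1.6449, np.eye(1)) == pytest.approx(
            stats.norm.sf(1.6449), abs=1e-12
        )

    def test_independent_pair_factorizes(self):
        p = max_statistic_pvalue(1.6449, np.eye(2))
        assert p == pytest.approx(1 - stats.norm.cdf(1.6449) ** 2, abs=1e-4)

    def test_perfectly_correlated_pair_collapses(self):
        om = np.array([[1.0, 1.0], [1.0, 1.0]])
        p2 = max_statistic_pvalue(1.3, om)
        p1 = max_statistic_pvalue(1.3, np.eye(1))
        assert p2 == pytest.approx(p1, abs=2e-4)

    def test_invalid_omega(self):
        with pytest.raises(ValueError):
            max_statistic_pvalue(1.0, np.array([[2.0, 0.0], [0.0, 1.0]]))


class TestResidualize:
    def test_intercept_only_demeans(self, rng):
        y = rng.standard_normal(30) + 5
        r = residualize(y, CovariateMatrix.empty(30))
        assert np.allclose(r.values, y - y.mean())

    def test_exact_fit_gives_zero_residuals(self, rng):
        z = rng.standard_normal(40)
        covar = CovariateMatrix(z[:, None], ["z"])
        r = residualize(3.0 - 2.0 * z, covar)
        assert np.abs(r.values).max() < 1e-10

    def test_orthogonality_to_design(self, rng):
        Z = rng.standard_normal((100, 2))
        covar = CovariateMatrix(Z, ["a", "b"])
        r = residualize(rng.standard_normal(100), covar)
        assert abs(r.values.sum()) < 1e-8
        assert np.abs(Z.T @ r.values).max() < 1e-8

    def test_collinear_design_raises(self, rng):
        z = rng.standard_normal(20)
        covar = CovariateMatrix(np.column_stack([z, 2 * z]), ["a", "b"])
        with pytest.raises(ValueError, match="rank-deficient"):
            residualize(rng.standard_normal(20), covar)


class TestScreening:
    def test_threshold_one_keeps_everything(self, medium_dataset, rng):
        geno, _ = medium_dataset
        label = rng.standard_normal(geno.n_samples)
        res = screen_snps(geno, label, alpha_m=1.0)
        assert res.kept_snp_ids == geno.snp_ids
        assert not res.fallback

    def test_null_label_keeps_alpha_fraction(self):
        geno = simulate_genotypes(300, 1000, ld_r=0.0, seed=21)
        label = np.random.default_rng(22).standard_normal(300)
        res = screen_snps(geno, label, alpha_m=0.05)
        kept = len(res.kept_snp_ids)
        assert abs(kept - 50) < 3 * np.sqrt(1000 * 0.05 * 0.95)
        assert res.label_type == "quantitative"

    def test_associated_snp_usually_kept(self):
        """A SNP with log-OR 1 on a binary label survives screening."""
        kept = 0
        reps = 40
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            g = rng.binomial(2, 0.3, size=500)
            logit = -0.5 + 1.0 * g
            y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
            geno = GenotypeMatrix(g[:, None], ["rs1"], [f"i{k}" for k in range(500)])
            res = screen_snps(geno, y.astype(float), alpha_m=0.05)
            kept += "rs1" in res.kept_snp_ids and not res.fallback
            assert res.label_type == "binary"
        assert kept >= 0.95 * reps

    def test_monomorphic_snp_never_kept(self):
        vals = np.column_stack([np.ones(50, int), np.random.default_rng(3).integers(0, 3, 50)])
        geno = GenotypeMatrix(vals, ["mono", "poly"], [f"i{k}" for k in range(50)])
        res = screen_snps(geno, np.random.default_rng(4).standard_normal(50), alpha_m=0.9999)
        assert res.per_snp_pvalues["mono"] == 1.0
        assert "mono" not in res.kept_snp_ids

    def test_empty_screen_falls_back(self, medium_dataset, rng):
        geno, _ = medium_dataset
        label = rng.standard_normal(geno.n_samples)
        res = screen_snps(geno, label, alpha_m=1e-12)
        assert res.fallback and res.kept_snp_ids == geno.snp_ids


class TestMskuTest:
    def _dataset(self, n=150, p=25, seed=5):
        geno = simulate_genotypes(n, p, seed=seed)
        covar = simulate_covariates(n, seed=seed + 1)
        pheno = simulate_phenotypes(geno, covar, np.zeros(n), t=1, seed=seed + 2)
        return geno, covar, pheno.values[:, 0]

    def test_determinism(self):
        geno, covar, y = self._dataset()
        bundle = default_kernel_bundle()
        r1 = msku_test(geno, geno.snp_ids, y, covar, bundle)
        r2 = msku_test(geno, geno.snp_ids, y, covar, bundle)
        assert r1.p_value == r2.p_value
        assert r1.q_max == r2.q_max
        assert r1.q_max == pytest.approx(max(s.q for s in r1.per_kernel))

    def test_invariance_to_phenotype_shift_and_covariate_affine(self):
        geno, covar, y = self._dataset()
        bundle = default_kernel_bundle()
        base = msku_test(geno, geno.snp_ids, y, covar, bundle)
        shifted = msku_test(geno, geno.snp_ids, y + 7.5, covar, bundle)
        A = np.array([[2.0, 1.0], [0.5, -1.0]])
        covar2 = CovariateMatrix(covar.values @ A + [3.0, -2.0], covar.names)
        affine = msku_test(geno, geno.snp_ids, y, covar2, bundle)
        assert shifted.q_max == pytest.approx(base.q_max, abs=1e-9)
        assert affine.q_max == pytest.approx(base.q_max, abs=1e-9)
        assert affine.p_value == pytest.approx(base.p_value, abs=1e-9)

    def test_monomorphic_pathway_snps_dropped(self):
        geno, covar, y = self._dataset()
        vals = geno.values.copy()
        vals[:, 0] = 1  # make first SNP monomorphic
        geno2 = GenotypeMatrix(vals, geno.snp_ids, geno.sample_ids)
        res = msku_test(geno2, geno2.snp_ids, y, covar, default_kernel_bundle())
        assert res.snps_used == geno.n_snps - 1

    def test_missing_pathway_snps_raise(self):
        geno, covar, y = self._dataset()
        with pytest.raises(KeyError):
            msku_test(geno, ["nope1", "nope2"], y, covar, default_kernel_bundle())

    def test_screening_with_independent_label_keeps_null_uniform(self):
        """1000 screened null tests give Uniform(0,1) p-values (KS at 0.01)."""
        # pathway large enough for the normal limit of Q (many kept SNPs)
        pvals = []
        for rep in range(1000):
            rng = np.random.default_rng(50000 + rep)
            geno = simulate_genotypes(150, 250, seed=60000 + rep)
            covar = simulate_covariates(150, seed=70000 + rep)
            pheno = simulate_phenotypes(geno, covar, np.zeros(150), t=1,
                                        seed=80000 + rep)
            label = rng.standard_normal(150)
            res = msku_test(geno, geno.snp_ids, pheno.values[:, 0], covar,
                            [KernelSpec("linear")], screening_label=label,
                            alpha_m=0.5)
            assert res.snps_used < 250  # screening actually dropped SNPs
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_grows_with_sample_size(self):
        """A sparse linear signal is detected more often at n = 800 than 200."""
        rates = {}
        for n in (200, 800):
            hits = 0
            B = 60
            for rep in range(B):
                geno = simulate_genotypes(n, 30, seed=90000 + rep)
                covar = simulate_covariates(n, seed=91000 + rep)
                from fcmsku import scenario_h

                h = scenario_h(geno, "N")
                pheno = simulate_phenotypes(geno, covar, h, t=1, seed=92000 + rep)
                res = msku_test(geno, geno.snp_ids, pheno.values[:, 0], covar,
                                default_kernel_bundle())
                hits += res.p_value < 0.05
            rates[n] = hits / B
        assert rates[800] > rates[200]
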