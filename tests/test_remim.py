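"""REML variance components and the linear score test."""

import numpy as np
import pytest
from scipy import linalg

import polyqtl as pq
from polyqtl.remim import RestrictedData, _lowrank_reml


def _qr_contrast_basis(n, seed=0):
    """An alternative orthonormal basis of the complement of 1."""
    rng = np.random.default_rng(seed)
    M = np.column_stack([np.ones(n), rng.standard_normal((n, n - 1))])
    Q, _ = np.linalg.qr(M)
    return Q[:, 1:].T


class TestRestrictedTransform:
    def test_two_individuals(self):
        A = pq.restricted_transform(2)
        assert np.allclose(np.abs(A), 1 / np.sqrt(2))

    @pytest.mark.parametrize("n", [2, 5, 298])
    def test_conditions(self, n):
        A = pq.restricted_transform(n)
        assert A.shape == (n - 1, n)
        assert np.allclose(A @ np.ones(n), 0.0, atol=1e-10)
        assert np.allclose(A @ A.T, np.eye(n - 1), atol=1e-10)

    def test_rejects_singletons(self):
        with pytest.raises(ValueError):
            pq.restricted_transform(1)


def test_score_invariant_to_contrast_basis(grid298):
    """Score statistics agree to 1e-8 under two different valid A bases."""
    y = pq.simulate_trait(
        grid298, pq.TraitSpec(qtl=((1, 40.0, 0.75),)), rng=1).y
    G = [grid298.G(grid298.map.locate(1, 40.0))]
    s1 = pq.score_statistic(RestrictedData.build(y, G), 0, [0.0])
    A2 = _qr_contrast_basis(y.size)
    s2 = pq.score_statistic(RestrictedData.build(y, G, A=A2), 0, [0.0])
    assert s1 == pytest.approx(s2, abs=1e-8)
    p1 = pq.score_pvalue(RestrictedData.build(y, G), 0, [0.0]).p_value
    p2 = pq.score_pvalue(RestrictedData.build(y, G, A=A2), 0, [0.0]).p_value
    assert p1 == pytest.approx(p2, rel=1e-6)


class TestREML:
    def test_no_kernels_closed_form(self, rng):
        y = rng.standard_normal(50) * 2.0 + 3.0
        fit = pq.reml_fit(y, [])
        assert fit.mu == pytest.approx(y.mean())
        assert fit.sigma2 == pytest.approx(y.var(ddof=1))

    def test_fitted_likelihood_beats_null(self, grid298):
        y = pq.simulate_trait(
            grid298, pq.TraitSpec(qtl=((2, 20.0, 1.0),)), rng=2).y
        G = grid298.G(grid298.map.locate(2, 20.0))
        fit = pq.reml_fit(y, [G])
        null = pq.reml_fit(y, [np.zeros_like(G)])
        assert fit.loglik >= null.loglik - 1e-9

    def test_kernel_scaling_leaves_variance_invariant(self, grid298):
        y = pq.simulate_trait(
            grid298, pq.TraitSpec(qtl=((3, 100.0, 1.0),)), rng=3).y
        G = grid298.G(grid298.map.locate(3, 100.0))
        fit1 = pq.reml_fit(y, [G])
        fit4 = pq.reml_fit(y, [4.0 * G])
        assert fit4.tau[0] == pytest.approx(fit1.tau[0] / 4.0, rel=1e-4)
        assert fit4.qtl[0].sigma2_q * 4.0 == pytest.approx(
            fit1.qtl[0].sigma2_q, rel=1e-4)
        assert fit4.sigma2 == pytest.approx(fit1.sigma2, rel=1e-6)

    def test_rejects_indefinite_kernel(self):
        y = np.arange(6.0)
        bad = -np.eye(6)
        with pytest.raises(ValueError):
            pq.reml_fit(y, [bad])

    def test_parameter_recovery_median_within_30_percent(self, grid298):
        """sigma_q^2 = 1.5, sigma^2 = 1, n = 298: median over 50 fits."""
        q = grid298.map.locate(2, 60.0)
        G = grid298.G(q)
        rng = np.random.default_rng(42)
        spec = pq.TraitSpec(qtl=((2, 60.0, 1.5),), residual_variance=1.0)
        est = [
            pq.reml_fit(pq.simulate_trait(grid298, spec, rng).y, [G]).qtl[0].sigma2_q
            for _ in range(50)
        ]
        assert np.median(est) == pytest.approx(1.5, rel=0.30)

    def test_lowrank_path_matches_dense(self, grid298):
        y = pq.simulate_trait(
            grid298, pq.TraitSpec(qtl=((1, 30.0, 0.8), (2, 80.0, 0.6))), rng=4).y
        idx = [grid298.map.locate(1, 30.0), grid298.map.locate(2, 80.0)]
        dense = pq.reml_fit(y, [grid298.G(i) for i in idx])
        A = pq.restricted_transform(y.size)
        X = np.concatenate([grid298.X[i] for i in idx], axis=1)
        tau, sigma2, loglik = _lowrank_reml(A @ y, A @ X, 2, 6)
        assert np.allclose(tau, dense.tau, rtol=1e-4, atol=1e-6)
        assert sigma2 == pytest.approx(dense.sigma2, rel=1e-5)
        assert loglik == pytest.approx(dense.loglik, abs=1e-5)


class TestScore:
    def test_identity_kernel_scores_zero(self, rng):
        y = rng.standard_normal(40)
        data = RestrictedData.build(y, [np.eye(40)])
        assert pq.score_statistic(data, 0, [0.0]) == pytest.approx(0.0, abs=1e-10)

    def test_score_is_likelihood_derivative(self, small_pop):
        """S_r equals d l / d tau_r at tau_r -> 0+ (finite difference)."""
        grid = small_pop.grid
        y = pq.simulate_trait(
            grid, pq.TraitSpec(qtl=((1, 50.0, 1.0),)), rng=5).y
        G = grid.G(grid.map.locate(1, 50.0))
        data = RestrictedData.build(y, [G])
        s = pq.score_statistic(data, 0, [0.0])

        def loglik(tau):
            nt = data.n_tilde
            V = np.eye(nt) + tau * data.G_tilde[0]
            sign, logdet = np.linalg.slogdet(V)
            quad = data.y_tilde @ np.linalg.solve(V, data.y_tilde)
            return -0.5 * (nt * np.log(quad) + logdet)

        h = 1e-6
        deriv = (loglik(h) - loglik(0.0)) / h
        assert s == pytest.approx(deriv, rel=1e-4)

    def test_null_score_has_zero_mean(self, small_pop):
        """E[S] = 0 under H0 within 3 Monte-Carlo standard errors."""
        grid = small_pop.grid
        G = grid.G(5)
        rng = np.random.default_rng(6)
        n = grid.n
        scores = np.array([
            pq.score_statistic(RestrictedData.build(rng.standard_normal(n), [G]),
                               0, [0.0])
            for _ in range(1000)
        ])
        se = scores.std(ddof=1) / np.sqrt(scores.size)
        assert abs(scores.mean()) < 3 * se

    def test_pvalue_scale_free(self, small_pop):
        """Exact single-kernel P is unchanged by rescaling the phenotype."""
        grid = small_pop.grid
        y = pq.simulate_trait(grid, pq.TraitSpec(qtl=((1, 20.0, 0.6),)), rng=7).y
        G = [grid.G(grid.map.locate(1, 20.0))]
        p1 = pq.score_pvalue(RestrictedData.build(y, G), 0, [0.0]).p_value
        p2 = pq.score_pvalue(RestrictedData.build(7.3 * y, G), 0, [0.0]).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_exact_agrees_with_monte_carlo_on_small_instances(self):
        """|P_exact - P_mc| < 3 binomial SE on 20 random problems, n <= 50."""
        rng = np.random.default_rng(8)
        n_draws = 100_000
        for trial in range(20):
            n = int(rng.integers(20, 51))
            gmap = pq.GeneticMap(lg=[1], pos=[0.0])
            pop = pq.simulate_population(pq.MeiosisConfig(4, gmap, n, seed=trial))
            G = [pop.grid.G(0)]
            y = rng.standard_normal(n) + rng.uniform(0, 0.6) * pop.grid.X[0] @ \
                rng.standard_normal(8)
            data = RestrictedData.build(y, G)
            p = pq.score_pvalue(data, 0, [0.0], method="exact").p_value
            p_mc = pq.score_pvalue(data, 0, [0.0], method="mc", rng=trial).p_value
            se = np.sqrt(max(p_mc * (1 - p_mc), 1e-5) / n_draws)
            assert abs(p - p_mc) < 3.5 * se + 1e-4

    def test_nuisance_requires_zero_tested_component(self, small_pop):
        grid = small_pop.grid
        y = np.arange(grid.n, dtype=float)
        data = RestrictedData.build(y, [grid.G(0), grid.G(10)])
        with pytest.raises(ValueError):
            pq.score_statistic(data, 0, [0.5, 0.1])

    def test_type_one_error_calibration(self, small_pop):
        """Empirical size of the exact test at nominal 0.05 over 2000 nulls."""
        grid = small_pop.grid
        G = grid.G(8)
        A = pq.restricted_transform(grid.n)
        Gt = A @ G @ A.T
        lam = np.clip(np.linalg.eigvalsh(Gt), 0.0, None)
        nt = grid.n - 1
        from polyqtl.quadform import tail_probability
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(2000):
            yt = rng.standard_normal(nt)
            c = float(yt @ Gt @ yt) / float(yt @ yt)
            p = tail_probability(lam - c, method="exact")
            hits += p < 0.05
        assert 0.03 <= hits / 2000 <= 0.07
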