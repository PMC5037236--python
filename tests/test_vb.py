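"""Variational Bayes: bound primitives, coordinate ascent, oracle agreement."""

import numpy as np
import pytest

import irtkit
from irtkit.types import ResponseMatrix
from irtkit.vb import bound_value, fit_vb, sj_bound, sj_optimal_xi

from conftest import log_marginal_1pl


def _gauss_hermite_expectation(m, v, n=64):
    """E[log(1 + e^Z)], Z ~ N(m, v), by Gauss–Hermite quadrature (oracle)."""
    x, w = np.polynomial.hermite_e.hermegauss(n)
    z = m + np.sqrt(v) * x
    return float(np.sum(w * np.logaddexp(0.0, z)) / np.sqrt(2 * np.pi))


class TestSjBound:
    def test_zero_variance_collapses_to_exact(self):
        for m in (-3.0, 0.0, 1.7, 10.0):
            for xi in (0.1, 0.5, 0.9):
                assert sj_bound(m, 0.0, xi) == pytest.approx(
                    np.logaddexp(0.0, m), rel=1e-12
                )
        assert sj_bound(0.0, 0.0, 0.3) == pytest.approx(np.log(2.0))

    def test_symmetric_point_closed_form(self):
        # SJ(0, 1, 1/2) = log 2 + 1/8, and it dominates the true expectation
        val = sj_bound(0.0, 1.0, 0.5)
        assert val == pytest.approx(np.log(2.0) + 0.125, rel=1e-12)
        assert val >= _gauss_hermite_expectation(0.0, 1.0)

    def test_dominates_quadrature_on_grid(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = rng.uniform(-6, 6)
            v = rng.uniform(0, 9)
            xi = rng.uniform(0.02, 0.98)
            assert sj_bound(m, v, xi) >= _gauss_hermite_expectation(m, v) - 1e-10

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sj_bound(0.0, -0.1, 0.5)
        with pytest.raises(ValueError):
            sj_bound(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            sj_bound(0.0, 1.0, 0.0)


class TestSjOptimalXi:
    def test_symmetry_gives_half(self):
        for v in (0.0, 0.5, 3.0, 10.0):
            assert sj_optimal_xi(0.0, v) == pytest.approx(0.5, abs=1e-10)

    def test_large_mean_limit(self):
        assert sj_optimal_xi(30.0, 1.0) > 1 - 1e-6
        assert sj_optimal_xi(-30.0, 1.0) < 1e-6

    def test_matches_grid_argmin(self):
        m, v = 1.0, 2.0
        xi_star = sj_optimal_xi(m, v)
        grid = np.arange(1e-5, 1.0, 1e-5)
        vals = sj_bound(np.full_like(grid, m), np.full_like(grid, v), grid)
        assert xi_star == pytest.approx(grid[np.argmin(vals)], abs=1e-4)

    def test_satisfies_stationarity_fixed_point(self):
        rng = np.random.default_rng(12)
        m = rng.uniform(-4, 4, size=50)
        v = rng.uniform(0, 6, size=50)
        xi = sj_optimal_xi(m, v)
        from scipy.special import expit

        np.testing.assert_allclose(xi, expit(m + (1 - 2 * xi) * v / 2), atol=1e-9)


class TestFitVb:
    def test_single_cell_matches_quadrature(self):
        # S=1, L=1, matched prior, y=1: q_theta mean within 0.05 of the
        # exact posterior mean from dense 2-D quadrature
        from scipy.stats import norm
        from irtkit.model import irf

        g = np.linspace(-8, 8, 801)
        TH, B = np.meshgrid(g, g, indexing="ij")
        w = norm.pdf(TH) * norm.pdf(B) * irf(TH, B, 1.0)
        w /= w.sum()
        exact = (w * TH).sum()
        data = ResponseMatrix(np.array([[1]]))
        state, est = fit_vb(data, "1PL", irtkit.make_prior("matched", "1PL"))
        assert est.abilities[0] == pytest.approx(exact, abs=0.05)
        assert est.difficulties[0] == pytest.approx(-exact, abs=0.05)

    def test_item_swap_symmetry(self):
        # two items with identical response columns get identical factors
        rng = np.random.default_rng(13)
        col = (rng.random(120) < 0.55).astype(int)
        other = (rng.random(120) < 0.3).astype(int)
        y = np.column_stack([col, other, col])
        state, est = fit_vb(ResponseMatrix(y), "2PL", irtkit.make_prior("matched", "2PL"))
        assert est.difficulties[0] == pytest.approx(est.difficulties[2], abs=1e-6)
        assert est.discriminations[0] == pytest.approx(est.discriminations[2], abs=1e-6)
        assert state.v_b[0] == pytest.approx(state.v_b[2], rel=1e-5)

    @pytest.mark.parametrize(
        "model,regime",
        [("1PL", "matched"), ("1PL", "stdvague"), ("1PL", "hierarchical"),
         ("2PL", "matched"), ("2PL", "hierarchical")],
    )
    def test_bound_monotone_per_sweep(self, model, regime, small_1pl, small_2pl):
        truth, data = small_1pl if model == "1PL" else small_2pl
        prior = irtkit.make_prior(regime, model)
        state, _ = fit_vb(data, model, prior, max_sweeps=60)
        hist = np.array(state.bound_history)
        assert np.all(np.diff(hist) > -1e-8)

    def test_tracked_bound_matches_recomputation(self, small_2pl):
        _, data = small_2pl
        prior = irtkit.make_prior("hierarchical", "2PL")
        state, _ = fit_vb(data, "2PL", prior)
        assert state.bound == pytest.approx(bound_value(state, data, prior), abs=1e-6)

    def test_perturbing_a_factor_decreases_bound(self, small_1pl):
        _, data = small_1pl
        prior = irtkit.make_prior("matched", "1PL")
        state, _ = fit_vb(data, "1PL", prior, tol=1e-10, max_sweeps=300)
        base = bound_value(state, data, prior)
        for delta in (0.05, -0.05):
            state.mu_theta[3] += delta
            perturbed = bound_value(state, data, prior)
            state.mu_theta[3] -= delta
            assert perturbed < base + 1e-10

    def test_bound_below_log_marginal(self):
        # variational objective <= exact log marginal likelihood (1PL,
        # where the moment match is exact and SJ is a true bound)
        truth = irtkit.draw_parameters(3, 2, "1PL", 101)
        data = irtkit.simulate_responses(truth, 101)
        prior = irtkit.make_prior("matched", "1PL")
        state, _ = fit_vb(data, "1PL", prior)
        logz = log_marginal_1pl(data, prior, n_grid=81, span=9.0)
        assert state.bound <= logz + 1e-6
        # a second, asymmetric instance
        truth2 = irtkit.draw_parameters(2, 3, "1PL", 707)
        data2 = irtkit.simulate_responses(truth2, 707)
        state2, _ = fit_vb(data2, "1PL", prior)
        logz2 = log_marginal_1pl(data2, prior, n_grid=81, span=9.0)
        assert state2.bound <= logz2 + 1e-6

    def test_hierarchical_gamma_update_formula(self, small_1pl):
        # Gamma factor for u_theta has shape 1 + S/2 and rate
        # 1 + E_q[sum (theta_i - m_theta)^2] / 2
        _, data = small_1pl
        prior = irtkit.make_prior("hierarchical", "1PL")
        state, _ = fit_vb(data, "1PL", prior)
        S = data.n_persons
        h = state.hyper["theta"]
        assert h["u_shape"] == pytest.approx(1 + S / 2)
        ess = (
            np.sum((state.mu_theta - h["m_mean"]) ** 2 + state.v_theta)
            + S * h["m_var"]
        )
        assert h["u_rate"] == pytest.approx(1 + ess / 2, rel=1e-9)

    def test_posterior_means_match_quadrature_tiny(self, tiny_oracle):
        y, oracle = tiny_oracle
        data = ResponseMatrix(y)
        for regime in ("matched", "stdvague", "hierarchical"):
            prior, means, _ = oracle[regime]
            state, est = fit_vb(data, "1PL", prior)
            got = np.concatenate([est.abilities, est.difficulties])
            want = np.array([means["theta1"], means["theta2"], means["theta3"],
                             means["b1"], means["b2"]])
            assert np.all(np.abs(got - want) < 0.05), (regime, got, want)

    def test_nonconvergence_flags_not_raises(self, small_2pl):
        _, data = small_2pl
        state, est = fit_vb(data, "2PL", irtkit.make_prior("matched", "2PL"),
                            max_sweeps=2)
        assert est.converged is False
        assert state.converged is False


class TestVbVsMcmc:
    def test_posterior_mean_agreement_matched_1pl(self, small_1pl):
        # the central empirical claim: VB posterior means track MCMC
        truth, data = small_1pl
        prior = irtkit.make_prior("matched", "1PL")
        _, vb_est = fit_vb(data, "1PL", prior)
        draws = irtkit.fit_mcmc(data, "1PL", prior, chains=1,
                                burnin=2500, keep=2500, seed=77)
        mc_est = irtkit.summarize(draws)
        for v, m in ((vb_est.abilities, mc_est.abilities),
                     (vb_est.difficulties, mc_est.difficulties)):
            assert np.corrcoef(v, m)[0, 1] > 0.99
            assert np.sqrt(np.mean((v - m) ** 2)) < 0.05
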