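"""Shared fixtures and independent oracles for the test suite.

The quadrature oracles here compute exact posterior summaries for tiny
instances by dense numerical integration; they are deliberately written
from the model density directly (no package estimation code) so they can
serve as independent checks on the MCMC and VB implementations.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import log_expit
from scipy.stats import norm

import irtkit
from irtkit.types import PriorConfig, ResponseMatrix


@pytest.fixture(scope="session")
def small_1pl():
    """A paired (truth, responses) 1PL dataset, S=250, L=10."""
    truth = irtkit.draw_parameters(250, 10, "1PL", 20240401)
    data = irtkit.simulate_responses(truth, 20240401)
    return truth, data


@pytest.fixture(scope="session")
def small_2pl():
    """A paired (truth, responses) 2PL dataset, S=250, L=10."""
    truth = irtkit.draw_parameters(250, 10, "2PL", 20240402)
    data = irtkit.simulate_responses(truth, 20240402)
    return truth, data


def informative_hier_prior(model):
    """Hierarchical regime with concentrated, proper hyperpriors.

    The study configuration uses a variance-1e6 hyper-mean prior and a
    Gamma(1, 1) precision hyperprior.  On 2-3-person instances those make
    the exact posterior unusable as a grid oracle: the near-flat
    hyper-mean leaves the common shift unconstrained, and the Gamma(1,1)
    precision gives the latents a heavy-tailed (low-df t-like) marginal
    whose posterior mean does not stabilize on any finite grid.  Oracle
    comparisons therefore tighten the hyperpriors to N(0, 1) and
    Gamma(50, 50); the hierarchical code paths under test (group priors,
    conjugate draws / closed-form factor updates) are identical.
    """
    cfg = irtkit.make_prior("hierarchical", model)
    return PriorConfig(
        regime=cfg.regime,
        model=cfg.model,
        hierarchical_ability=cfg.hierarchical_ability,
        hierarchical_difficulty=cfg.hierarchical_difficulty,
        hierarchical_discrimination=cfg.hierarchical_discrimination,
        hyper_mean_prior=(0.0, 1.0),
        hyper_precision_prior=(50.0, 50.0),
    )


@pytest.fixture(scope="session")
def tiny_oracle():
    """Exact posterior means for a 3x2 1PL instance, per prior regime.

    Computed once per session; shared by the MCMC and VB oracle tests.
    """
    y = np.array([[1, 1], [1, 0], [0, 0]])
    out = {}
    for regime in ("matched", "stdvague", "hierarchical"):
        prior = (
            informative_hier_prior("1PL")
            if regime == "hierarchical"
            else irtkit.make_prior(regime, "1PL")
        )
        means, sds = exact_posterior_1pl(y, prior, n_theta=31, span=6.0)
        out[regime] = (prior, means, sds)
    return y, out


def _group_log_prior_hier(X, v0, a0=1.0, b0=1.0, n_u=300):
    """log p(x_1..x_n) for x_j ~ N(m, 1/u), m ~ N(0, v0), u ~ Gamma(a0, b0).

    The m-integral is Gaussian and closed-form: the marginal of x is
    N(0, (1/u) I + v0 J), an equicorrelated normal whose density factors
    over the mean direction (variance 1/u + n v0) and the n-1 orthogonal
    directions (variance 1/u).  The u-integral is a log-spaced grid sum.
    ``X`` has the group members on the last axis.
    """
    from scipy.special import logsumexp

    X = np.asarray(X, dtype=float)
    n = X.shape[-1]
    flat = X.reshape(-1, n)
    from scipy.special import gammaln

    u = np.exp(np.linspace(np.log(1e-3), np.log(40.0), n_u))
    log_wu = a0 * np.log(b0) - gammaln(a0) + (a0 - 1.0) * np.log(u) - b0 * u
    s2_sum = flat.sum(axis=1) ** 2 / n          # squared norm along mean direction
    s2_orth = (flat**2).sum(axis=1) - s2_sum
    var_mean = 1.0 / u[:, None] + n * v0
    var_orth = 1.0 / u[:, None]
    ll = (
        -0.5 * (s2_sum[None, :] / var_mean + np.log(2 * np.pi * var_mean))
        - 0.5 * (s2_orth[None, :] / var_orth + (n - 1) * np.log(2 * np.pi * var_orth))
    )
    dlog = np.log(u[1]) - np.log(u[0])
    integrand = ll + log_wu[:, None] + np.log(u[:, None]) + np.log(dlog)
    return logsumexp(integrand, axis=0).reshape(X.shape[:-1])


def exact_posterior_1pl(y, prior, n_theta=31, span=6.0):
    """Exact posterior means/SDs for a tiny 1PL instance (S <= 3, L = 2).

    The ability axes are a dense S-dimensional grid.  For flat regimes
    the difficulty integrals factor per item and run over a wide 1-D grid
    (so the variance-1e3 vague prior is not truncated); under the
    hierarchical regime (with a proper hyper-mean prior, see
    ``informative_hier_prior``) both the ability S-tuple and the
    difficulty pair use the equicorrelated group prior, and the
    difficulty integral is a joint 2-D grid.
    """
    from scipy.special import logsumexp

    y = np.asarray(y)
    S, L = y.shape
    assert L == 2 and S <= 3
    hier = prior.regime == "hierarchical"
    g = np.linspace(-span, span, n_theta)
    theta_axes = np.meshgrid(*([g] * S), indexing="ij")
    theta_flat = np.stack([t.ravel() for t in theta_axes], axis=1)  # (G, S)
    G = theta_flat.shape[0]

    # accumulate, chunked over the ability grid, the log-normalizer and
    # the b-moments of the conditional posterior given each theta tuple
    logZ = np.zeros(G)
    mom1 = np.empty((G, 2))
    mom2 = np.empty((G, 2))
    if hier:
        v0 = prior.hyper_mean_prior[1]
        a0, b0 = prior.hyper_precision_prior
        lp_theta = _group_log_prior_hier(theta_flat, v0, a0, b0)
        gb = np.linspace(-span, span, 61)
        B1, B2 = np.meshgrid(gb, gb, indexing="ij")
        b_pairs = np.stack([B1.ravel(), B2.ravel()], axis=1)  # (NB, 2)
        lp_b = _group_log_prior_hier(b_pairs, v0, a0, b0)
        chunk = max(1, int(2e6 // len(lp_b)))
        for lo in range(0, G, chunk):
            th = theta_flat[lo:lo + chunk]  # (c, S)
            ll = np.broadcast_to(lp_b[None, :], (len(th), len(lp_b))).copy()
            for i in range(S):
                for k in range(2):
                    eta = th[:, i][:, None] - b_pairs[None, :, k]
                    ll += log_expit(eta) if y[i, k] == 1 else log_expit(-eta)
            lz = logsumexp(ll, axis=1)
            w = np.exp(ll - lz[:, None])
            logZ[lo:lo + chunk] = lz
            mom1[lo:lo + chunk] = w @ b_pairs
            mom2[lo:lo + chunk] = w @ b_pairs**2
    else:
        mt, vt = prior.ability_prior
        mb, vb = prior.difficulty_prior
        lp_theta = norm.logpdf(theta_flat, mt, np.sqrt(vt)).sum(axis=1)
        b_half = max(6.0, 5.0 * np.sqrt(vb))
        gb = np.linspace(-b_half, b_half, 2001)
        lb1 = norm.logpdf(gb, mb, np.sqrt(vb))
        chunk = max(1, int(2e6 // len(gb)))
        for lo in range(0, G, chunk):
            th = theta_flat[lo:lo + chunk]
            for k in range(2):  # items factor given the abilities
                ll = np.broadcast_to(lb1[None, :], (len(th), len(gb))).copy()
                for i in range(S):
                    eta = th[:, i][:, None] - gb[None, :]
                    ll += log_expit(eta) if y[i, k] == 1 else log_expit(-eta)
                lz = logsumexp(ll, axis=1)
                w = np.exp(ll - lz[:, None])
                logZ[lo:lo + chunk] += lz
                mom1[lo:lo + chunk, k] = w @ gb
                mom2[lo:lo + chunk, k] = w @ gb**2

    log_post = lp_theta + logZ
    log_post -= log_post.max()
    wt = np.exp(log_post)
    wt /= wt.sum()

    means, sds = {}, {}
    for i in range(S):
        mean = float(wt @ theta_flat[:, i])
        var = float(wt @ theta_flat[:, i] ** 2) - mean**2
        means[f"theta{i+1}"], sds[f"theta{i+1}"] = mean, np.sqrt(max(var, 0.0))
    for k in range(2):
        mean = float(wt @ mom1[:, k])
        var = float(wt @ mom2[:, k]) - mean**2
        means[f"b{k+1}"], sds[f"b{k+1}"] = mean, np.sqrt(max(var, 0.0))
    return means, sds


def exact_posterior_2pl_1x1(y11, prior, n_grid=61, span=6.0, n_loga=41):
    """Exact posterior means for a 1-person 1-item 2PL instance (3-D grid)."""
    g = np.linspace(-span, span, n_grid)
    ma, va = prior.log_discrimination_prior
    la = np.linspace(ma - 4 * np.sqrt(va), ma + 4 * np.sqrt(va), n_loga)
    mt, vt = prior.ability_prior
    mb, vb = prior.difficulty_prior
    T = g[:, None, None]
    B = g[None, :, None]
    A = np.exp(la)[None, None, :]
    eta = A * (T - B)
    ll = log_expit(eta) if y11 == 1 else log_expit(-eta)
    logpost = (
        ll
        + norm.logpdf(T, mt, np.sqrt(vt))
        + norm.logpdf(B, mb, np.sqrt(vb))
        + norm.logpdf(la, ma, np.sqrt(va))[None, None, :]
    )
    logpost -= logpost.max()
    w = np.exp(logpost)
    w /= w.sum()
    return {
        "theta": float((w * T).sum()),
        "b": float((w * B).sum()),
        "loga": float((w * la[None, None, :]).sum()),
    }


def log_marginal_1pl(data: ResponseMatrix, prior, n_grid=121, span=7.0):
    """log marginal likelihood of a tiny 1PL dataset by dense quadrature.

    Integrates the likelihood against the (flat-regime) priors over every
    person and item parameter; feasible for S + L <= 5 or so.
    """
    y = data.entries
    S, L = y.shape
    g = np.linspace(-span, span, n_grid)
    dg = g[1] - g[0]
    mt, vt = prior.ability_prior
    mb, vb = prior.difficulty_prior
    # iterate over item-parameter grid combos, integrating persons independently
    from itertools import product

    from scipy.special import logsumexp

    lb = norm.logpdf(g, mb, np.sqrt(vb)) + np.log(dg)
    lt = norm.logpdf(g, mt, np.sqrt(vt)) + np.log(dg)
    total = []
    for combo in product(range(n_grid), repeat=L):
        b = g[list(combo)]
        eta = g[:, None] - b[None, :]  # theta-grid x items
        ll_cells = np.where(y[:, None, :] == 1, log_expit(eta)[None], log_expit(-eta)[None])
        person_int = logsumexp(ll_cells.sum(axis=2) + lt[None, :], axis=1)
        total.append(person_int.sum() + sum(lb[c] for c in combo))
    return float(logsumexp(np.array(total)))
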