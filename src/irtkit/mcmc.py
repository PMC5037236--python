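"""Metropolis-within-Gibbs sampling for 1PL/2PL models under all prior regimes.

Latent abilities, difficulties, and (for 2PL) log-discriminations are
updated by univariate Gaussian random-walk Metropolis steps against their
full conditionals; under the hierarchical regime the normal-gamma
hyperparameters are drawn exactly from their conjugate full conditionals.
Proposal standard deviations adapt during burn-in only (targeting
acceptance rates between 0.3 and 0.5), leaving the post-burn-in chain a
valid fixed-kernel Markov chain.

The default chain protocol discards 5000 burn-in iterations and retains
the next 1000; point estimates are posterior means and reported SEs are
posterior standard deviations (see :func:`summarize`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_expit

from .types import ModelTag, ParameterEstimates, PriorConfig, ResponseMatrix

_ADAPT_WINDOW = 50
_ACC_LO, _ACC_HI = 0.3, 0.5
_SD_SHRINK, _SD_GROW = 0.8, 1.25


@dataclass
class ChainDraws:
    """Retained MCMC draws, shaped (retained, chains[, dim]) per parameter."""

    draws: dict
    burnin: int
    retained: int
    acceptance: dict = field(default_factory=dict)
    model: ModelTag = "2PL"
    prior: str = "matched"

    def parameter_names(self):
        return list(self.draws)


def _loglik_matrix(theta, b, a, y):
    eta = a[None, :] * (theta[:, None] - b[None, :])
    return np.where(y == 1, log_expit(eta), log_expit(-eta))


class _HierGibbs:
    """Conjugate normal-gamma full conditionals for a hierarchical block.

    For x_1..x_n ~ N(m, 1/u) with m ~ N(0, V0) and u ~ Gamma(a0, b0):

        m | x, u ~ N( u * sum(x) / (n u + 1/V0),  1 / (n u + 1/V0) )
        u | x, m ~ Gamma( a0 + n/2,  b0 + sum((x - m)^2) / 2 )
    """

    def __init__(self, hyper_mean_prior, hyper_precision_prior):
        self.tau0 = 1.0 / hyper_mean_prior[1]
        self.mu0 = hyper_mean_prior[0]
        self.a0, self.b0 = hyper_precision_prior

    def draw_mean(self, rng, x, u):
        n = len(x)
        prec = n * u + self.tau0
        mean = (u * x.sum() + self.tau0 * self.mu0) / prec
        return rng.normal(mean, 1.0 / np.sqrt(prec))

    def draw_precision(self, rng, x, m):
        shape = self.a0 + len(x) / 2.0
        rate = self.b0 + 0.5 * np.sum((x - m) ** 2)
        return rng.gamma(shape, 1.0 / rate)


def fit_mcmc(
    data: ResponseMatrix,
    model: ModelTag,
    prior: PriorConfig,
    chains: int = 1,
    burnin: int = 5000,
    keep: int = 1000,
    seed: int = 0,
) -> ChainDraws:
    """Run the Metropolis-within-Gibbs sampler.

    Initial values follow the study protocol: all location parameters at 0
    and hierarchical standard deviations at 1.  Each chain uses an
    independent child stream of ``seed``.
    """
    if prior.regime == "none":
        raise ValueError("MCMC requires a proper prior regime")
    if keep <= 0 or chains < 1:
        raise ValueError("need keep > 0 and chains >= 1")
    y = data.entries
    S, L = y.shape
    two_pl = model == "2PL"

    store = {
        "theta": np.empty((keep, chains, S)),
        "b": np.empty((keep, chains, L)),
    }
    if two_pl:
        store["loga"] = np.empty((keep, chains, L))
    hier = prior.regime == "hierarchical"
    if hier:
        for name in ["m_theta", "u_theta", "m_b", "u_b"] + (
            ["m_a", "u_a"] if two_pl else []
        ):
            store[name] = np.empty((keep, chains))
    acc_totals = {}

    for chain in range(chains):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(chain,)))
        )
        theta = np.zeros(S)
        b = np.zeros(L)
        loga = np.zeros(L)
        a = np.ones(L)

        if hier:
            hyp = _HierGibbs(prior.hyper_mean_prior, prior.hyper_precision_prior)
            m_th, u_th = 0.0, 1.0
            m_b_, u_b_ = 0.0, 1.0
            m_a_, u_a_ = 0.0, 1.0
        else:
            mt, vt = prior.ability_prior
            mb, vb = prior.difficulty_prior
            m_th, u_th = mt, 1.0 / vt
            m_b_, u_b_ = mb, 1.0 / vb
            if two_pl:
                ma, va = prior.log_discrimination_prior
                m_a_, u_a_ = ma, 1.0 / va

        sd_theta = np.full(S, 1.0)
        wide_b = (not hier) and prior.difficulty_prior[1] > 100.0
        sd_b = np.full(L, 2.5 if wide_b else 1.0)
        sd_loga = np.full(L, 0.5)
        acc_theta = np.zeros(S)
        acc_b = np.zeros(L)
        acc_loga = np.zeros(L)
        kept_acc = {"theta": 0.0, "b": 0.0, "loga": 0.0}

        # log-likelihood matrix of the current state, maintained across blocks
        M = _loglik_matrix(theta, b, a, y)
        for it in range(burnin + keep):
            adapting = it < burnin

            # --- ability block ---
            prop = theta + sd_theta * rng.standard_normal(S)
            M_prop = _loglik_matrix(prop, b, a, y)
            lp_cur = M.sum(axis=1) - 0.5 * u_th * (theta - m_th) ** 2
            lp_prop = M_prop.sum(axis=1) - 0.5 * u_th * (prop - m_th) ** 2
            acc = np.log(rng.random(S)) < lp_prop - lp_cur
            theta = np.where(acc, prop, theta)
            M = np.where(acc[:, None], M_prop, M)
            acc_theta += acc

            # --- difficulty block ---
            prop = b + sd_b * rng.standard_normal(L)
            M_prop = _loglik_matrix(theta, prop, a, y)
            lp_cur = M.sum(axis=0) - 0.5 * u_b_ * (b - m_b_) ** 2
            lp_prop = M_prop.sum(axis=0) - 0.5 * u_b_ * (prop - m_b_) ** 2
            acc = np.log(rng.random(L)) < lp_prop - lp_cur
            b = np.where(acc, prop, b)
            M = np.where(acc[None, :], M_prop, M)
            acc_b += acc

            # --- log-discrimination block (2PL) ---
            if two_pl:
                prop = loga + sd_loga * rng.standard_normal(L)
                a_prop = np.exp(prop)
                M_prop = _loglik_matrix(theta, b, a_prop, y)
                lp_cur = M.sum(axis=0) - 0.5 * u_a_ * (loga - m_a_) ** 2
                lp_prop = M_prop.sum(axis=0) - 0.5 * u_a_ * (prop - m_a_) ** 2
                acc = np.log(rng.random(L)) < lp_prop - lp_cur
                loga = np.where(acc, prop, loga)
                M = np.where(acc[None, :], M_prop, M)
                a = np.exp(loga)
                acc_loga += acc

            # --- hyperparameters (exact conjugate Gibbs) ---
            if hier:
                m_th = hyp.draw_mean(rng, theta, u_th)
                u_th = hyp.draw_precision(rng, theta, m_th)
                m_b_ = hyp.draw_mean(rng, b, u_b_)
                u_b_ = hyp.draw_precision(rng, b, m_b_)
                if two_pl:
                    m_a_ = hyp.draw_mean(rng, loga, u_a_)
                    u_a_ = hyp.draw_precision(rng, loga, m_a_)

            if adapting and (it + 1) % _ADAPT_WINDOW == 0:
                for rates, sds in (
                    (acc_theta, sd_theta),
                    (acc_b, sd_b),
                    (acc_loga, sd_loga),
                ):
                    r = rates / _ADAPT_WINDOW
                    sds *= np.where(
                        r > _ACC_HI, _SD_GROW, np.where(r < _ACC_LO, _SD_SHRINK, 1.0)
                    )
                    rates[:] = 0.0

            if it == burnin:
                acc_theta[:] = 0.0
                acc_b[:] = 0.0
                acc_loga[:] = 0.0
            if it >= burnin:
                t = it - burnin
                store["theta"][t, chain] = theta
                store["b"][t, chain] = b
                if two_pl:
                    store["loga"][t, chain] = loga
                if hier:
                    store["m_theta"][t, chain] = m_th
                    store["u_theta"][t, chain] = u_th
                    store["m_b"][t, chain] = m_b_
                    store["u_b"][t, chain] = u_b_
                    if two_pl:
                        store["m_a"][t, chain] = m_a_
                        store["u_a"][t, chain] = u_a_

        kept_acc["theta"] = acc_theta.mean() / keep
        kept_acc["b"] = acc_b.mean() / keep
        if two_pl:
            kept_acc["loga"] = acc_loga.mean() / keep
        for k, v in kept_acc.items():
            acc_totals[k] = acc_totals.get(k, 0.0) + v / chains

    return ChainDraws(
        draws=store,
        burnin=burnin,
        retained=keep,
        acceptance=acc_totals,
        model=model,
        prior=prior.regime,
    )


def summarize(draws: ChainDraws) -> ParameterEstimates:
    """Posterior-mean point estimates with posterior-SD standard errors.

    Draws are pooled over retained iterations and chains; the SD uses the
    n-1 divisor.  2PL discriminations are summarized on the natural scale
    (mean and SD of exp(log a) draws).
    """
    if draws.retained < 2:
        raise ValueError("need at least 2 retained draws to summarize")

    def pool(name):
        arr = draws.draws[name]
        flat = arr.reshape(-1, arr.shape[-1]) if arr.ndim == 3 else arr.reshape(-1, 1)
        return flat.mean(axis=0), flat.std(axis=0, ddof=1)

    theta, se_theta = pool("theta")
    b, se_b = pool("b")
    if draws.model == "2PL":
        a_draws = np.exp(draws.draws["loga"])
        flat = a_draws.reshape(-1, a_draws.shape[-1])
        a, se_a = flat.mean(axis=0), flat.std(axis=0, ddof=1)
    else:
        L = len(b)
        a, se_a = np.ones(L), np.zeros(L)
    return ParameterEstimates(
        abilities=theta,
        difficulties=b,
        discriminations=a,
        se_abilities=se_theta,
        se_difficulties=se_b,
        se_discriminations=se_a,
        method="MCMC",
        prior=draws.prior,
        model=draws.model,
        info={"acceptance": draws.acceptance},
    )
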