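"""Mean-field variational Bayes for 1PL/2PL models via the Saul–Jordan bound.

The posterior is approximated by a fully factorized family: a Gaussian
factor per ability, per difficulty, and (2PL) per log-discrimination,
plus Gaussian/Gamma factors for the hierarchical hyperparameters.  The
intractable Bernoulli-logistic expectation E[log(1 + e^eta)] is replaced
by the Saul–Jordan upper bound with one variational parameter xi per
person-item cell, giving a tractable lower bound on the evidence that is
maximized by coordinate ascent:

* xi_ik is set to its optimal value given the current logit moments;
* each Gaussian factor takes damped Newton steps on (mean, log variance);
* hierarchical hyper-factors are updated in closed conjugate form.

For the 2PL the logit eta = a(theta - b) is not Gaussian under q; its
exact first two moments under the factorized q (using lognormal moments
of a) are matched to a Gaussian before applying the bound.  For the 1PL
(a = 1) the logit is exactly Gaussian and no approximation beyond
Saul–Jordan is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import digamma, expit, gammaln

from .types import ModelTag, ParameterEstimates, PriorConfig, ResponseMatrix

_XI_EPS = 1e-10
_NEWTON_INNER = 5
_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Saul–Jordan bound primitives
# ---------------------------------------------------------------------------

def sj_bound(m, v, xi):
    """Saul–Jordan upper bound on E[log(1 + e^Z)] for Z ~ N(m, v).

    SJ(m, v, xi) = xi*m + log( exp(-xi*m + xi^2 v/2)
                              + exp((1-xi)*m + (1-xi)^2 v/2) ),
    valid for 0 < xi < 1 and v >= 0; at v = 0 it collapses to the exact
    value log(1 + e^m) for every xi.
    """
    m = np.asarray(m, dtype=float)
    v = np.asarray(v, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if np.any(v < 0):
        raise ValueError("variance v must be nonnegative")
    if np.any((xi <= 0) | (xi >= 1)):
        raise ValueError("xi must lie strictly inside (0, 1)")
    t1 = -xi * m + xi**2 * v / 2.0
    t2 = (1.0 - xi) * m + (1.0 - xi) ** 2 * v / 2.0
    out = xi * m + np.logaddexp(t1, t2)
    return float(out) if out.ndim == 0 else out


def sj_optimal_xi(m, v):
    """The xi in (0,1) minimizing the Saul–Jordan bound.

    Solves the stationarity condition xi = sigma(m + (1 - 2 xi) v / 2) by
    Newton iteration on g(xi) = xi - sigma(...), which is strictly
    increasing in xi, so the root is unique.  Vectorized over inputs.
    """
    m = np.asarray(m, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("variance v must be nonnegative")
    xi = np.full(np.broadcast(m, v).shape, 0.5)
    for _ in range(60):
        s = expit(m + (1.0 - 2.0 * xi) * v / 2.0)
        g = xi - s
        gp = 1.0 + v * s * (1.0 - s)
        xi_new = np.clip(xi - g / gp, _XI_EPS, 1.0 - _XI_EPS)
        if np.max(np.abs(xi_new - xi)) < 1e-12:
            xi = xi_new
            break
        xi = xi_new
    if xi.ndim == 0:
        return float(xi)
    return xi


def _sj_derivs(m, v, xi):
    """First/second partials of the SJ bound in (m, v).

    With z = m + (1 - 2 xi) v / 2 and p = sigma(z):
        S_m  = p
        S_v  = (xi^2 (1-p) + (1-xi)^2 p) / 2
        S_mm = p(1-p)
        S_mv = p(1-p)(1-2xi)/2
        S_vv = p(1-p)(1-2xi)^2/4
    """
    p = expit(m + (1.0 - 2.0 * xi) * v / 2.0)
    pq = p * (1.0 - p)
    half = (1.0 - 2.0 * xi) / 2.0
    S_v = (xi**2 * (1.0 - p) + (1.0 - xi) ** 2 * p) / 2.0
    return p, S_v, pq, pq * half, pq * half**2


# ---------------------------------------------------------------------------
# State container
# ---------------------------------------------------------------------------

@dataclass
class VBState:
    """All variational factors plus the tracked bound value."""

    mu_theta: np.ndarray
    v_theta: np.ndarray
    mu_b: np.ndarray
    v_b: np.ndarray
    mu_loga: Optional[np.ndarray]  # None for 1PL
    v_loga: Optional[np.ndarray]
    xi: np.ndarray
    hyper: dict = field(default_factory=dict)
    bound: float = -np.inf
    bound_history: list = field(default_factory=list)
    converged: bool = False
    n_sweeps: int = 0
    model: ModelTag = "2PL"


def _alpha_beta(state: VBState):
    """E[a] and E[a^2] under the lognormal factor (1 for the 1PL)."""
    if state.mu_loga is None:
        L = len(state.mu_b)
        return np.ones(L), np.ones(L)
    alpha = np.exp(state.mu_loga + state.v_loga / 2.0)
    beta = np.exp(2.0 * state.mu_loga + 2.0 * state.v_loga)
    return alpha, beta


def _logit_moments(state: VBState):
    """Gaussian moment-match of eta_ik = a_k (theta_i - b_k) under q."""
    alpha, beta = _alpha_beta(state)
    d = state.mu_theta[:, None] - state.mu_b[None, :]
    g = d**2 + state.v_theta[:, None] + state.v_b[None, :]
    m = alpha[None, :] * d
    v = beta[None, :] * g - alpha[None, :] ** 2 * d**2
    return m, np.maximum(v, 1e-300), d, g, alpha, beta


# ---------------------------------------------------------------------------
# Effective priors (expectations over hyper-factors where hierarchical)
# ---------------------------------------------------------------------------

def _effective_prior(state: VBState, prior: PriorConfig, block: str):
    """(mu0, u0, E[log u0], v_m0) for one latent block under the regime."""
    flat = {
        "theta": prior.ability_prior,
        "b": prior.difficulty_prior,
        "loga": prior.log_discrimination_prior,
    }[block]
    hier_flag = {
        "theta": prior.hierarchical_ability,
        "b": prior.hierarchical_difficulty,
        "loga": prior.hierarchical_discrimination,
    }[block]
    if hier_flag:
        h = state.hyper[block]
        eu = h["u_shape"] / h["u_rate"]
        elogu = digamma(h["u_shape"]) - np.log(h["u_rate"])
        return h["m_mean"], eu, elogu, h["m_var"]
    mean, var = flat
    return mean, 1.0 / var, -np.log(var), 0.0


# ---------------------------------------------------------------------------
# Bound (objective) audit
# ---------------------------------------------------------------------------

def bound_value(state: VBState, data: ResponseMatrix, prior: PriorConfig) -> float:
    """Recompute the full variational objective from scratch.

    data term + E_q[log prior] + factor entropies; for the hierarchical
    regime the hyper-factor prior expectations and entropies are included.
    On the 1PL this is a true lower bound on the log marginal likelihood.
    """
    y = data.entries
    m, v, _, _, _, _ = _logit_moments(state)
    total = float(np.sum(y * m - sj_bound(m, v, state.xi)))

    blocks = [("theta", state.mu_theta, state.v_theta),
              ("b", state.mu_b, state.v_b)]
    if state.mu_loga is not None:
        blocks.append(("loga", state.mu_loga, state.v_loga))

    for block, mu, var in blocks:
        mu0, u0, elogu, vm0 = _effective_prior(state, prior, block)
        total += float(
            np.sum(
                0.5 * elogu - 0.5 * _LOG2PI
                - 0.5 * u0 * ((mu - mu0) ** 2 + var + vm0)
            )
        )
        total += float(np.sum(0.5 * np.log(2.0 * np.pi * np.e * var)))  # entropy

    for block, h in state.hyper.items():
        V0 = prior.hyper_mean_prior[1]
        a0, b0 = prior.hyper_precision_prior
        # mean factor: E[log N(m; 0, V0)] + entropy
        total += (
            -0.5 * np.log(2.0 * np.pi * V0)
            - (h["m_mean"] ** 2 + h["m_var"]) / (2.0 * V0)
            + 0.5 * np.log(2.0 * np.pi * np.e * h["m_var"])
        )
        # precision factor: E[log Gamma(u; a0, b0)] + entropy
        sh, ra = h["u_shape"], h["u_rate"]
        elogu = digamma(sh) - np.log(ra)
        eu = sh / ra
        total += (
            a0 * np.log(b0) - gammaln(a0) + (a0 - 1.0) * elogu - b0 * eu
        )
        total += sh - np.log(ra) + gammaln(sh) + (1.0 - sh) * digamma(sh)
    return total


# ---------------------------------------------------------------------------
# Block updates
# ---------------------------------------------------------------------------

def _block_objective(state, y, prior, block):
    """Per-factor objective pieces (data + prior + entropy) for one block."""
    m, v, _, _, _, _ = _logit_moments(state)
    cell = y * m - sj_bound(m, v, state.xi)
    axis = 1 if block == "theta" else 0
    mu, var = {
        "theta": (state.mu_theta, state.v_theta),
        "b": (state.mu_b, state.v_b),
        "loga": (state.mu_loga, state.v_loga),
    }[block]
    mu0, u0, _, _ = _effective_prior(state, prior, block)
    return (
        cell.sum(axis=axis)
        - 0.5 * u0 * ((mu - mu0) ** 2 + var)
        + 0.5 * np.log(var)
    )


def _newton_gaussian_block(state, y, prior, block):
    """Damped Newton ascent on (mean, log variance) for a Gaussian block.

    Runs up to ``_NEWTON_INNER`` vectorized Newton steps, step-halving per
    factor whenever the proposed step would decrease that factor's slice
    of the bound.
    """
    axis = 1 if block == "theta" else 0
    mu0, u0, _, _ = _effective_prior(state, prior, block)

    f_before = _block_objective(state, y, prior, block)
    for _ in range(_NEWTON_INNER):
        m, v, d, g, alpha, beta = _logit_moments(state)
        Sm, Sv, Smm, Smv, Svv = _sj_derivs(m, v, state.xi)
        resid = y - Sm
        al = alpha[None, :]
        be = beta[None, :]
        excess = be - al**2  # E[a^2] - E[a]^2 >= 0, zero for 1PL

        if block == "theta":
            mu, var = state.mu_theta, state.v_theta
            h = 2.0 * d * excess          # dv/dmu_theta
            f_mu = (resid * al - Sv * h).sum(axis=1) - u0 * (mu - mu0)
            f_mumu = (
                -(Smm * al**2 + 2.0 * Smv * al * h + Svv * h**2)
                - Sv * 2.0 * excess
            ).sum(axis=1) - u0
            f_v = (-Sv * be).sum(axis=1) - 0.5 * u0
            f_vv = (-Svv * be**2).sum(axis=1)
            f_muv = (-Smv * al * be - Svv * h * be).sum(axis=1)
        elif block == "b":
            mu, var = state.mu_b, state.v_b
            h = -2.0 * d * excess         # dv/dmu_b
            f_mu = (-resid * al - Sv * h).sum(axis=0) - u0 * (mu - mu0)
            f_mumu = (
                -(Smm * al**2 - 2.0 * Smv * al * h + Svv * h**2)
                - Sv * 2.0 * excess
            ).sum(axis=0) - u0
            f_v = (-Sv * be).sum(axis=0) - 0.5 * u0
            f_vv = (-Svv * be**2).sum(axis=0)
            f_muv = (Smv * al * be - Svv * h * be).sum(axis=0)
        else:  # log-discrimination
            mu, var = state.mu_loga, state.v_loga
            ad = al * d
            dv_mu = 2.0 * (be * g - al**2 * d**2)
            dv_v = 2.0 * be * g - al**2 * d**2
            f_mu = (resid * ad - Sv * dv_mu).sum(axis=0) - u0 * (mu - mu0)
            f_mumu = (
                resid * ad
                - (Smm * ad**2 + 2.0 * Smv * ad * dv_mu + Svv * dv_mu**2)
                - Sv * 2.0 * dv_mu
            ).sum(axis=0) - u0
            f_v = (resid * ad / 2.0 - Sv * dv_v).sum(axis=0) - 0.5 * u0
            f_vv = (
                resid * ad / 4.0
                - (Smm * ad**2 / 4.0 + Smv * ad * dv_v + Svv * dv_v**2)
                - Sv * (4.0 * be * g - al**2 * d**2)
            ).sum(axis=0)
            f_muv = (
                resid * ad / 2.0
                - (
                    Smm * ad**2 / 2.0
                    + Smv * (ad * dv_v + ad * dv_mu / 2.0)
                    + Svv * dv_mu * dv_v
                )
                - Sv * (4.0 * be * g - 2.0 * al**2 * d**2)
            ).sum(axis=0)

        # chain rule to (mu, w = log v)
        g_mu = f_mu
        g_w = var * f_v + 0.5
        H_mm = f_mumu
        H_mw = var * f_muv
        H_ww = var * f_v + var**2 * f_vv

        # Newton direction where the Hessian is negative definite,
        # scaled gradient otherwise
        det = H_mm * H_ww - H_mw**2
        nd = (H_mm < 0) & (det > 0)
        det_safe = np.where(nd, det, 1.0)
        d_mu = np.where(nd, -(H_ww * g_mu - H_mw * g_w) / det_safe, 0.1 * g_mu)
        d_w = np.where(nd, -(-H_mw * g_mu + H_mm * g_w) / det_safe, 0.1 * g_w)
        d_mu = np.clip(d_mu, -2.0, 2.0)
        d_w = np.clip(d_w, -2.0, 2.0)
        if max(np.max(np.abs(d_mu)), np.max(np.abs(d_w))) < 1e-8:
            break

        step = np.ones_like(mu)
        for _ in range(12):
            mu_new = mu + step * d_mu
            var_new = var * np.exp(step * d_w)
            _assign(state, block, mu_new, var_new)
            f_after = _block_objective(state, y, prior, block)
            worse = f_after < f_before - 1e-12
            if not worse.any():
                break
            step = np.where(worse, step * 0.5, step)
        if worse.any():  # revert factors that never found an ascent step
            _assign(
                state, block,
                np.where(worse, mu, mu_new), np.where(worse, var, var_new),
            )
            f_after = np.where(worse, f_before, f_after)
        f_before = f_after


def _assign(state, block, mu, var):
    if block == "theta":
        state.mu_theta, state.v_theta = mu, var
    elif block == "b":
        state.mu_b, state.v_b = mu, var
    else:
        state.mu_loga, state.v_loga = mu, var


def _scaled_copy(state: VBState, gamma: float) -> VBState:
    """Joint rescaling along the model's scale direction, c = e^gamma.

    theta- and b-side locations/variances scale by c (hyper rates by c^2,
    keeping E[u] (x - m)^2 terms invariant); log-discrimination locations
    shift by -gamma.  The data term of the bound is exactly invariant
    under this map, so it moves mass only through the prior/entropy
    terms — a parameter-expansion direction along which plain coordinate
    ascent is slow.
    """
    c = np.exp(gamma)
    new = VBState(
        mu_theta=c * state.mu_theta,
        v_theta=c**2 * state.v_theta,
        mu_b=c * state.mu_b,
        v_b=c**2 * state.v_b,
        mu_loga=state.mu_loga - gamma,
        v_loga=state.v_loga.copy(),
        xi=state.xi,
        model=state.model,
    )
    for block, h in state.hyper.items():
        if block == "loga":
            new.hyper[block] = {
                "m_mean": h["m_mean"] - gamma,
                "m_var": h["m_var"],
                "u_shape": h["u_shape"],
                "u_rate": h["u_rate"],
            }
        else:
            new.hyper[block] = {
                "m_mean": c * h["m_mean"],
                "m_var": c**2 * h["m_var"],
                "u_shape": h["u_shape"],
                "u_rate": c**2 * h["u_rate"],
            }
    return new


def _px_scale_move(state: VBState, data: ResponseMatrix, prior: PriorConfig):
    """One line search along the scale expansion; returns the better state."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda gmm: -bound_value(_scaled_copy(state, gmm), data, prior),
        bounds=(-0.7, 0.7),
        method="bounded",
        options={"xatol": 1e-4},
    )
    if -res.fun > bound_value(state, data, prior):
        best = _scaled_copy(state, float(res.x))
        best.bound = -res.fun
        return best
    return state


def _update_hypers(state: VBState, prior: PriorConfig):
    """Closed-form conjugate mean-field updates for the hyper-factors.

    For a latent block x_1..x_n: the mean factor is Gaussian with
    precision n E[u] + 1/V0, and the precision factor is Gamma with shape
    a0 + n/2 and rate b0 + E[sum (x_j - m)^2]/2.
    """
    V0 = prior.hyper_mean_prior[1]
    a0, b0 = prior.hyper_precision_prior
    latents = {
        "theta": (state.mu_theta, state.v_theta),
        "b": (state.mu_b, state.v_b),
        "loga": (state.mu_loga, state.v_loga),
    }
    for block, h in state.hyper.items():
        mu, var = latents[block]
        n = len(mu)
        eu = h["u_shape"] / h["u_rate"]
        prec = n * eu + 1.0 / V0
        h["m_mean"] = eu * mu.sum() / prec
        h["m_var"] = 1.0 / prec
        ess = np.sum((mu - h["m_mean"]) ** 2 + var) + n * h["m_var"]
        h["u_shape"] = a0 + n / 2.0
        h["u_rate"] = b0 + 0.5 * ess


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def fit_vb(
    data: ResponseMatrix,
    model: ModelTag,
    prior: PriorConfig,
    tol: float = 1e-6,
    max_sweeps: int = 500,
):
    """Coordinate-ascent VB fit.

    Per sweep: xi refresh, theta block, b block, (2PL) log-a block, then
    hierarchical hyper-factors; stops when the bound improves by less
    than ``tol``.  Non-convergence within ``max_sweeps`` sets a warning
    flag on the result rather than raising.

    Returns
    -------
    (VBState, ParameterEstimates)
    """
    if prior.regime == "none":
        raise ValueError("VB requires a proper prior regime")
    y = data.entries.astype(float)
    S, L = y.shape
    two_pl = model == "2PL"

    state = VBState(
        mu_theta=np.zeros(S),
        v_theta=np.ones(S),
        mu_b=np.zeros(L),
        v_b=np.ones(L),
        mu_loga=np.zeros(L) if two_pl else None,
        v_loga=np.ones(L) if two_pl else None,
        xi=np.full((S, L), 0.5),
        model=model,
    )
    for block, flag in (
        ("theta", prior.hierarchical_ability),
        ("b", prior.hierarchical_difficulty),
        ("loga", prior.hierarchical_discrimination and two_pl),
    ):
        if flag:
            state.hyper[block] = {
                "m_mean": 0.0, "m_var": 1.0, "u_shape": 1.0, "u_rate": 1.0,
            }

    prev = -np.inf
    for sweep in range(1, max_sweeps + 1):
        m, v, *_ = _logit_moments(state)
        state.xi = np.clip(sj_optimal_xi(m, v), _XI_EPS, 1.0 - _XI_EPS)
        _newton_gaussian_block(state, y, prior, "theta")
        _newton_gaussian_block(state, y, prior, "b")
        if two_pl:
            _newton_gaussian_block(state, y, prior, "loga")
        if state.hyper:
            _update_hypers(state, prior)
            if two_pl and "loga" in state.hyper:
                history = state.bound_history
                state = _px_scale_move(state, data, prior)
                state.bound_history = history
        state.bound = bound_value(state, data, prior)
        state.bound_history.append(state.bound)
        state.n_sweeps = sweep
        if state.bound - prev < tol and sweep > 1:
            state.converged = True
            break
        prev = state.bound

    if two_pl:
        a_hat = np.exp(state.mu_loga + state.v_loga / 2.0)
        se_a = np.sqrt(
            (np.exp(state.v_loga) - 1.0)
            * np.exp(2.0 * state.mu_loga + state.v_loga)
        )
    else:
        a_hat, se_a = np.ones(L), np.zeros(L)

    est = ParameterEstimates(
        abilities=state.mu_theta,
        difficulties=state.mu_b,
        discriminations=a_hat,
        se_abilities=np.sqrt(state.v_theta),
        se_difficulties=np.sqrt(state.v_b),
        se_discriminations=se_a,
        method="VB",
        prior=prior.regime,
        model=model,
        converged=state.converged,
        info={"bound": state.bound, "n_sweeps": state.n_sweeps},
    )
    return state, est
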