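"""Marginal maximum likelihood (Bock–Aitkin EM) for 1PL/2PL item parameters.

Item parameters are estimated by maximizing the likelihood marginalized
over a fixed N(0, 1) ability distribution, approximated on a discrete
quadrature grid.  The E-step computes each person's posterior weights over
grid nodes; the M-step performs a per-item weighted logistic regression of
expected correct counts on the node locations (slope fixed at 1 for 1PL).
Abilities are then scored by person-wise ML, as in the CML pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .model import ml_abilities
from .types import ModelTag, ParameterEstimates, ResponseMatrix

_PARAM_TOL = 1e-5
_MAX_CYCLES = 500
_B_CLAMP = 10.0
_A_CLAMP = 20.0


@dataclass
class QuadratureGrid:
    """Fixed quadrature grid over the ability scale.

    Defaults to 41 equally spaced nodes on [-5, 5] weighted by the standard
    normal density and renormalized — the classic fixed-grid choice for
    Bock–Aitkin EM with an assumed N(0,1) latent distribution.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.nodes.shape != self.weights.shape or self.nodes.ndim != 1:
            raise ValueError("nodes and weights must be matching 1-D vectors")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    @classmethod
    def default(cls, n: int = 41, span: float = 5.0) -> "QuadratureGrid":
        nodes = np.linspace(-span, span, n)
        w = norm.pdf(nodes)
        return cls(nodes=nodes, weights=w / w.sum())


def _cell_loglik(y: np.ndarray, eta_kq: np.ndarray) -> np.ndarray:
    """(S, Q) log-likelihood of each person's responses at each node."""
    # log p and log(1-p) at each item x node
    log_p = -np.logaddexp(0.0, -eta_kq)
    log_q = -np.logaddexp(0.0, eta_kq)
    return y @ log_p + (1.0 - y) @ log_q


def fit_mml(
    data: ResponseMatrix,
    model: ModelTag,
    grid: QuadratureGrid | None = None,
) -> ParameterEstimates:
    """Fit item parameters by Bock–Aitkin EM, then score abilities by ML.

    The marginal log-likelihood is asserted non-decreasing every cycle
    (EM monotonicity).  Items drifting past |b| > 10 or a > 20 are clamped
    and the fit flagged as non-converged (Heywood-type divergence).  Item
    SEs are the observed information of the marginal likelihood, computed
    per item with cross-item blocks ignored.
    """
    if grid is None:
        grid = QuadratureGrid.default()
    y = data.entries.astype(float)
    S, L = y.shape
    if np.any(y.sum(axis=0) == 0) or np.any(y.sum(axis=0) == S):
        raise ValueError("degenerate item (all-0 or all-1 column)")
    x = grid.nodes
    logA = np.log(grid.weights)
    Q = len(x)

    # parametrize eta = a * x + c with c = -a b
    a = np.ones(L)
    c = np.zeros(L)
    two_pl = model == "2PL"

    eta = a[:, None] * x[None, :] + c[:, None]
    ll_iq = _cell_loglik(y, eta)
    marg = float(logsumexp(logA[None, :] + ll_iq, axis=1).sum())

    history = [marg]
    converged = False
    for _ in range(_MAX_CYCLES):
        # E-step: posterior node weights per person
        w = logA[None, :] + ll_iq
        w = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        n_q = w.sum(axis=0)            # expected persons at node q
        r_kq = y.T @ w                 # expected correct counts (L, Q)

        # M-step: per-item damped Newton for the weighted logistic
        # regression; the objective Q_k is concave, and step-halving on it
        # preserves EM monotonicity
        def q_value(a_, c_):
            eta_ = a_[:, None] * x[None, :] + c_[:, None]
            lp = -np.logaddexp(0.0, -eta_)
            lq = -np.logaddexp(0.0, eta_)
            return (r_kq * lp + (n_q[None, :] - r_kq) * lq).sum(axis=1)

        a_new, c_new = a.copy(), c.copy()
        q_cur = q_value(a_new, c_new)
        for _ in range(25):
            p = expit(a_new[:, None] * x[None, :] + c_new[:, None])
            resid = r_kq - n_q[None, :] * p
            wgt = n_q[None, :] * p * (1.0 - p)
            g_c = resid.sum(axis=1)
            h_cc = wgt.sum(axis=1)
            if two_pl:
                g_a = resid @ x
                h_ca = wgt @ x
                h_aa = wgt @ x**2
                det = np.maximum(h_aa * h_cc - h_ca**2, 1e-300)
                da = np.clip((h_cc * g_a - h_ca * g_c) / det, -1.0, 1.0)
                dc = np.clip((h_aa * g_c - h_ca * g_a) / det, -1.0, 1.0)
            else:
                da = np.zeros_like(a_new)
                dc = np.clip(g_c / np.maximum(h_cc, 1e-300), -1.0, 1.0)
            if max(np.abs(da).max(), np.abs(dc).max()) < 1e-10:
                break
            step = np.ones_like(c_new)
            for _ in range(20):
                a_try = np.clip(a_new + step * da, 0.05, _A_CLAMP)
                c_try = c_new + step * dc
                q_try = q_value(a_try, c_try)
                worse = q_try < q_cur - 1e-12
                if not worse.any():
                    break
                step = np.where(worse, step * 0.5, step)
            keep = q_try >= q_cur - 1e-12
            a_new = np.where(keep, a_try, a_new)
            c_new = np.where(keep, c_try, c_new)
            q_cur = np.where(keep, q_try, q_cur)

        delta = max(np.abs(a_new - a).max(), np.abs(c_new - c).max())
        a, c = a_new, c_new
        eta = a[:, None] * x[None, :] + c[:, None]
        ll_iq = _cell_loglik(y, eta)
        marg = float(logsumexp(logA[None, :] + ll_iq, axis=1).sum())
        if marg < history[-1] - 1e-8:
            raise AssertionError(
                f"EM marginal log-likelihood decreased: {history[-1]} -> {marg}"
            )
        history.append(marg)
        if delta < _PARAM_TOL:
            converged = True
            break

    b = -c / a
    heywood = (np.abs(b) > _B_CLAMP) | (a > _A_CLAMP - 1e-9)
    if heywood.any():
        converged = False
        b = np.clip(b, -_B_CLAMP, _B_CLAMP)
        a = np.clip(a, None, _A_CLAMP)
        c = -a * b

    se_b, se_a = _item_ses(y, a, c, x, logA, two_pl)

    theta, se_theta = ml_abilities(data, b, a if two_pl else np.ones(L))
    return ParameterEstimates(
        abilities=theta,
        difficulties=b,
        discriminations=a if two_pl else np.ones(L),
        se_abilities=se_theta,
        se_difficulties=se_b,
        se_discriminations=se_a if two_pl else np.zeros(L),
        method="MML",
        prior="none",
        model=model,
        converged=converged,
        info={
            "marginal_loglik": history[-1],
            "loglik_history": history,
            "heywood_items": np.flatnonzero(heywood).tolist(),
        },
    )


def _item_ses(y, a, c, x, logA, two_pl):
    """Observed-information SEs per item from the marginal likelihood.

    The score of the marginal log-likelihood w.r.t. item k's parameters
    follows Fisher's identity (posterior-weighted complete-data score);
    the per-item observed information is its negative derivative, obtained
    by central differences in (c_k, a_k), with cross-item blocks ignored.
    The (c, a) covariance is mapped to (b, a) by the delta method.
    """
    S, L = y.shape
    eta = a[:, None] * x[None, :] + c[:, None]
    base_ll = _cell_loglik(y, eta)  # (S, Q)

    def grad_k(k, ck, ak):
        eta_k = ak * x + ck
        log_p = -np.logaddexp(0.0, -eta_k)
        log_q = -np.logaddexp(0.0, eta_k)
        ll_k = np.outer(y[:, k], log_p) + np.outer(1.0 - y[:, k], log_q)
        eta_base_k = a[k] * x + c[k]
        lp0 = -np.logaddexp(0.0, -eta_base_k)
        lq0 = -np.logaddexp(0.0, eta_base_k)
        ll_base_k = np.outer(y[:, k], lp0) + np.outer(1.0 - y[:, k], lq0)
        ll_iq = base_ll - ll_base_k + ll_k
        w = logA[None, :] + ll_iq
        w = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        resid = w * (y[:, [k]] - expit(eta_k)[None, :])
        gc = resid.sum()
        ga = resid @ x
        return np.array([gc, float(ga.sum())])

    h = 1e-4
    se_b = np.empty(L)
    se_a = np.empty(L)
    for k in range(L):
        d_c = (grad_k(k, c[k] + h, a[k]) - grad_k(k, c[k] - h, a[k])) / (2 * h)
        if two_pl:
            d_a = (grad_k(k, c[k], a[k] + h) - grad_k(k, c[k], a[k] - h)) / (2 * h)
            info = -np.array([[d_c[0], d_a[0]], [d_c[1], d_a[1]]])
            info = 0.5 * (info + info.T)
            try:
                cov = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                cov = np.full((2, 2), np.nan)
            # b = -c/a: grad wrt (c, a) is (-1/a, c/a^2)
            gb = np.array([-1.0 / a[k], c[k] / a[k] ** 2])
            vb = float(gb @ cov @ gb)
            va = float(cov[1, 1])
            se_b[k] = np.sqrt(max(vb, 0.0))
            se_a[k] = np.sqrt(max(va, 0.0))
        else:
            info_cc = -d_c[0]
            se_b[k] = 1.0 / np.sqrt(max(info_cc, 1e-300))
            se_a[k] = 0.0
    return se_b, se_a
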