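"""Conditional maximum likelihood (CML) for the Rasch (1PL) model.

Under the 1PL model the person raw score is a sufficient statistic for
ability, so item difficulties can be estimated from the likelihood of the
responses *conditional* on the raw scores, which is free of the person
parameters.  The conditional likelihood is built from elementary symmetric
functions (ESFs) of the item easiness parameters eps_k = exp(-b_k):

    gamma_r(eps) = sum over r-subsets A of {1..L} of prod_{k in A} eps_k.

Persons with extreme raw scores (0 or perfect) carry no conditional
information and are excluded from item estimation; difficulties are
normalized to sum to zero.  Abilities are then scored by person-wise ML on
all persons (extreme scores clamped, see :mod:`irtkit.model`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .model import ml_abilities
from .types import ParameterEstimates, ResponseMatrix

_GRAD_TOL = 1e-8
_MAX_ITER = 100


def _esf_linear(eps: np.ndarray) -> np.ndarray:
    """ESF vector gamma[0..L] by the (stable, all-positive) summation recursion."""
    L = len(eps)
    g = np.zeros(L + 1)
    g[0] = 1.0
    for k in range(L):
        g[1:] = g[1:] + eps[k] * g[:-1]
    return g


def _esf_log(log_eps: np.ndarray) -> np.ndarray:
    """log gamma[0..L] via the summation recursion in log space."""
    L = len(log_eps)
    g = np.full(L + 1, -np.inf)
    g[0] = 0.0
    for k in range(L):
        g[1:] = np.logaddexp(g[1:], g[:-1] + log_eps[k])
    return g


def _esf_first_partials(eps: np.ndarray) -> np.ndarray:
    """(L, L) table: row k holds gamma^{(k)}_r, r = 0..L-1 (item k removed).

    All L leave-one-out recursions are run simultaneously: iterating over
    items, each item updates every row except its own.
    """
    L = len(eps)
    G = np.zeros((L, L))
    G[:, 0] = 1.0
    for j in range(L):
        rows = np.arange(L) != j
        G[rows, 1:] = G[rows, 1:] + eps[j] * G[rows, :-1]
    return G


def _esf_second_partials(eps: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """(n_pairs, L-1) table of gamma^{(k,l)}_r for the given (k, l) index pairs."""
    L = len(eps)
    n = len(pairs)
    G = np.zeros((n, L - 1))
    G[:, 0] = 1.0
    for j in range(L):
        rows = (pairs[:, 0] != j) & (pairs[:, 1] != j)
        G[rows, 1:] = G[rows, 1:] + eps[j] * G[rows, :-1]
    return G


@dataclass
class EsfTable:
    """Elementary symmetric functions of an easiness vector.

    ``gamma[r]`` is the order-r ESF of all L items; ``gamma_partial[k, r]``
    is the order-r ESF with item k removed, linked by the identity
    gamma[r] = gamma_partial[k, r] + eps_k * gamma_partial[k, r-1].
    """

    easiness: np.ndarray
    gamma: np.ndarray
    gamma_partial: np.ndarray


def elementary_symmetric(easiness) -> EsfTable:
    """Compute the full and leave-one-out ESF tables for an easiness vector.

    Uses the summation recursion, which only adds positive terms and is
    numerically stable (unlike the difference recursion); cost O(L^2).
    """
    eps = np.asarray(easiness, dtype=float)
    if eps.ndim != 1 or len(eps) < 1:
        raise ValueError("easiness must be a nonempty 1-D vector")
    if np.any(eps <= 0) or not np.all(np.isfinite(eps)):
        raise ValueError("easiness values must be finite and strictly positive")
    return EsfTable(
        easiness=eps,
        gamma=_esf_linear(eps),
        gamma_partial=_esf_first_partials(eps),
    )


def _conditional_loglik(b: np.ndarray, s_item: np.ndarray, n_r: np.ndarray) -> float:
    """Conditional log-likelihood of interior persons given raw scores.

    ell(b) = -sum_k s_k b_k - sum_r n_r log gamma_r, with the sums over
    interior raw scores r = 1..L-1.
    """
    log_gamma = _esf_log(-b)
    r = np.arange(1, len(b))
    return float(-(s_item * b).sum() - (n_r * log_gamma[r]).sum())


def fit_cml(data: ResponseMatrix) -> ParameterEstimates:
    """Fit 1PL difficulties by CML and score abilities by ML.

    Newton–Raphson on the conditional log-likelihood with analytic
    gradient and Hessian (built from first- and second-order partial
    ESFs), constrained to the sum-to-zero normalization.  SEs come from
    the inverse information restricted to the sum-zero subspace; ability
    SEs from the test information at the ML estimate.
    """
    y = data.entries
    S, L = y.shape
    raw = y.sum(axis=1)
    interior = (raw > 0) & (raw < L)
    y_int = y[interior]
    if y_int.shape[0] == 0:
        raise ValueError("no persons with interior raw scores; CML is undefined")

    s_item = y_int.sum(axis=0).astype(float)
    n_int = y_int.shape[0]
    bad = np.flatnonzero((s_item == 0) | (s_item == n_int))
    if bad.size:
        raise ValueError(
            f"degenerate item(s) {bad.tolist()}: all-0 or all-1 among "
            "non-extreme persons; conditional ML estimate does not exist"
        )
    # counts of interior raw scores r = 1..L-1
    n_r = np.bincount(y_int.sum(axis=1), minlength=L + 1)[1:L].astype(float)

    C = null_space(np.ones((1, L)))  # orthonormal basis of the sum-zero subspace
    b = np.zeros(L)
    ll = _conditional_loglik(b, s_item, n_r)
    pairs = np.array([(k, l) for k in range(L) for l in range(k + 1, L)])

    converged = False
    for _ in range(_MAX_ITER):
        eps = np.exp(-b)
        gamma = _esf_linear(eps)
        Gk = _esf_first_partials(eps)
        if not np.all(np.isfinite(gamma)):
            raise FloatingPointError("ESF overflow; difficulties diverged")
        # pi[r-1, k] = P(person with raw score r answers item k correctly)
        r = np.arange(1, L)
        pi = (eps[None, :] * Gk[:, r - 1].T) / gamma[r][:, None]
        grad = -s_item + n_r @ pi

        # information matrix: I_kl = sum_r n_r Cov_r(x_k, x_l)
        Gkl = _esf_second_partials(eps, pairs)
        info = np.zeros((L, L))
        # diagonal: pi(1-pi); off-diagonal needs joint pi_rkl
        info[np.arange(L), np.arange(L)] = n_r @ (pi * (1.0 - pi))
        ee = eps[pairs[:, 0]] * eps[pairs[:, 1]]
        # joint probability needs gamma^{(k,l)}_{r-2}; r-2 = -1 contributes 0
        joint = np.zeros((L - 1, len(pairs)))
        rr = r[r >= 2]
        joint[rr - 1] = ee[None, :] * Gkl[:, rr - 2].T / gamma[rr][:, None]
        cov_off = n_r @ (joint - pi[:, pairs[:, 0]] * pi[:, pairs[:, 1]])
        info[pairs[:, 0], pairs[:, 1]] = cov_off
        info[pairs[:, 1], pairs[:, 0]] = cov_off

        g_proj = C.T @ grad
        if np.max(np.abs(g_proj)) < _GRAD_TOL:
            converged = True
            break
        info_proj = C.T @ info @ C
        delta = C @ np.linalg.solve(info_proj, g_proj)
        # step-halving to guarantee ascent
        step = 1.0
        for _ in range(30):
            b_new = b + step * delta
            b_new -= b_new.mean()
            ll_new = _conditional_loglik(b_new, s_item, n_r)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        b, ll = b_new, ll_new

    cov = C @ np.linalg.inv(info_proj) @ C.T
    se_b = np.sqrt(np.diag(cov))

    theta, se_theta = ml_abilities(data, b, np.ones(L))
    return ParameterEstimates(
        abilities=theta,
        difficulties=b,
        discriminations=np.ones(L),
        se_abilities=se_theta,
        se_difficulties=se_b,
        se_discriminations=np.zeros(L),
        method="CML",
        prior="none",
        model="1PL",
        converged=converged,
        info={"conditional_loglik": ll, "n_interior": int(n_int)},
    )
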