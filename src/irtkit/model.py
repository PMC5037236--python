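"""Core model mathematics shared by every estimator.

The two-parameter logistic (2PL) response function is

    P(Y_ik = 1 | theta_i, b_k, a_k) = sigma(a_k (theta_i - b_k)),

with sigma the standard logistic function; the 1PL (Rasch) model fixes
a_k = 1.  This module provides the response function and Bernoulli
log-likelihood (both overflow-safe), the named prior regimes used by the
Bayesian estimators, and maximum-likelihood ability scoring given item
parameters.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, log_expit

from .types import ModelTag, PriorConfig, ResponseMatrix

#: ML ability assigned to zero / perfect raw scores, where the ML estimate
#: diverges.  All examinees are retained in downstream error metrics.
EXTREME_ABILITY_CLAMP = 4.0


def irf(theta, b, a=1.0):
    """Item response function: probability of a correct response.

    Accepts scalars or broadcastable arrays; computed via the numerically
    stable logistic so logits up to +-700 neither overflow nor underflow
    to an exact 0/1 prematurely.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("discrimination a must be strictly positive")
    return expit(a * (np.asarray(theta, dtype=float) - np.asarray(b, dtype=float)))


def loglik(data: ResponseMatrix, params) -> float:
    """Bernoulli log-likelihood of a response matrix under local independence.

    ``params`` is any object with ``abilities``, ``difficulties`` and
    ``discriminations`` vectors (true parameters or estimates).
    """
    y = data.entries
    theta = np.asarray(params.abilities, dtype=float)
    b = np.asarray(params.difficulties, dtype=float)
    a = np.asarray(params.discriminations, dtype=float)
    if y.shape != (len(theta), len(b)):
        raise ValueError(
            f"dimension mismatch: data {y.shape}, parameters ({len(theta)}, {len(b)})"
        )
    eta = a[None, :] * (theta[:, None] - b[None, :])
    # y*log p + (1-y)*log(1-p) = log sigma(eta) where y=1, log sigma(-eta) where y=0
    return float(np.sum(np.where(y == 1, log_expit(eta), log_expit(-eta))))


def make_prior(regime: str, model: ModelTag) -> PriorConfig:
    """Build a named prior regime.

    * ``matched`` — the generating distributions: theta, b ~ N(0, 1);
      log a ~ N(0, 0.25^2) (i.e. a lognormal with log-SD 0.25).
    * ``stdvague`` — theta ~ N(0, 1); b ~ N(0, 1e3); log a ~ N(0, 8).
      The large second parameters are read as variances.
    * ``hierarchical`` — theta ~ N(m_theta, 1/u_theta), b ~ N(m_b, 1/u_b),
      log a ~ N(m_a, 1/u_a) with hyperpriors m ~ N(0, 1e6) and
      u ~ Gamma(shape 1, rate 1).
    * ``none`` — no priors; only valid for the likelihood methods.
    """
    if model not in ("1PL", "2PL"):
        raise ValueError(f"unknown model tag {model!r}")
    loga = model == "2PL"
    if regime == "matched":
        return PriorConfig(
            regime=regime,
            model=model,
            ability_prior=(0.0, 1.0),
            difficulty_prior=(0.0, 1.0),
            log_discrimination_prior=(0.0, 0.25**2) if loga else None,
        )
    if regime == "stdvague":
        return PriorConfig(
            regime=regime,
            model=model,
            ability_prior=(0.0, 1.0),
            difficulty_prior=(0.0, 1.0e3),
            log_discrimination_prior=(0.0, 8.0) if loga else None,
        )
    if regime == "hierarchical":
        return PriorConfig(
            regime=regime,
            model=model,
            hierarchical_ability=True,
            hierarchical_difficulty=True,
            hierarchical_discrimination=loga,
        )
    if regime == "none":
        return PriorConfig(regime=regime, model=model)
    raise ValueError(f"unknown prior regime {regime!r}")


def ml_abilities(
    data: ResponseMatrix,
    difficulties: np.ndarray,
    discriminations: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
):
    """Per-person ML ability estimates given item parameters.

    The per-person log-likelihood is strictly concave in theta, so damped
    Newton iteration from 0 converges for every non-extreme response
    pattern.  Zero and perfect raw scores have no finite maximiser; they
    are clamped to -+``EXTREME_ABILITY_CLAMP`` and retained.  The SE is
    1/sqrt(test information) evaluated at the estimate (at the clamp for
    extreme scores).

    Returns
    -------
    (abilities, se_abilities) : pair of length-S arrays
    """
    b = np.asarray(difficulties, dtype=float)
    a = np.asarray(discriminations, dtype=float)
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(a))):
        raise ValueError("item parameters must be finite")
    y = data.entries.astype(float)
    S, L = y.shape
    raw = y.sum(axis=1)
    extreme_low = raw == 0
    extreme_high = raw == L
    interior = ~(extreme_low | extreme_high)

    theta = np.zeros(S)
    active = interior.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        p = irf(theta[active, None], b[None, :], a[None, :])
        grad = ((y[active] - p) * a[None, :]).sum(axis=1)
        info = (p * (1.0 - p) * a[None, :] ** 2).sum(axis=1)
        step = grad / info
        # loglik in theta is concave; cap the step to keep Newton tame at
        # near-extreme patterns
        step = np.clip(step, -2.0, 2.0)
        theta[active] += step
        conv = np.abs(grad) < tol
        idx = np.flatnonzero(active)
        active[idx[conv]] = False

    theta[extreme_low] = -EXTREME_ABILITY_CLAMP
    theta[extreme_high] = EXTREME_ABILITY_CLAMP

    p_hat = irf(theta[:, None], b[None, :], a[None, :])
    info = (p_hat * (1.0 - p_hat) * a[None, :] ** 2).sum(axis=1)
    se = 1.0 / np.sqrt(info)
    return theta, se
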