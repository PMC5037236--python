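"""Synthetic data generation for the parameter-recovery studies.

Abilities and difficulties are drawn iid from the standard normal
distribution; 2PL discriminations from a lognormal with log-mean 0 and
log-SD 0.25 (so the median slope is exactly 1).  Responses are produced by
comparing the 2PL/1PL response probability against an iid Uniform(0,1)
threshold per person-item cell.

Reproducibility contract: every draw is driven by a ``numpy`` SeedSequence
derived from the caller's integer seed.  Parameter draws and response
thresholds consume *separate* child streams, so the same dataset can be
re-materialised piecewise, and all estimators compared within a replication
see identical data.
"""

from __future__ import annotations

import numpy as np

from .model import irf
from .types import ModelTag, ResponseMatrix, TrueParameters

#: log-scale SD of the generating lognormal for 2PL discriminations
DISCRIMINATION_LOG_SD = 0.25

_PARAM_STREAM = 0
_RESPONSE_STREAM = 1


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(stream,)))
    )


def draw_parameters(S: int, L: int, model: ModelTag, seed: int) -> TrueParameters:
    """Draw true person and item parameters for an S-person, L-item test.

    Parameters
    ----------
    S, L
        Number of examinees and items; both must be at least 2.
    model
        ``"1PL"`` (all slopes fixed at 1) or ``"2PL"`` (lognormal slopes).
    seed
        Integer root seed; the same seed always reproduces the same draw.
    """
    if S < 2 or L < 2:
        raise ValueError(f"invalid design: need S >= 2 and L >= 2, got S={S}, L={L}")
    if model not in ("1PL", "2PL"):
        raise ValueError(f"unknown model tag {model!r}")
    rng = _child_rng(seed, _PARAM_STREAM)
    abilities = rng.standard_normal(S)
    difficulties = rng.standard_normal(L)
    if model == "2PL":
        discriminations = rng.lognormal(mean=0.0, sigma=DISCRIMINATION_LOG_SD, size=L)
    else:
        discriminations = np.ones(L)
    return TrueParameters(
        abilities=abilities,
        difficulties=difficulties,
        discriminations=discriminations,
        model=model,
    )


def simulate_responses(params: TrueParameters, seed: int) -> ResponseMatrix:
    """Simulate a binary response matrix from true parameters.

    Cell (i, k) is 1 exactly when an independent Uniform(0,1) threshold
    falls below the response probability P(Y_ik = 1 | theta_i, b_k, a_k).
    """
    rng = _child_rng(seed, _RESPONSE_STREAM)
    prob = irf(
        params.abilities[:, None],
        params.difficulties[None, :],
        params.discriminations[None, :],
    )
    u = rng.random(prob.shape)
    return ResponseMatrix(entries=(u < prob).astype(np.int8))


def response_probabilities(params) -> np.ndarray:
    """S x L matrix of response probabilities implied by a parameter set."""
    return irf(
        np.asarray(params.abilities)[:, None],
        np.asarray(params.difficulties)[None, :],
        np.asarray(params.discriminations)[None, :],
    )
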