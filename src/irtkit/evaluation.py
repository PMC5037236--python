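"""Recovery metrics: identifiability alignment, average RMSEs, SEs, eta^2 ANOVA.

The 2PL likelihood is invariant under a shift/scale re-expression of the
parameters; before errors are measured, each replication's estimates are
transformed by the (s, t) minimizing

    J(s, t) = RMSE(theta | s,t) + RMSE(b | s,t) + RMSE(a | s,t),

with theta' = s theta + t, b' = s b + t, a' = a / s (the
likelihood-preserving re-expression of the model).  For the 1PL the scale
is fixed by a = 1, so s = 1, only the shift is optimized, and the
discrimination term is dropped.  Average RMSEs are root-mean-squares
within a replication, averaged (unweighted) over replications.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .types import ModelTag, ParameterEstimates, TrueParameters


def _rmse(x, y) -> float:
    return float(np.sqrt(np.mean((np.asarray(x) - np.asarray(y)) ** 2)))


def _transform(est: ParameterEstimates, s: float, t: float) -> ParameterEstimates:
    """Apply the shift/scale triple to a parameter set (SEs scaled along)."""
    return ParameterEstimates(
        abilities=s * est.abilities + t,
        difficulties=s * est.difficulties + t,
        discriminations=est.discriminations / s,
        se_abilities=s * est.se_abilities,
        se_difficulties=s * est.se_difficulties,
        se_discriminations=est.se_discriminations / s,
        method=est.method,
        prior=est.prior,
        model=est.model,
        converged=est.converged,
        info=dict(est.info),
    )


@dataclass
class AlignmentResult:
    s: float
    t: float
    aligned: ParameterEstimates
    objective: float


def _J(est: ParameterEstimates, truth: TrueParameters, s: float, t: float,
       include_a: bool) -> float:
    val = _rmse(s * est.abilities + t, truth.abilities) + _rmse(
        s * est.difficulties + t, truth.difficulties
    )
    if include_a:
        val += _rmse(est.discriminations / s, truth.discriminations)
    return val


def align(
    est: ParameterEstimates,
    truth: TrueParameters,
    model: ModelTag | None = None,
) -> AlignmentResult:
    """Find the (s, t) minimizing J and return the transformed estimates.

    2PL: Nelder–Mead on (log s, t) started from the best point of a
    21 x 21 grid over s in [0.5, 2], t in [-1, 1].  1PL: s = 1 and the
    scalar shift is optimized directly.
    """
    model = model or est.model
    if len(est.abilities) != len(truth.abilities) or len(est.difficulties) != len(
        truth.difficulties
    ):
        raise ValueError("estimate / truth dimension mismatch")
    if np.std(truth.abilities) == 0 and np.std(truth.difficulties) == 0:
        import warnings

        warnings.warn("degenerate truth (zero variance); alignment skipped")
        return AlignmentResult(1.0, 0.0, est, _J(est, truth, 1.0, 0.0, model == "2PL"))

    if model == "1PL":
        res = minimize_scalar(
            lambda t: _J(est, truth, 1.0, t, include_a=False),
            bounds=(-5.0, 5.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        s_opt, t_opt, j_opt = 1.0, float(res.x), float(res.fun)
    else:
        grid_s = np.linspace(0.5, 2.0, 21)
        grid_t = np.linspace(-1.0, 1.0, 21)
        best = (np.inf, 1.0, 0.0)
        for s in grid_s:
            for t in grid_t:
                val = _J(est, truth, s, t, True)
                if val < best[0]:
                    best = (val, s, t)
        res = minimize(
            lambda p: _J(est, truth, np.exp(p[0]), p[1], True),
            x0=np.array([np.log(best[1]), best[2]]),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000},
        )
        s_opt, t_opt = float(np.exp(res.x[0])), float(res.x[1])
        j_opt = float(res.fun)

    aligned = _transform(est, s_opt, t_opt)
    return AlignmentResult(s_opt, t_opt, aligned, j_opt)


# ---------------------------------------------------------------------------
# Average RMSE metrics (RMSE within replication, mean over replications)
# ---------------------------------------------------------------------------

def _check_reps(est_reps, truth_reps):
    if len(est_reps) != len(truth_reps) or len(est_reps) == 0:
        raise ValueError("need R >= 1 matched (estimate, truth) replications")


def average_rmse_theta(est_reps, truth_reps) -> float:
    """Average over replications of the per-replication ability RMSE."""
    _check_reps(est_reps, truth_reps)
    return float(
        np.mean([_rmse(e.abilities, t.abilities) for e, t in zip(est_reps, truth_reps)])
    )


def average_rmse_b(est_reps, truth_reps) -> float:
    """Average over replications of the per-replication difficulty RMSE."""
    _check_reps(est_reps, truth_reps)
    return float(
        np.mean(
            [_rmse(e.difficulties, t.difficulties) for e, t in zip(est_reps, truth_reps)]
        )
    )


def average_rmse_a(est_reps, truth_reps) -> float:
    """Average over replications of the per-replication discrimination RMSE."""
    _check_reps(est_reps, truth_reps)
    return float(
        np.mean(
            [
                _rmse(e.discriminations, t.discriminations)
                for e, t in zip(est_reps, truth_reps)
            ]
        )
    )


def average_rmse_p(est_reps, truth_reps) -> float:
    """Average RMSE of the person-item response probabilities.

    Probabilities are computed from the (untransformed) estimated and true
    parameter sets via the response function; the RMSE runs over all
    person-item cells within a replication.
    """
    from .datagen import response_probabilities

    _check_reps(est_reps, truth_reps)
    vals = []
    for e, t in zip(est_reps, truth_reps):
        vals.append(_rmse(response_probabilities(e), response_probabilities(t)))
    return float(np.mean(vals))


def average_se(se_reps) -> float:
    """Mean SE within each replication, averaged over replications."""
    if len(se_reps) == 0:
        raise ValueError("need R >= 1 replications")
    return float(np.mean([np.mean(se) for se in se_reps]))


# ---------------------------------------------------------------------------
# eta^2 ANOVA over the simulation design
# ---------------------------------------------------------------------------

def anova_eta2(
    observations: pd.DataFrame,
    metric: str,
    factors: tuple = ("EM", "SS", "TL"),
) -> pd.DataFrame:
    """Fixed-effects eta^2 decomposition on a balanced full factorial.

    One row per main effect, two-way interaction, the highest-order
    interaction, and the residual; eta^2 = SS_effect / SS_total in
    percent, flagged small / medium / large at the 8% / 14% thresholds.
    Raises on unbalanced designs (the study design is balanced).
    """
    df = observations
    counts = df.groupby(list(factors), observed=True).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal cell counts")
    y = df[metric].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    def cell_means(cols):
        return df.groupby(list(cols), observed=True)[metric].transform("mean").to_numpy()

    present = [f for f in factors if df[f].nunique() > 1]
    effects = {}
    # main effects
    for f in factors:
        effects[(f,)] = float(((cell_means([f]) - grand) ** 2).sum()) if f in present else 0.0
    # interactions, built by inclusion-exclusion over lower-order terms
    for order in range(2, len(factors) + 1):
        for combo in combinations(factors, order):
            if not all(f in present for f in combo):
                effects[combo] = 0.0
                continue
            ss_full = float(((cell_means(combo) - grand) ** 2).sum())
            lower = sum(
                effects[sub]
                for o in range(1, order)
                for sub in combinations(combo, o)
            )
            effects[combo] = max(ss_full - lower, 0.0)
    ss_model = sum(effects.values())
    ss_resid = max(ss_total - ss_model, 0.0)

    def label(pct):
        if pct > 14.0:
            return "large"
        if pct >= 8.0:
            return "medium"
        return "small"

    rows = []
    for combo, ss in effects.items():
        pct = 100.0 * ss / ss_total if ss_total > 0 else 0.0
        rows.append(
            {"effect": " x ".join(combo), "SS": ss, "eta2_pct": pct, "size": label(pct)}
        )
    pct = 100.0 * ss_resid / ss_total if ss_total > 0 else 0.0
    rows.append({"effect": "residual", "SS": ss_resid, "eta2_pct": pct, "size": label(pct)})
    return pd.DataFrame(rows)
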