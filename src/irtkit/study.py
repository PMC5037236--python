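"""Simulation-study orchestration: crossed design, pairing, resumability.

The study crosses sample size x test length x estimation method for a
given model, with R replications per cell.  Within a replication every
method sees the *same* response matrix: the data seed is derived from the
root seed and (model, S, L, replication) only — never from the method —
so method comparisons are paired.  Each finished cell is persisted as a
CSV of per-replication metrics; re-running a study recomputes only the
missing cells.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cml import fit_cml
from .datagen import draw_parameters, simulate_responses
from .evaluation import align, average_rmse_p
from .mcmc import fit_mcmc, summarize
from .mml import fit_mml
from .model import make_prior
from .types import ModelTag
from .vb import fit_vb

log = logging.getLogger("irtkit.study")

ALL_METHODS_1PL = (
    "CML",
    "MML",
    "MCMC-matched",
    "MCMC-stdvague",
    "MCMC-hierarchical",
    "VB-matched",
    "VB-stdvague",
    "VB-hierarchical",
)
ALL_METHODS_2PL = tuple(m for m in ALL_METHODS_1PL if m != "CML")

_METRIC_COLS = [
    "rmse_theta", "rmse_b", "rmse_a", "rmse_p",
    "mean_se_theta", "mean_se_b", "mean_se_a",
]


@dataclass
class StudyDesign:
    """Crossed simulation design (a subset of the full study grid)."""

    model: ModelTag = "1PL"
    sample_sizes: Sequence[int] = (250, 500, 1000, 2000)
    test_lengths: Sequence[int] = (10, 20, 40)
    methods: Sequence[str] = ALL_METHODS_1PL
    replications: int = 100
    root_seed: int = 0
    burnin: int = 5000
    keep: int = 1000
    vb_tol: float = 1e-6
    vb_max_sweeps: int = 500

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("need at least one replication")
        if self.model == "2PL" and "CML" in self.methods:
            raise ValueError("CML is only defined for the 1PL model")

    def cells(self):
        for S in self.sample_sizes:
            for L in self.test_lengths:
                for method in self.methods:
                    yield S, L, method


def derive_seed(root_seed: int, model: str, S: int, L: int, rep: int) -> int:
    """Replication-level data seed; independent of the estimation method."""
    key = f"{root_seed}|{model}|{S}|{L}|{rep}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") & 0x7FFFFFFF


def make_dataset(root_seed: int, model: ModelTag, S: int, L: int, rep: int):
    """The paired (truth, responses) pair every method sees for a replication."""
    seed = derive_seed(root_seed, model, S, L, rep)
    truth = draw_parameters(S, L, model, seed)
    data = simulate_responses(truth, seed)
    return truth, data


def fit_one(data, model: ModelTag, method: str, seed: int, design: StudyDesign):
    """Dispatch a single fit; returns ParameterEstimates."""
    if method == "CML":
        return fit_cml(data)
    if method == "MML":
        return fit_mml(data, model)
    family, _, regime = method.partition("-")
    prior = make_prior(regime, model)
    if family == "MCMC":
        draws = fit_mcmc(
            data, model, prior,
            chains=1, burnin=design.burnin, keep=design.keep, seed=seed,
        )
        return summarize(draws)
    if family == "VB":
        _, est = fit_vb(
            data, model, prior,
            tol=design.vb_tol, max_sweeps=design.vb_max_sweeps,
        )
        return est
    raise ValueError(f"unknown method {method!r}")


def run_condition(design: StudyDesign, S: int, L: int, method: str) -> pd.DataFrame:
    """Run one design cell: R replications of generate / fit / align / measure.

    Returns a frame with one row per replication; estimator failures are
    recorded as missing metric rows with ``failed=True``, never dropped
    silently.
    """
    rows = []
    for rep in range(design.replications):
        seed = derive_seed(design.root_seed, design.model, S, L, rep)
        truth, data = make_dataset(design.root_seed, design.model, S, L, rep)
        row = {
            "model": design.model, "method": method, "S": S, "L": L,
            "rep": rep, "failed": False, "converged": True,
        }
        t0 = time.perf_counter()
        try:
            est = fit_one(data, design.model, method, seed, design)
            res = align(est, truth, design.model)
            al = res.aligned
            row.update(
                rmse_theta=float(np.sqrt(np.mean((al.abilities - truth.abilities) ** 2))),
                rmse_b=float(np.sqrt(np.mean((al.difficulties - truth.difficulties) ** 2))),
                rmse_a=(
                    float(np.sqrt(np.mean((al.discriminations - truth.discriminations) ** 2)))
                    if design.model == "2PL" else 0.0
                ),
                rmse_p=average_rmse_p([est], [truth]),
                mean_se_theta=float(np.mean(est.se_abilities)),
                mean_se_b=float(np.mean(est.se_difficulties)),
                mean_se_a=(
                    float(np.mean(est.se_discriminations))
                    if design.model == "2PL" else 0.0
                ),
                align_s=res.s, align_t=res.t,
                converged=bool(est.converged),
            )
        except Exception as exc:  # noqa: BLE001 — failures are data, not fatal
            log.warning("fit failed: %s S=%d L=%d rep=%d: %s", method, S, L, rep, exc)
            row["failed"] = True
            row["error"] = str(exc)
            for colname in _METRIC_COLS:
                row[colname] = np.nan
        row["seconds"] = time.perf_counter() - t0
        rows.append(row)
    return pd.DataFrame(rows)


def _cell_path(out_dir: Path, model, method, S, L) -> Path:
    return out_dir / f"cell_{model}_{method}_S{S}_L{L}.csv"


def run_study(design: StudyDesign, out_dir) -> pd.DataFrame:
    """Run (or resume) every cell of a design, persisting per-cell CSVs.

    Cells whose CSV already exists are loaded, not recomputed.  Returns
    the concatenated long-format results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for S, L, method in design.cells():
        path = _cell_path(out_dir, design.model, method, S, L)
        if path.exists():
            frames.append(pd.read_csv(path))
            continue
        log.info("running cell model=%s method=%s S=%d L=%d", design.model, method, S, L)
        cell = run_condition(design, S, L, method)
        cell.to_csv(path, index=False)
        frames.append(cell)
    if not frames:
        return pd.DataFrame()
    results = pd.concat(frames, ignore_index=True)
    results.to_csv(out_dir / f"results_{design.model}.csv", index=False)
    return results


# ---------------------------------------------------------------------------
# Report tables (marginal means with equal cell weighting)
# ---------------------------------------------------------------------------

_TABLE_SPECS = {
    # marginal means by estimation method (1PL)
    "T3": dict(by=["method"], metrics=["rmse_theta", "mean_se_theta", "rmse_b",
                                       "mean_se_b", "rmse_p"]),
    # 1PL: by sample size (difficulty) and test length (ability, probability)
    "T4": dict(by=["method", "S", "L"], metrics=None),
    # 2PL marginal means by test length
    "T6": dict(by=["method", "L"], metrics=["rmse_theta", "mean_se_theta", "rmse_p"]),
    # 2PL marginal means by sample size
    "T7": dict(by=["method", "S"], metrics=["rmse_b", "mean_se_b", "rmse_a",
                                            "mean_se_a"]),
    # 2PL marginal means by method
    "T8": dict(by=["method"], metrics=["rmse_theta", "mean_se_theta", "rmse_b",
                                       "mean_se_b", "rmse_a", "mean_se_a", "rmse_p"]),
}


def _equal_weight_marginal(results: pd.DataFrame, by, metrics) -> pd.DataFrame:
    """Mean over replications within cell, then unweighted mean over cells."""
    ok = results[~results["failed"]]
    cell_means = ok.groupby(["method", "S", "L"], observed=True)[metrics].mean().reset_index()
    return cell_means.groupby(by, observed=True)[metrics].mean().reset_index()


def tabulate(results: pd.DataFrame, table: str) -> pd.DataFrame:
    """Compute one of the report tables from long-format study results.

    ``table`` is one of T3, T4, T6, T7, T8.  Raises with an explicit list
    of gaps if required cells are missing entirely.
    """
    if table not in _TABLE_SPECS:
        raise ValueError(f"unknown table {table!r}; choose from {sorted(_TABLE_SPECS)}")
    if results.empty:
        raise ValueError("empty results")
    missing = results.groupby(["method", "S", "L"], observed=True)["failed"].all()
    gaps = missing[missing].index.tolist()
    if gaps:
        raise ValueError(f"cells with no successful replication: {gaps}")
    spec = _TABLE_SPECS[table]
    if table == "T4":
        by_ss = _equal_weight_marginal(results, ["method", "S"], ["rmse_b", "mean_se_b"])
        by_tl = _equal_weight_marginal(
            results, ["method", "L"], ["rmse_theta", "mean_se_theta", "rmse_p"]
        )
        by_ss = by_ss.melt(id_vars=["method", "S"], var_name="metric")
        by_ss = by_ss.rename(columns={"S": "level"}).assign(margin="SS")
        by_tl = by_tl.melt(id_vars=["method", "L"], var_name="metric")
        by_tl = by_tl.rename(columns={"L": "level"}).assign(margin="TL")
        long = pd.concat([by_ss, by_tl], ignore_index=True)
        return long.pivot_table(
            index=["margin", "metric", "level"], columns="method", values="value",
            observed=True,
        ).reset_index()
    metrics = spec["metrics"]
    return _equal_weight_marginal(results, spec["by"], metrics)


def format_table(df: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a report table."""
    return df.to_string(index=False, float_format=lambda x: f"{x:8.3f}")
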