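"""Shared domain containers: true parameters, response data, estimates, priors.

Conventions used throughout the package:

* ``theta`` — person ability on the logit scale.
* ``b`` — item difficulty (location) on the logit scale.
* ``a`` — item discrimination (slope); fixed at 1 for the 1PL model.
* Model tags are the strings ``"1PL"`` and ``"2PL"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd

ModelTag = Literal["1PL", "2PL"]

VALID_MODELS = ("1PL", "2PL")


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class TrueParameters:
    """Generating parameters for a simulated test administration."""

    abilities: np.ndarray
    difficulties: np.ndarray
    discriminations: np.ndarray
    model: ModelTag = "2PL"

    def __post_init__(self) -> None:
        self.abilities = _as_1d(self.abilities, "abilities")
        self.difficulties = _as_1d(self.difficulties, "difficulties")
        self.discriminations = _as_1d(self.discriminations, "discriminations")
        if self.model not in VALID_MODELS:
            raise ValueError(f"unknown model tag {self.model!r}")
        if len(self.discriminations) != len(self.difficulties):
            raise ValueError("discriminations and difficulties must have equal length")
        if np.any(self.discriminations <= 0):
            raise ValueError("discriminations must be strictly positive")
        if self.model == "1PL" and not np.all(self.discriminations == 1.0):
            raise ValueError("1PL requires all discriminations equal to 1")

    @property
    def n_persons(self) -> int:
        return len(self.abilities)

    @property
    def n_items(self) -> int:
        return len(self.difficulties)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns kind/index/value."""
        rows = []
        for kind, vec in (
            ("ability", self.abilities),
            ("difficulty", self.difficulties),
            ("discrimination", self.discriminations),
        ):
            rows.append(
                pd.DataFrame({"kind": kind, "index": np.arange(len(vec)), "value": vec})
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path], model: ModelTag = "2PL") -> "TrueParameters":
        df = pd.read_csv(path)
        pick = lambda kind: (
            df[df["kind"] == kind].sort_values("index")["value"].to_numpy()
        )
        return cls(
            abilities=pick("ability"),
            difficulties=pick("difficulty"),
            discriminations=pick("discrimination"),
            model=model,
        )


@dataclass
class ResponseMatrix:
    """S x L matrix of binary item responses with person/item labels."""

    entries: np.ndarray
    person_ids: Optional[np.ndarray] = None
    item_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries)
        if arr.ndim != 2:
            raise ValueError(f"entries must be 2-D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("entries must contain only 0 and 1")
        self.entries = arr.astype(np.int8)
        if self.person_ids is None:
            self.person_ids = np.array([f"p{i}" for i in range(arr.shape[0])])
        if self.item_ids is None:
            self.item_ids = np.array([f"i{k}" for k in range(arr.shape[1])])
        if len(self.person_ids) != arr.shape[0] or len(self.item_ids) != arr.shape[1]:
            raise ValueError("id labels do not match entry dimensions")

    @property
    def n_persons(self) -> int:
        return self.entries.shape[0]

    @property
    def n_items(self) -> int:
        return self.entries.shape[1]

    @property
    def raw_scores(self) -> np.ndarray:
        return self.entries.sum(axis=1)

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            self.entries, index=pd.Index(self.person_ids, name="person"),
            columns=self.item_ids,
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ResponseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            entries=df.to_numpy(),
            person_ids=df.index.to_numpy(),
            item_ids=df.columns.to_numpy(),
        )


@dataclass
class PriorConfig:
    """A named prior regime for the Bayesian estimators.

    Flat regimes (``matched``, ``stdvague``) carry fixed normal priors as
    ``(mean, variance)`` pairs; the ``hierarchical`` regime replaces the
    difficulty / log-discrimination (and ability) prior parameters with
    normal-gamma hyperpriors: hyper-means ~ N(0, 1e6) and precisions
    ~ Gamma(shape 1, rate 1).  The discrimination prior always lives on the
    log scale (a is lognormal iff log a is normal).  ``regime="none"`` marks
    the likelihood-only estimators (CML / MML).
    """

    regime: str
    model: ModelTag
    ability_prior: Optional[tuple] = None  # (mean, variance)
    difficulty_prior: Optional[tuple] = None
    log_discrimination_prior: Optional[tuple] = None
    hierarchical_ability: bool = False
    hierarchical_difficulty: bool = False
    hierarchical_discrimination: bool = False
    hyper_mean_prior: tuple = (0.0, 1.0e6)  # normal (mean, variance)
    hyper_precision_prior: tuple = (1.0, 1.0)  # gamma (shape, rate)

    def __post_init__(self) -> None:
        if self.regime not in ("matched", "stdvague", "hierarchical", "none"):
            raise ValueError(f"unknown prior regime {self.regime!r}")
        for name in ("ability_prior", "difficulty_prior", "log_discrimination_prior"):
            val = getattr(self, name)
            if val is not None and val[1] <= 0:
                raise ValueError(f"{name} variance must be strictly positive")


@dataclass
class ParameterEstimates:
    """Point estimates with per-parameter standard errors.

    ``se_*`` holds information-based SEs for the likelihood methods and
    posterior standard deviations for the Bayesian ones.  For 1PL fits the
    discriminations are identically 1 with SE 0.
    """

    abilities: np.ndarray
    difficulties: np.ndarray
    discriminations: np.ndarray
    se_abilities: np.ndarray
    se_difficulties: np.ndarray
    se_discriminations: np.ndarray
    method: str = ""
    prior: str = "none"
    model: ModelTag = "2PL"
    converged: bool = True
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "abilities", "difficulties", "discriminations",
            "se_abilities", "se_difficulties", "se_discriminations",
        ):
            setattr(self, name, _as_1d(getattr(self, name), name))
        if len(self.difficulties) != len(self.discriminations):
            raise ValueError("item vectors must have equal length")
        if len(self.abilities) != len(self.se_abilities):
            raise ValueError("abilities and se_abilities length mismatch")
        for name in ("se_abilities", "se_difficulties", "se_discriminations"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, est, se in (
            ("ability", self.abilities, self.se_abilities),
            ("difficulty", self.difficulties, self.se_difficulties),
            ("discrimination", self.discriminations, self.se_discriminations),
        ):
            rows.append(
                pd.DataFrame(
                    {
                        "kind": kind,
                        "index": np.arange(len(est)),
                        "estimate": est,
                        "se": se,
                        "method": self.method,
                        "prior": self.prior,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path], model: ModelTag = "2PL") -> "ParameterEstimates":
        df = pd.read_csv(path)
        pick = lambda kind, col: (
            df[df["kind"] == kind].sort_values("index")[col].to_numpy()
        )
        return cls(
            abilities=pick("ability", "estimate"),
            difficulties=pick("difficulty", "estimate"),
            discriminations=pick("discrimination", "estimate"),
            se_abilities=pick("ability", "se"),
            se_difficulties=pick("difficulty", "se"),
            se_discriminations=pick("discrimination", "se"),
            method=str(df["method"].iloc[0]),
            prior=str(df["prior"].iloc[0]),
            model=model,
        )
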