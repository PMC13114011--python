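"""Shared containers for symptom networks.

The central object is :class:`IsingModel`: a pairwise binary Markov random
field over labeled symptom nodes, parameterized by a symmetric coupling
matrix ``omega`` (edge weights, log-odds scale) and a threshold vector
``tau`` (intercepts, log-odds scale).  The probability of an activation
pattern x in {0,1}^p is

    P(x) ∝ exp( Σ_i tau_i x_i  +  Σ_{i<j} omega_ij x_i x_j ).

Under this parameterization a negative threshold means the symptom tends to
stay inactive when all its neighbours are inactive, which is the reading
used throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["IsingModel", "BinaryMatrix", "SymptomPanel"]


@dataclass
class IsingModel:
    """Labeled Ising model: couplings ``omega``, thresholds ``tau``.

    Parameters
    ----------
    nodes
        Ordered node labels, e.g. ``["PHQ1", ..., "GAD7"]``.
    omega
        ``(p, p)`` symmetric coupling matrix with zero diagonal.
    tau
        Length-``p`` threshold vector.
    communities
        Optional node -> community mapping (a-priori symptom domains,
        e.g. ``"depression"`` / ``"anxiety"``).
    meta
        Free-form provenance (seed, estimator settings, ...).
    """

    nodes: list[str]
    omega: np.ndarray
    tau: np.ndarray
    communities: dict[str, str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        p = len(self.nodes)
        if self.omega.shape != (p, p):
            raise ValueError(f"omega must be ({p}, {p}), got {self.omega.shape}")
        if self.tau.shape != (p,):
            raise ValueError(f"tau must have length {p}, got {self.tau.shape}")
        if not np.all(np.isfinite(self.omega)) or not np.all(np.isfinite(self.tau)):
            raise ValueError("omega and tau must be finite")
        if not np.allclose(self.omega, self.omega.T, atol=1e-12):
            raise ValueError("omega must be symmetric")
        if np.any(np.diag(self.omega) != 0):
            raise ValueError("omega must have a zero diagonal")
        if self.communities is not None:
            missing = set(self.nodes) - set(self.communities)
            if missing:
                raise ValueError(f"nodes without a community: {sorted(missing)}")

    @property
    def p(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.omega[iu]))

    def node_index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def edge_list(self) -> pd.DataFrame:
        """Nonzero edges as a tidy table (node_i, node_j, weight)."""
        i, j = np.triu_indices(self.p, k=1)
        w = self.omega[i, j]
        keep = w != 0
        return pd.DataFrame(
            {
                "node_i": np.asarray(self.nodes)[i[keep]],
                "node_j": np.asarray(self.nodes)[j[keep]],
                "weight": w[keep],
            }
        )

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "communities": self.communities,
            "omega": self.omega.ravel().tolist(),
            "tau": self.tau.tolist(),
            "meta": self.meta,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: Mapping) -> "IsingModel":
        p = len(d["nodes"])
        return cls(
            nodes=list(d["nodes"]),
            omega=np.asarray(d["omega"], dtype=float).reshape(p, p),
            tau=np.asarray(d["tau"], dtype=float),
            communities=dict(d["communities"]) if d.get("communities") else None,
            meta=dict(d.get("meta", {})),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "IsingModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class BinaryMatrix:
    """Participants x items activation matrix with values in {0, 1}."""

    data: pd.DataFrame
    communities: dict[str, str] | None = None

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("BinaryMatrix entries must be 0 or 1")
        self.data = self.data.astype(np.int8)

    @property
    def nodes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n(self) -> int:
        return len(self.data)

    def prevalence(self) -> pd.Series:
        return self.data.mean()

    def subset(self, nodes: Sequence[str]) -> "BinaryMatrix":
        comm = (
            {k: v for k, v in self.communities.items() if k in set(nodes)}
            if self.communities
            else None
        )
        return BinaryMatrix(self.data[list(nodes)], comm)


@dataclass
class SymptomPanel:
    """Participants x items ordinal questionnaire table.

    ``scores`` holds integer item scores; ``item_scales`` maps each item to
    its instrument ("PHQ", "GAD" or "NMP"); ``score_ranges`` gives the
    declared (min, max) per item; ``response_times`` is an optional
    per-participant mean seconds-per-item vector.
    """

    scores: pd.DataFrame
    item_scales: dict[str, str]
    score_ranges: dict[str, tuple[int, int]]
    response_times: pd.Series | None = None

    def __post_init__(self) -> None:
        for item in self.scores.columns:
            if item not in self.item_scales:
                raise ValueError(f"item {item!r} has no scale assignment")
            lo, hi = self.score_ranges[item]
            col = self.scores[item]
            if col.isna().any():
                raise ValueError(f"item {item!r} contains missing values")
            if (col < lo).any() or (col > hi).any():
                raise ValueError(f"item {item!r} outside declared range [{lo}, {hi}]")
        if self.response_times is not None and len(self.response_times) != len(self.scores):
            raise ValueError("response_times length must match number of participants")

    @property
    def items(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n(self) -> int:
        return len(self.scores)

    def items_of(self, scale: str) -> list[str]:
        return [c for c in self.scores.columns if self.item_scales[c] == scale]

    def communities(self) -> dict[str, str]:
        """A-priori community labels for the PHQ/GAD network items."""
        names = {"PHQ": "depression", "GAD": "anxiety"}
        return {
            item: names[self.item_scales[item]]
            for item in self.items
            if self.item_scales[item] in names
        }

    def total(self, scale: str) -> pd.Series:
        return self.scores[self.items_of(scale)].sum(axis=1)

    def to_csv(self, path: str | Path) -> None:
        df = self.scores.copy()
        if self.response_times is not None:
            df["rt_per_item_s"] = self.response_times.to_numpy()
        df.to_csv(path, index=False)
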