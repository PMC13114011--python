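"""Node centrality: expected influence and bridge expected influence.

One-step expected influence (EI) of a node is the signed sum of its edge
weights; bridge EI restricts the sum to edges that cross a-priori
community boundaries and quantifies a symptom's role in linking distinct
symptom domains.  Centralities are z-standardized across nodes and nodes
more than one standard deviation above the mean are flagged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .models import IsingModel

__all__ = [
    "expected_influence",
    "bridge_expected_influence",
    "standardize",
    "centrality_table",
]


def expected_influence(model: IsingModel) -> pd.Series:
    """One-step EI: EI_i = sum_j omega_ij (signed row sum)."""
    return pd.Series(model.omega.sum(axis=1), index=model.nodes, name="EI")


def bridge_expected_influence(
    model: IsingModel, communities: dict[str, str] | None = None
) -> pd.Series:
    """One-step bridge EI: sum of weights to nodes in other communities."""
    comm = communities if communities is not None else model.communities
    if comm is None:
        raise ValueError("bridge EI requires a node -> community mapping")
    missing = set(model.nodes) - set(comm)
    if missing:
        raise ValueError(f"nodes without a community: {sorted(missing)}")
    labels = np.array([comm[n] for n in model.nodes])
    cross = labels[:, None] != labels[None, :]
    return pd.Series(
        (model.omega * cross).sum(axis=1), index=model.nodes, name="bridge_EI"
    )


def standardize(values: pd.Series | np.ndarray) -> tuple[pd.Series, pd.Series]:
    """Z-scores (n-1 SD) and strict z > 1 flags.

    A constant vector has no meaningful z-scores: they are set to zero
    (with a warning) and nothing is flagged.
    """
    v = pd.Series(values)
    if len(v) < 2:
        raise ValueError("standardization needs at least two values")
    sd = v.std(ddof=1)
    if sd == 0:
        warnings.warn("constant centrality vector; z-scores set to 0", stacklevel=2)
        z = pd.Series(np.zeros(len(v)), index=v.index)
    else:
        z = (v - v.mean()) / sd
    return z, z > 1.0


def centrality_table(
    model: IsingModel, communities: dict[str, str] | None = None
) -> pd.DataFrame:
    """EI (and bridge EI when communities are known) with z-scores and flags."""
    comm = communities if communities is not None else model.communities
    ei = expected_influence(model)
    z_ei, flag_ei = standardize(ei)
    out = pd.DataFrame({
        "community": pd.Series(comm) if comm else pd.Series("all", index=ei.index),
        "EI": ei,
        "z_EI": z_ei,
        "flag_EI": flag_ei,
    })
    if comm is not None and len(set(comm.values())) > 1:
        bei = bridge_expected_influence(model, comm)
        z_bei, flag_bei = standardize(bei)
        out["bridge_EI"] = bei
        out["z_bridge_EI"] = z_bei
        out["flag_bridge"] = flag_bei
    out.index.name = "node"
    return out.loc[model.nodes]
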