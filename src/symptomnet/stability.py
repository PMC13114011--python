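"""Bootstrap accuracy and stability diagnostics for Ising networks.

Nonparametric row-resampling bootstrap for edge-weight confidence
intervals and pairwise difference tests, and the case-dropping bootstrap
for centrality stability summarized by the correlation-stability
coefficient (CS-C): the largest fraction of participants that can be
dropped while the correlation between original and subsample centrality
orderings stays at or above 0.7 with 95% probability.  CS-C above 0.25,
0.5 and 0.75 is conventionally read as acceptable, good and excellent
stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .centrality import expected_influence
from .ising_fit import fit_ising
from .models import BinaryMatrix, IsingModel

__all__ = [
    "EdgeBootstrap",
    "StabilityCurve",
    "nonparametric_bootstrap",
    "difference_test",
    "case_dropping",
    "cs_coefficient",
    "CS_INTERPRETATION",
]

log = logging.getLogger(__name__)

DEFAULT_B = 1000
DEFAULT_PROPORTIONS = (0.1, 0.2, 0.25, 0.3, 0.4, 0.5, 0.6, 0.7, 0.75)
CS_INTERPRETATION = {0.25: "acceptable", 0.5: "good", 0.75: "excellent"}


def _pair_label(a: str, b: str) -> str:
    return f"{a}--{b}"


@dataclass
class EdgeBootstrap:
    """Row-resampling bootstrap of the full Ising fit."""

    observed: IsingModel
    edge_draws: pd.DataFrame  # B x pairs, columns "i--j"
    tau_draws: pd.DataFrame   # B x nodes
    ei_draws: pd.DataFrame    # B x nodes
    B: int
    n_failed: int
    seed: int | None

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Per-edge observed weight, bootstrap mean, and quantile CI."""
        lo, hi = 50 * (1 - level), 50 * (1 + level)
        iu = np.triu_indices(self.observed.p, k=1)
        rows = []
        for i, j in zip(*iu):
            a, b = self.observed.nodes[i], self.observed.nodes[j]
            draws = self.edge_draws[_pair_label(a, b)]
            rows.append({
                "node_i": a,
                "node_j": b,
                "weight": self.observed.omega[i, j],
                "boot_mean": draws.mean(),
                "ci_low": np.percentile(draws, lo),
                "ci_high": np.percentile(draws, hi),
            })
        return pd.DataFrame(rows)


@dataclass
class StabilityCurve:
    """Case-dropping bootstrap correlations, long format."""

    samples: pd.DataFrame  # columns: drop, replicate, correlation
    centrality: str
    n_skipped: int = 0
    degenerate: bool = False

    @property
    def proportions(self) -> np.ndarray:
        return np.sort(self.samples["drop"].unique())

    def quantile(self, q: float = 0.05) -> pd.Series:
        return self.samples.groupby("drop")["correlation"].quantile(q)


def nonparametric_bootstrap(
    X: BinaryMatrix,
    B: int = DEFAULT_B,
    seed: int | None = None,
    **fit_kwargs,
) -> EdgeBootstrap:
    """Resample rows with replacement B times and refit the whole pipeline.

    Failed refits (e.g. a resample with a constant column) are dropped and
    tallied.  Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if B < DEFAULT_B:
        log.warning("B=%d below the recommended %d resamples", B, DEFAULT_B)
    rng = np.random.default_rng(seed)
    observed = fit_ising(X, **fit_kwargs)
    nodes = observed.nodes
    iu = np.triu_indices(observed.p, k=1)
    pair_labels = [_pair_label(nodes[i], nodes[j]) for i, j in zip(*iu)]

    edge_rows, tau_rows, ei_rows = [], [], []
    n_failed = 0
    n = X.n
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        resample = BinaryMatrix(X.data.iloc[idx].reset_index(drop=True), X.communities)
        try:
            m = fit_ising(resample, **fit_kwargs)
        except Exception as exc:
            n_failed += 1
            log.info("bootstrap resample failed: %s", exc)
            continue
        edge_rows.append(m.omega[iu])
        tau_rows.append(m.tau)
        ei_rows.append(expected_influence(m).to_numpy())
    if n_failed:
        log.warning("%d/%d bootstrap resamples failed and were dropped", n_failed, B)
    return EdgeBootstrap(
        observed=observed,
        edge_draws=pd.DataFrame(edge_rows, columns=pair_labels),
        tau_draws=pd.DataFrame(tau_rows, columns=nodes),
        ei_draws=pd.DataFrame(ei_rows, columns=nodes),
        B=B,
        n_failed=n_failed,
        seed=seed,
    )


def difference_test(
    boot: EdgeBootstrap,
    a: str | tuple[str, str],
    b: str | tuple[str, str],
    level: float = 0.05,
) -> bool:
    """Bootstrapped difference test between two edges or two nodes' EI.

    Significant iff the (1 - level) bootstrap quantile interval of the
    paired differences excludes zero.  Edges are addressed as
    ``(node_i, node_j)`` tuples, nodes by label (EI difference).
    """
    def draws_of(x):
        if isinstance(x, tuple):
            lab = _pair_label(*x)
            alt = _pair_label(x[1], x[0])
            if lab in boot.edge_draws:
                return boot.edge_draws[lab]
            if alt in boot.edge_draws:
                return boot.edge_draws[alt]
            raise KeyError(f"unknown edge {x!r}")
        if x in boot.ei_draws.columns:
            return boot.ei_draws[x]
        raise KeyError(f"unknown node {x!r}")

    diff = draws_of(a).to_numpy() - draws_of(b).to_numpy()
    lo, hi = np.percentile(diff, [100 * level / 2, 100 * (1 - level / 2)])
    return not (lo <= 0.0 <= hi)


def case_dropping(
    X: BinaryMatrix,
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
    B: int = DEFAULT_B,
    centrality_fn: Callable[[IsingModel], pd.Series] | None = None,
    seed: int | None = None,
    corr: str = "pearson",
    **fit_kwargs,
) -> StabilityCurve:
    """Case-dropping bootstrap for centrality stability.

    For each drop proportion d, draw B subsamples of ceil((1-d) n) rows
    without replacement, refit, and record the correlation between the
    full-sample and subsample centrality vectors.  Subsamples too small to
    fit (fewer than 3p rows) or that fail to refit are skipped and
    tallied.
    """
    props = tuple(sorted(float(d) for d in proportions))
    if any(not (0 < d <= 0.8) for d in props):
        raise ValueError("drop proportions must lie in (0, 0.8]")
    if len(set(props)) != len(props):
        raise ValueError("drop proportions must be distinct")
    if corr not in ("pearson", "spearman"):
        raise ValueError("corr must be 'pearson' or 'spearman'")
    centrality_fn = centrality_fn or expected_influence
    rng = np.random.default_rng(seed)
    full = fit_ising(X, **fit_kwargs)
    base = pd.Series(centrality_fn(full))
    name = getattr(centrality_fn, "__name__", "centrality")
    degenerate = base.std(ddof=1) == 0
    if degenerate:
        log.warning("full-sample %s vector is constant; correlations undefined", name)

    n, p = X.n, len(X.nodes)
    rows = []
    n_skipped = 0
    for d in props:
        n_sub = int(np.ceil((1 - d) * n))
        for rep in range(B):
            if n_sub < 3 * p:
                n_skipped += 1
                continue
            idx = rng.choice(n, size=n_sub, replace=False)
            sub = BinaryMatrix(X.data.iloc[idx].reset_index(drop=True), X.communities)
            try:
                m = fit_ising(sub, **fit_kwargs)
            except Exception as exc:
                n_skipped += 1
                log.info("case-dropping refit failed at d=%.2f: %s", d, exc)
                continue
            vec = pd.Series(centrality_fn(m)).reindex(base.index)
            if degenerate or vec.std(ddof=1) == 0:
                r = np.nan
            else:
                r = base.corr(vec, method=corr)
            rows.append({"drop": d, "replicate": rep, "correlation": r})
    return StabilityCurve(
        samples=pd.DataFrame(rows, columns=["drop", "replicate", "correlation"]),
        centrality=name,
        n_skipped=n_skipped,
        degenerate=degenerate,
    )


def cs_coefficient(
    curve: StabilityCurve, r_min: float = 0.7, prob: float = 0.95
) -> float:
    """Correlation-stability coefficient.

    The largest tested drop proportion d such that, at every tested
    proportion up to and including d, the empirical (1 - prob) quantile of
    the correlations is at least ``r_min``; 0.0 if no proportion
    qualifies.  The monotone guard prevents an isolated pass at a high
    drop rate from inflating the coefficient.
    """
    if curve.degenerate or curve.samples["correlation"].isna().all():
        raise ValueError("degenerate stability curve; CS-C undefined")
    q = curve.quantile(1 - prob)
    cs = 0.0
    for d in np.sort(q.index.to_numpy()):
        if np.isnan(q[d]) or q[d] < r_min:
            break
        cs = float(d)
    return cs
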