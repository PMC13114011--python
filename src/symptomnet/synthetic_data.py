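"""Synthetic symptom-network data.

Ground-truth generators and samplers used to exercise and validate every
downstream stage of the pipeline: sparse attractive Ising models with two
a-priori symptom communities (9 depression + 7 anxiety nodes by default),
exact enumeration of the model distribution (the brute-force oracle for the
samplers and for intervention analysis), i.i.d. and Metropolis-Hastings
sampling, Gaussian-copula ordinal questionnaire panels with calibrated
binary prevalences, and planted response-time vectors for the
participant-quality filters.

The default generator settings emulate a college-student screening cohort:
all-positive couplings, all-negative thresholds, and item activation
prevalences roughly between 0.2 and 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import logsumexp, ndtri

from .models import BinaryMatrix, IsingModel, SymptomPanel

__all__ = [
    "make_ground_truth",
    "enumerate_distribution",
    "exact_expected_sum",
    "exact_marginals",
    "sample_ising",
    "OrdinalPanelSpec",
    "default_panel_spec",
    "generate_ordinal_panel",
    "generate_response_times",
    "TABLE_PREVALENCES",
]

MAX_ENUM_NODES = 20

# Default calibration targets for the 16 PHQ/GAD items: fraction of
# participants endorsing each symptom at any level (score > 0).
TABLE_PREVALENCES: dict[str, float] = {
    "PHQ1": 0.64, "PHQ2": 0.47, "PHQ3": 0.54, "PHQ4": 0.64, "PHQ5": 0.56,
    "PHQ6": 0.44, "PHQ7": 0.55, "PHQ8": 0.36, "PHQ9": 0.23,
    "GAD1": 0.66, "GAD2": 0.58, "GAD3": 0.67, "GAD4": 0.57, "GAD5": 0.48,
    "GAD6": 0.60, "GAD7": 0.49,
}

# Per-block edge densities reproducing the comorbidity-network edge counts
# of 33 within-depression, 20 within-anxiety and 34 cross-community edges
# on a 9 + 7 node graph (block sizes 36, 21, 63).
PAPER_BLOCK_DENSITY: tuple[float, float, float] = (33 / 36, 20 / 21, 34 / 63)


def _block_pairs(idx_a: np.ndarray, idx_b: np.ndarray | None = None) -> list[tuple[int, int]]:
    if idx_b is None:
        return [(int(i), int(j)) for k, i in enumerate(idx_a) for j in idx_a[k + 1:]]
    return [(int(i), int(j)) for i in idx_a for j in idx_b]


def make_ground_truth(
    n_dep: int = 9,
    n_anx: int = 7,
    edge_density: float | tuple[float, float, float] = PAPER_BLOCK_DENSITY,
    weight_range: tuple[float, float] = (0.15, 0.6),
    tau_range: tuple[float, float] = (-3.1, -1.55),
    seed: int | None = None,
) -> IsingModel:
    """Draw a sparse attractive two-community ground-truth Ising model.

    Each of the three blocks (within-depression, within-anxiety,
    cross-community) receives exactly ``round(density * block_size)``
    edges, drawn uniformly at random without replacement; weights are
    i.i.d. uniform on ``weight_range`` (must be positive) and thresholds
    i.i.d. uniform on ``tau_range`` (must be negative).

    ``edge_density`` may be a scalar applied to all blocks or a
    ``(dep, anx, between)`` triple; the default reproduces the canonical
    33/20/34 block edge counts of the 16-node comorbidity graph.
    """
    if n_dep < 1 or n_anx < 1:
        raise ValueError("n_dep and n_anx must be >= 1")
    if np.isscalar(edge_density):
        densities = (float(edge_density),) * 3
    else:
        densities = tuple(float(d) for d in edge_density)  # type: ignore[arg-type]
        if len(densities) != 3:
            raise ValueError("edge_density must be a scalar or a (dep, anx, between) triple")
    if any(d < 0 or d > 1 for d in densities):
        raise ValueError("edge densities must lie in [0, 1]")
    lo_w, hi_w = weight_range
    if not (0 < lo_w <= hi_w):
        raise ValueError("weight_range must be a positive interval (attractive couplings)")
    lo_t, hi_t = tau_range
    if not (lo_t <= hi_t < 0):
        raise ValueError("tau_range must be a negative interval (deactivation-prone symptoms)")

    rng = np.random.default_rng(seed)
    p = n_dep + n_anx
    nodes = [f"PHQ{i + 1}" for i in range(n_dep)] + [f"GAD{i + 1}" for i in range(n_anx)]
    communities = {n: ("depression" if n.startswith("PHQ") else "anxiety") for n in nodes}
    dep_idx = np.arange(n_dep)
    anx_idx = np.arange(n_dep, p)

    omega = np.zeros((p, p))
    blocks = [
        _block_pairs(dep_idx),
        _block_pairs(anx_idx),
        _block_pairs(dep_idx, anx_idx),
    ]
    for pairs, density in zip(blocks, densities):
        n_edges = int(round(density * len(pairs)))
        if n_edges == 0:
            continue
        chosen = rng.choice(len(pairs), size=n_edges, replace=False)
        for k in chosen:
            i, j = pairs[k]
            w = rng.uniform(lo_w, hi_w)
            omega[i, j] = omega[j, i] = w
    tau = rng.uniform(lo_t, hi_t, size=p)

    return IsingModel(
        nodes=nodes,
        omega=omega,
        tau=tau,
        communities=communities,
        meta={"seed": seed, "generator": "make_ground_truth",
              "edge_density": densities, "weight_range": weight_range,
              "tau_range": tau_range},
    )


def _all_states(p: int) -> np.ndarray:
    """All 2^p binary row vectors, in integer order (bit 0 = node 0)."""
    ints = np.arange(2 ** p, dtype=np.int64)
    return ((ints[:, None] >> np.arange(p)) & 1).astype(np.int8)


def enumerate_distribution(model: IsingModel) -> pd.DataFrame:
    """Exact distribution over all 2^p activation patterns.

    Returns one row per state with the node columns, ``prob`` and
    ``sum_score``; this is the brute-force oracle behind the samplers and
    the exact intervention analysis.  Refuses models with more than
    ``MAX_ENUM_NODES`` nodes.
    """
    p = model.p
    if p > MAX_ENUM_NODES:
        raise ValueError(
            f"enumeration over 2^{p} states is infeasible; "
            f"use sample_ising(method='metropolis') for p > {MAX_ENUM_NODES}"
        )
    states = _all_states(p).astype(float)
    log_w = states @ model.tau + 0.5 * np.einsum("si,ij,sj->s", states, model.omega, states)
    log_z = logsumexp(log_w)
    probs = np.exp(log_w - log_z)
    out = pd.DataFrame(states.astype(np.int8), columns=model.nodes)
    out["prob"] = probs
    out["sum_score"] = states.sum(axis=1).astype(int)
    return out


def exact_expected_sum(model: IsingModel) -> float:
    """Exact expected network sum score E[Σ_i x_i] by enumeration."""
    dist = enumerate_distribution(model)
    return float(np.dot(dist["prob"], dist["sum_score"]))


def exact_marginals(model: IsingModel) -> pd.Series:
    """Exact per-node activation probabilities by enumeration."""
    dist = enumerate_distribution(model)
    return pd.Series(
        {n: float(np.dot(dist["prob"], dist[n])) for n in model.nodes}, name="p_active"
    )


@njit(cache=False)
def _mh_chain(omega, tau, state, n_keep, burn_in, thin, uniforms):  # pragma: no cover
    """Single-site-flip Metropolis chain; one sweep = one sequential pass."""
    p = tau.shape[0]
    out = np.empty((n_keep, p), dtype=np.int8)
    n_sweeps = burn_in + n_keep * thin
    u_idx = 0
    kept = 0
    for sweep in range(n_sweeps):
        for i in range(p):
            field = tau[i]
            for j in range(p):
                field += omega[i, j] * state[j]
            # log-probability change of flipping site i
            delta = (1.0 - 2.0 * state[i]) * field
            if delta >= 0.0 or uniforms[u_idx] < np.exp(delta):
                state[i] = 1.0 - state[i]
            u_idx += 1
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            for i in range(p):
                out[kept, i] = np.int8(state[i])
            kept += 1
    return out


def sample_ising(
    model: IsingModel,
    n_samples: int,
    method: str = "metropolis",
    burn_in: int = 1000,
    thin: int = 1,
    seed: int | None = None,
) -> BinaryMatrix:
    """Sample activation patterns from an Ising model.

    ``method="exact"`` draws i.i.d. from the enumerated distribution
    (p <= 20 only); ``method="metropolis"`` runs a single-site-flip
    Metropolis chain (one recorded sample per ``thin`` full sweeps after
    ``burn_in`` sweeps).  Deterministic given ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    p = model.p

    if method == "exact":
        dist = enumerate_distribution(model)
        probs = dist["prob"].to_numpy()
        idx = rng.choice(len(probs), size=n_samples, p=probs / probs.sum())
        data = _all_states(p)[idx]
    elif method == "metropolis":
        if burn_in < 0 or thin < 1:
            raise ValueError("burn_in must be >= 0 and thin >= 1")
        # start from the independent (omega = 0) model
        state = (rng.random(p) < 1.0 / (1.0 + np.exp(-model.tau))).astype(np.float64)
        uniforms = rng.random((burn_in + n_samples * thin) * p)
        data = _mh_chain(
            model.omega.astype(np.float64),
            model.tau.astype(np.float64),
            state,
            n_samples,
            burn_in,
            thin,
            uniforms,
        )
    else:
        raise ValueError(f"unknown sampling method {method!r}")

    return BinaryMatrix(pd.DataFrame(data, columns=model.nodes), model.communities)


@dataclass
class OrdinalPanelSpec:
    """Recipe for a Gaussian-copula ordinal questionnaire panel.

    Each item has an integer score range ``(lo, hi)`` and a target
    endorsement prevalence: the probability of scoring above ``lo``
    (for 0-based PHQ/GAD items this is exactly the binarized prevalence).
    ``latent_corr`` is the copula correlation matrix that induces the
    item dependencies.
    """

    items: list[str]
    score_ranges: dict[str, tuple[int, int]]
    prevalences: dict[str, float]
    latent_corr: np.ndarray
    item_scales: dict[str, str]
    n: int = 1638
    seed: int | None = None
    decay: float = 0.5  # geometric decay of mass across endorsed categories

    def __post_init__(self) -> None:
        k = len(self.items)
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        if self.latent_corr.shape != (k, k):
            raise ValueError("latent_corr shape must match number of items")
        if not np.allclose(self.latent_corr, self.latent_corr.T):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(self.latent_corr), 1.0):
            raise ValueError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(self.latent_corr)[0] <= 1e-10:
            raise ValueError("latent_corr must be positive-definite")
        for item in self.items:
            pi = self.prevalences[item]
            if not (0 < pi < 1):
                raise ValueError(f"prevalence of {item!r} must lie strictly in (0, 1)")
            lo, hi = self.score_ranges[item]
            if hi <= lo:
                raise ValueError(f"degenerate score range for {item!r}")


def _two_block_latent_corr(
    n_dep: int,
    n_anx: int,
    rng: np.random.Generator,
    within: tuple[float, float] = (0.35, 0.55),
    between: tuple[float, float] = (0.15, 0.30),
) -> np.ndarray:
    """Jittered two-block exchangeable correlation, repaired to PD."""
    p = n_dep + n_anx
    comm = np.array([0] * n_dep + [1] * n_anx)
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            lo, hi = within if comm[i] == comm[j] else between
            R[i, j] = R[j, i] = rng.uniform(lo, hi)
    # clip eigenvalues and renormalize to a proper correlation matrix
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, 1e-4, None)
    R = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    return R / np.outer(d, d)


def default_panel_spec(n: int = 1638, seed: int | None = None) -> OrdinalPanelSpec:
    """Standard 16-item PHQ-9 + GAD-7 panel with calibrated prevalences.

    Items are scored 0-3; endorsement prevalences follow the package's
    reference cohort targets (:data:`TABLE_PREVALENCES`); the latent
    correlation has a jittered two-community block structure (stronger
    within depression and within anxiety than across).
    """
    rng = np.random.default_rng(None if seed is None else seed + 1_000_003)
    items = list(TABLE_PREVALENCES)
    return OrdinalPanelSpec(
        items=items,
        score_ranges={it: (0, 3) for it in items},
        prevalences=dict(TABLE_PREVALENCES),
        latent_corr=_two_block_latent_corr(9, 7, rng),
        item_scales={it: it[:3] for it in items},
        n=n,
        seed=seed,
    )


def generate_ordinal_panel(spec: OrdinalPanelSpec) -> SymptomPanel:
    """Draw an ordinal panel from a Gaussian copula.

    Latent scores Z ~ N(0, latent_corr) are cut into categories so that
    P(score > lo) equals the item's target prevalence and the endorsed
    mass decays geometrically across the upper categories (right-skewed
    marginals typical of screening questionnaires).
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.items)
    L = np.linalg.cholesky(spec.latent_corr)
    Z = rng.standard_normal((spec.n, k)) @ L.T

    scores = np.empty((spec.n, k), dtype=int)
    for j, item in enumerate(spec.items):
        lo, hi = spec.score_ranges[item]
        n_cat = hi - lo + 1
        pi = spec.prevalences[item]
        upper = spec.decay ** np.arange(n_cat - 1)
        cat_probs = np.concatenate([[1 - pi], pi * upper / upper.sum()])
        cuts = ndtri(np.cumsum(cat_probs)[:-1])
        scores[:, j] = lo + np.searchsorted(cuts, Z[:, j], side="left")

    return SymptomPanel(
        scores=pd.DataFrame(scores, columns=spec.items),
        item_scales=dict(spec.item_scales),
        score_ranges=dict(spec.score_ranges),
    )


def generate_response_times(
    n: int,
    fast_fraction: float = 0.0,
    slow_fraction: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Mean seconds-per-item vector with planted careless/slow responders.

    Exactly ``round(fast_fraction * n)`` entries fall below 2 seconds
    (insufficient-effort responders) and ``round(slow_fraction * n)``
    entries lie far in the upper tail (60-120 s), well above any
    Tukey-fence cutoff computed from the moderate bulk (2.5-9.5 s).
    Positions are shuffled; deterministic given ``seed``.
    """
    if fast_fraction < 0 or slow_fraction < 0 or fast_fraction + slow_fraction >= 1:
        raise ValueError("fast_fraction + slow_fraction must be < 1 and nonnegative")
    rng = np.random.default_rng(seed)
    n_fast = int(round(fast_fraction * n))
    n_slow = int(round(slow_fraction * n))
    n_mod = n - n_fast - n_slow
    times = np.concatenate([
        rng.uniform(0.5, 1.9, size=n_fast),
        rng.uniform(60.0, 120.0, size=n_slow),
        rng.uniform(2.5, 9.5, size=n_mod),
    ])
    rng.shuffle(times)
    return times
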