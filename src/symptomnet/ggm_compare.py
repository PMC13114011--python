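"""Continuous-score partial-correlation networks and Mantel comparison.

To check that the present/absent binarization does not distort the
network, a Gaussian graphical model is fitted to the original ordinal
item scores via the graphical lasso over a regularization path with EBIC
selection, and the resulting partial-correlation matrix is compared with
the binary-data Ising weight matrix by a permutation Mantel test: the
Pearson correlation of the lower-triangle entries under simultaneous
random node relabelings of one matrix.  A high correlation indicates that
the binary and continuous networks share their structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

from .models import SymptomPanel

__all__ = ["GgmModel", "MantelResult", "estimate_ggm", "mantel_test"]

log = logging.getLogger(__name__)

GGM_GAMMA = 0.5
N_ALPHA = 50
ALPHA_MIN_RATIO = 0.01


@dataclass
class GgmModel:
    """EBIC-selected partial correlation network."""

    nodes: list[str]
    partials: np.ndarray  # symmetric, zero diagonal
    alpha: float
    gamma: float
    meta: dict

    def __post_init__(self) -> None:
        self.partials = np.asarray(self.partials, dtype=float)
        if not np.allclose(self.partials, self.partials.T, atol=1e-10):
            raise ValueError("partial correlation matrix must be symmetric")
        if np.any(np.abs(self.partials) > 1 + 1e-8):
            raise ValueError("partial correlations must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "type": "ggm",
            "nodes": self.nodes,
            "partials": self.partials.ravel().tolist(),
            "alpha": self.alpha,
            "gamma": self.gamma,
            "meta": self.meta,
        }


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n_perm": self.n_perm, "seed": self.seed}


def _ggm_ebic(precision: np.ndarray, S: np.ndarray, n: int, gamma: float) -> float:
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return np.inf
    ll = 0.5 * n * (logdet - np.trace(S @ precision))
    iu = np.triu_indices(p, k=1)
    E = int(np.count_nonzero(np.abs(precision[iu]) > 1e-8))
    return -2.0 * ll + E * np.log(n) + 4.0 * gamma * E * np.log(p)


def estimate_ggm(
    panel: SymptomPanel | pd.DataFrame,
    gamma: float = GGM_GAMMA,
    n_alpha: int = N_ALPHA,
    items: list[str] | None = None,
) -> GgmModel:
    """Graphical-lasso path on the item Pearson correlation matrix.

    The regularization grid descends log-spaced from the largest absolute
    off-diagonal correlation; the fit minimizing the extended BIC (edge
    penalty weight ``gamma``, default 0.5) is converted to partial
    correlations rho_ij = -kappa_ij / sqrt(kappa_ii kappa_jj) with a
    conventional zero diagonal.
    """
    if isinstance(panel, SymptomPanel):
        cols = items or [c for c in panel.items if panel.item_scales[c] in ("PHQ", "GAD")]
        df = panel.scores[cols]
    else:
        df = panel[items] if items else panel
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        log.warning("n=%d <= p=%d; GGM estimates may be unstable", n, p)
    S = np.corrcoef(X, rowvar=False)
    if np.isnan(S).any():
        raise ValueError("correlation matrix undefined (constant item?)")
    eigmin = np.linalg.eigvalsh(S)[0]
    if eigmin <= 1e-10:
        raise ValueError(
            "item correlation matrix is not positive-definite; consider adding a "
            "small ridge to its diagonal before estimation"
        )

    alpha_max = np.max(np.abs(S - np.diag(np.diag(S))))
    alphas = np.geomspace(alpha_max, alpha_max * ALPHA_MIN_RATIO, n_alpha)
    best = None
    n_failed = 0
    for alpha in alphas:
        try:
            _, precision = graphical_lasso(S, alpha=alpha, max_iter=500)
        except Exception as exc:
            n_failed += 1
            log.debug("graphical lasso failed at alpha=%.4g: %s", alpha, exc)
            continue
        ebic = _ggm_ebic(precision, S, n, gamma)
        if best is None or ebic < best[0]:
            best = (ebic, alpha, precision)
    if best is None:
        raise RuntimeError("graphical lasso failed at every regularization value")
    _, alpha_sel, K = best
    d = np.sqrt(np.diag(K))
    partials = -K / np.outer(d, d)
    np.fill_diagonal(partials, 0.0)
    partials[np.abs(partials) < 1e-10] = 0.0
    partials = (partials + partials.T) / 2.0
    return GgmModel(
        nodes=list(df.columns),
        partials=partials,
        alpha=float(alpha_sel),
        gamma=gamma,
        meta={"n": n, "n_alpha": n_alpha, "n_failed_alphas": n_failed},
    )


def mantel_test(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Permutation Mantel test between two symmetric network matrices.

    The statistic is the Pearson correlation of the lower-triangle
    off-diagonal entries; the null distribution applies ``n_perm``
    simultaneous random row/column permutations to ``B``.  Two-sided
    p-value with the add-one correction, so p is always positive and at
    least 1/(n_perm + 1).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A and B must be square matrices of the same size")
    if not (np.allclose(A, A.T, atol=1e-10) and np.allclose(B, B.T, atol=1e-10)):
        raise ValueError("A and B must be symmetric")
    p = A.shape[0]
    il = np.tril_indices(p, k=-1)
    a, b = A[il], B[il]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant off-diagonal entries; Mantel r undefined")
    r_obs = float(np.corrcoef(a, b)[0, 1])

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(p)
        bp = B[np.ix_(perm, perm)][il]
        r_perm = np.corrcoef(a, bp)[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    pval = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p=float(pval), n_perm=n_perm, seed=seed)
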