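"""Shared fixtures: small analytically tractable models and panels."""

import numpy as np
import pytest

from symptomnet.models import IsingModel
from symptomnet.synthetic_data import default_panel_spec, generate_ordinal_panel


@pytest.fixture(scope="session")
def toy_pair() -> IsingModel:
    """Two coupled nodes, zero thresholds, omega_12 = 1.

    Hand enumeration of the four states gives P(1,1) = e/(3+e) and an
    expected sum score of (2+2e)/(3+e).
    """
    return IsingModel(
        nodes=["a", "b"],
        omega=np.array([[0.0, 1.0], [1.0, 0.0]]),
        tau=np.zeros(2),
    )


@pytest.fixture(scope="session")
def hub_model() -> IsingModel:
    """Eight nodes with one strong hub and spread-out thresholds.

    The hub (S1) couples to every other node at 0.6; the others form a
    weak chain.  By exact enumeration the hub is the alleviation target
    with the largest drop in expected sum score, well separated from the
    runner-up, which makes sampled rankings checkable.
    """
    p = 8
    omega = np.zeros((p, p))
    for j in range(1, p):
        omega[0, j] = omega[j, 0] = 0.6
    for j in range(1, p - 1):
        omega[j, j + 1] = omega[j + 1, j] = 0.25
    tau = np.array([-1.0, -1.8, -2.2, -1.4, -2.6, -1.6, -2.0, -2.4])
    return IsingModel(nodes=[f"S{i+1}" for i in range(p)], omega=omega, tau=tau)


@pytest.fixture(scope="session")
def small_panel():
    """Calibrated 16-item ordinal panel, 400 participants."""
    return generate_ordinal_panel(default_panel_spec(n=400, seed=2))


def batch_se(x: np.ndarray, n_batches: int = 30) -> float:
    """Batch-means Monte-Carlo standard error for an autocorrelated chain."""
    n = len(x) // n_batches * n_batches
    means = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
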