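"""Generators and sampling oracles: exact enumeration is the ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symptomnet.models import IsingModel
from symptomnet.synthetic_data import (
    TABLE_PREVALENCES,
    default_panel_spec,
    enumerate_distribution,
    exact_expected_sum,
    exact_marginals,
    generate_ordinal_panel,
    generate_response_times,
    make_ground_truth,
    sample_ising,
)

from conftest import batch_se


class TestMakeGroundTruth:
    def test_default_block_edge_counts(self):
        """Default densities yield the 33/20/34 within/within/between split."""
        m = make_ground_truth(seed=0)
        assert m.p == 16
        wd = np.count_nonzero(m.omega[:9, :9][np.triu_indices(9, 1)])
        wa = np.count_nonzero(m.omega[9:, 9:][np.triu_indices(7, 1)])
        bt = np.count_nonzero(m.omega[:9, 9:])
        assert (wd, wa, bt) == (33, 20, 34)
        assert m.n_edges == 87

    def test_zero_density_gives_empty_graph(self):
        m = make_ground_truth(edge_density=0.0, seed=1)
        assert m.p == 16
        assert m.n_edges == 0
        assert set(m.communities.values()) == {"depression", "anxiety"}

    def test_deterministic_and_seed_sensitive(self):
        a = make_ground_truth(seed=11)
        b = make_ground_truth(seed=11)
        c = make_ground_truth(seed=12)
        assert np.array_equal(a.omega, b.omega) and np.array_equal(a.tau, b.tau)
        assert not np.array_equal(a.omega, c.omega)
        assert a.n_edges == c.n_edges  # sparsity honored exactly either way

    def test_all_positive_weights_all_negative_taus(self):
        m = make_ground_truth(seed=3)
        iu = np.triu_indices(16, 1)
        nz = m.omega[iu][m.omega[iu] != 0]
        assert np.all(nz > 0)
        assert np.all(m.tau < 0)

    @pytest.mark.parametrize(
        "kwargs", [{"weight_range": (-0.2, 0.3)}, {"tau_range": (-1.0, 0.5)},
                   {"edge_density": 1.5}],
    )
    def test_invalid_ranges_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_ground_truth(**kwargs, seed=0)


class TestEnumeration:
    def test_single_free_node_is_a_fair_coin(self):
        m = IsingModel(nodes=["x"], omega=np.zeros((1, 1)), tau=np.zeros(1))
        dist = enumerate_distribution(m)
        assert dist["prob"].to_numpy() == pytest.approx([0.5, 0.5])

    def test_coupled_pair_hand_enumeration(self, toy_pair):
        dist = enumerate_distribution(toy_pair)
        p11 = dist.loc[(dist["a"] == 1) & (dist["b"] == 1), "prob"].item()
        assert p11 == pytest.approx(np.e / (3 + np.e), abs=1e-12)
        assert exact_expected_sum(toy_pair) == pytest.approx(
            (2 + 2 * np.e) / (3 + np.e), abs=1e-12
        )

    def test_deep_negative_thresholds_suppress_activation(self):
        m = IsingModel(
            nodes=["x", "y"], omega=np.zeros((2, 2)), tau=np.array([-10.0, -10.0])
        )
        dist = enumerate_distribution(m)
        p00 = dist.loc[(dist["x"] == 0) & (dist["y"] == 0), "prob"].item()
        assert p00 == pytest.approx(1.0, abs=1e-4)

    def test_probabilities_sum_to_one(self):
        for seed in range(3):
            m = make_ground_truth(n_dep=4, n_anx=3, edge_density=0.5, seed=seed)
            assert enumerate_distribution(m)["prob"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_refuses_large_state_space(self):
        m = make_ground_truth(n_dep=12, n_anx=9, seed=0)
        with pytest.raises(ValueError, match="metropolis"):
            enumerate_distribution(m)

    @given(st.integers(0, 6), st.floats(0.1, 1.5))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_raising_any_threshold_raises_expected_sum(self, node, bump):
        """In an attractive model, making any symptom more activation-prone
        never lowers the exact expected sum score."""
        m = make_ground_truth(n_dep=4, n_anx=3, edge_density=0.5, seed=42)
        tau2 = m.tau.copy()
        tau2[node] += bump
        m2 = IsingModel(nodes=m.nodes, omega=m.omega, tau=tau2)
        assert exact_expected_sum(m2) >= exact_expected_sum(m) - 1e-12


class TestSampling:
    def test_independent_fair_coins(self):
        m = IsingModel(nodes=list("abcd"), omega=np.zeros((4, 4)), tau=np.zeros(4))
        X = sample_ising(m, 10_000, method="metropolis", seed=0)
        assert X.values.shape == (10_000, 4)
        assert np.all((X.values.mean(axis=0) > 0.47) & (X.values.mean(axis=0) < 0.53))

    def test_exact_sampler_matches_enumeration(self):
        """Chi-square goodness of fit over all 16 states, alpha = 0.01."""
        from scipy import stats

        m = make_ground_truth(n_dep=2, n_anx=2, edge_density=0.6, seed=8)
        dist = enumerate_distribution(m)
        X = sample_ising(m, 100_000, method="exact", seed=4)
        code = X.values @ (2 ** np.arange(4))
        observed = np.bincount(code, minlength=16)
        expected = dist["prob"].to_numpy() * 100_000
        chi2 = np.sum((observed - expected) ** 2 / expected)
        assert stats.chi2.sf(chi2, df=15) > 0.01

    def test_metropolis_matches_enumeration_on_pair(self, toy_pair):
        X = sample_ising(toy_pair, 50_000, method="metropolis", seed=13)
        joint = ((X.data["a"] == 1) & (X.data["b"] == 1)).to_numpy().astype(float)
        se = batch_se(joint)
        assert abs(joint.mean() - np.e / (3 + np.e)) < 3 * se

    def test_reproducible_and_correct_shape(self):
        m = make_ground_truth(seed=2)
        X1 = sample_ising(m, 5000, seed=123)
        X2 = sample_ising(m, 5000, seed=123)
        assert X1.values.shape == (5000, 16)
        assert np.array_equal(X1.values, X2.values)


class TestOrdinalPanel:
    def test_calibrated_prevalence(self):
        """Binarized column means sit within +-0.03 of their targets at the
        reference cohort size."""
        panel = generate_ordinal_panel(default_panel_spec(n=1638, seed=42))
        binary = (panel.scores > 0).mean()
        for item, target in TABLE_PREVALENCES.items():
            assert abs(binary[item] - target) < 0.03, item

    def test_shape_and_range(self):
        panel = generate_ordinal_panel(default_panel_spec(n=1638, seed=0))
        assert panel.scores.shape == (1638, 16)
        assert panel.scores.to_numpy().min() >= 0
        assert panel.scores.to_numpy().max() <= 3

    def test_identity_copula_gives_uncorrelated_items(self):
        spec = default_panel_spec(n=4000, seed=5)
        spec.latent_corr = np.eye(16)
        spec.prevalences = {it: 0.5 for it in spec.items}
        panel = generate_ordinal_panel(spec)
        corr = panel.scores.corr().to_numpy()
        off = corr[np.triu_indices(16, 1)]
        assert np.max(np.abs(off)) < 0.06  # ~3.8 sigma at n=4000

    def test_non_positive_definite_rejected(self):
        spec = default_panel_spec(n=100, seed=1)
        bad = np.ones((16, 16))
        spec_dict = spec.__dict__ | {"latent_corr": bad}
        from symptomnet.synthetic_data import OrdinalPanelSpec

        with pytest.raises(ValueError, match="positive-definite"):
            OrdinalPanelSpec(**{k: spec_dict[k] for k in (
                "items", "score_ranges", "prevalences", "latent_corr",
                "item_scales", "n", "seed", "decay")})


class TestResponseTimes:
    def test_planted_counts(self):
        t = generate_response_times(100, fast_fraction=0.1, slow_fraction=0.05, seed=0)
        assert len(t) == 100
        assert int(np.sum(t < 2)) == 10
        assert int(np.sum(t > 50)) == 5

    def test_no_slow_outliers_when_disabled(self):
        t = generate_response_times(500, fast_fraction=0.1, slow_fraction=0.0, seed=1)
        assert np.sum(t > 50) == 0

    def test_reproducible(self):
        a = generate_response_times(50, 0.1, 0.1, seed=7)
        b = generate_response_times(50, 0.1, 0.1, seed=7)
        assert np.array_equal(a, b)
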