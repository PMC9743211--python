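"""MSM and TICA estimation against analytic and counting oracles."""

import numpy as np
import pytest

from tcbackmap.msm import (
    TICA,
    MarkovStateModel,
    assign_states,
    cosine_similarity_on_support,
    eigenvector_similarity,
    implied_timescales,
    kmeans_discretize,
    msm_estimate,
    normalize_timescales,
    tica_fit,
)


def sample_chain(T, n_steps, rng, start=0):
    """Direct Markov-chain sampling (the counting oracle's data source)."""
    cum = np.cumsum(T, axis=1)
    states = np.empty(n_steps, dtype=np.int64)
    s = start
    u = rng.random(n_steps)
    for t in range(n_steps):
        s = int(np.searchsorted(cum[s], u[t]))
        states[t] = s
    return states


class TestKMeans:
    def test_single_centroid_is_data_mean(self, rng):
        x = rng.normal(size=(100, 2))
        centroids, labels = kmeans_discretize(x, 1, rng)
        assert np.allclose(centroids[0], x.mean(axis=0))
        assert np.all(labels == 0)

    def test_planted_clusters_recovered(self, rng):
        a = rng.normal(size=(50, 2))
        b = rng.normal(size=(50, 2)) + 20.0
        x = np.vstack([a, b])
        centroids, labels = kmeans_discretize(x, 2, rng)
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
        assert labels[0] != labels[-1]

    def test_frozen_centroids_reused_for_assignment(self, rng):
        x = rng.normal(size=(60, 2))
        centroids, labels = kmeans_discretize(x, 4, rng)
        assert np.array_equal(assign_states(x, centroids), labels)

    def test_reproducible_under_seed(self, rng):
        x = np.random.default_rng(0).normal(size=(80, 3))
        c1, _ = kmeans_discretize(x, 3, np.random.default_rng(5))
        c2, _ = kmeans_discretize(x, 3, np.random.default_rng(5))
        assert np.array_equal(c1, c2)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_discretize(np.zeros((3, 1)), 5, rng)


class TestMSM:
    def test_stochastic_matrix_contract(self, rng):
        dtraj = sample_chain(np.array([[0.8, 0.2], [0.3, 0.7]]), 5000, rng)
        m = msm_estimate(dtraj, lag=1)
        T = m.transition_matrix
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(T >= 0)
        assert m.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)

    def test_two_state_estimation_recovers_truth(self):
        T_true = np.array([[0.95, 0.05], [0.10, 0.90]])
        rng = np.random.default_rng(11)
        dtraj = sample_chain(T_true, 10**6, rng)
        m = msm_estimate(dtraj, lag=1)
        assert np.abs(m.transition_matrix - T_true).max() < 0.01

    def test_constant_sequence_yields_single_state_model(self):
        m = msm_estimate(np.zeros(100, dtype=int), lag=1)
        assert m.transition_matrix.shape == (1, 1)
        assert m.state_ids.tolist() == [0]

    def test_no_transitions_at_lag_rejected(self):
        with pytest.raises(ValueError):
            msm_estimate(np.array([0, 1]), lag=10)

    def test_disconnected_state_dropped(self):
        # state 2 appears once at the end and never transitions back
        dtraj = np.array([0, 1, 0, 1, 0, 1, 0, 2])
        m = msm_estimate(dtraj, lag=1)
        assert set(m.state_ids.tolist()) == {0, 1}

    def test_estimator_wrapper_exposes_fitted_attributes(self, rng):
        dtraj = sample_chain(np.array([[0.9, 0.1], [0.2, 0.8]]), 20000, rng)
        est = MarkovStateModel(lag=1).fit(dtraj)
        assert est.transition_matrix_.shape == (2, 2)
        assert len(est.timescales_) == 1


class TestImpliedTimescales:
    def test_analytic_two_state_timescale(self):
        m = msm_estimate_from_matrix(np.array([[0.9, 0.1], [0.2, 0.8]]))
        ts = implied_timescales(m)
        assert len(ts) == 1
        assert ts[0] == pytest.approx(-1.0 / np.log(0.7), rel=1e-12)

    def test_stationary_eigenvalue_excluded(self):
        m = msm_estimate_from_matrix(np.array([[0.9, 0.1], [0.2, 0.8]]))
        ts = implied_timescales(m)
        assert np.all(np.isfinite(ts))  # the lambda=1 mode would be infinite

    def test_linear_in_lag_for_fixed_eigenvalues(self):
        m1 = msm_estimate_from_matrix(np.array([[0.9, 0.1], [0.2, 0.8]]), lag_time=1.0)
        m5 = msm_estimate_from_matrix(np.array([[0.9, 0.1], [0.2, 0.8]]), lag_time=5.0)
        assert implied_timescales(m5)[0] == pytest.approx(5 * implied_timescales(m1)[0])


def msm_estimate_from_matrix(T, lag_time=None):
    """Build a TransitionModel directly from a known transition matrix."""
    from tcbackmap.msm import TransitionModel

    return TransitionModel(
        transition_matrix=T,
        lag=1,
        state_ids=np.arange(len(T)),
        counts=T * 1000,
        lag_time=lag_time,
    )


class TestNormalizeTimescales:
    def test_slowest_processes_matched(self):
        rescaled, factor = normalize_timescales([20.0, 4.0], [100.0, 30.0])
        assert factor == 5.0
        assert rescaled[0] == 100.0

    def test_self_normalization_is_identity(self):
        rescaled, factor = normalize_timescales([7.0, 2.0], [7.0, 2.0])
        assert factor == 1.0
        assert np.allclose(rescaled, [7.0, 2.0])

    def test_pairwise_ratios_preserved(self):
        target = np.array([40.0, 10.0, 2.0])
        rescaled, _ = normalize_timescales(target, [333.0])
        assert np.allclose(rescaled / rescaled[0], target / target[0])


class TestEigenvectorSimilarity:
    def test_identical_models_give_unit_similarity(self, rng):
        dtraj = sample_chain(np.array([[0.9, 0.1], [0.2, 0.8]]), 20000, rng)
        m = msm_estimate(dtraj, lag=1)
        assert np.allclose(eigenvector_similarity(m, m), 1.0)

    def test_hand_computed_restricted_cosine(self):
        assert cosine_similarity_on_support([2.0, 2.0], [1.0, 0.0]) == pytest.approx(
            2.0 / np.sqrt(8.0)
        )

    def test_orthogonal_vectors_give_zero(self):
        assert cosine_similarity_on_support([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_sign_flip_invariance(self, rng):
        v = rng.normal(size=6)
        w = rng.normal(size=6)
        assert cosine_similarity_on_support(v, w) == pytest.approx(
            cosine_similarity_on_support(v, -w)
        )


class TestTica:
    def test_eigenvalues_bounded_by_one(self, rng):
        x = np.cumsum(rng.normal(size=(2000, 3)), axis=0) * 0.01 + rng.normal(size=(2000, 3))
        model = tica_fit(x, lag=5)
        assert np.all(model.eigenvalues <= 1.0 + 1e-10)
        assert np.all(model.eigenvalues >= -1.0 - 1e-10)

    def test_white_noise_has_no_autocorrelation(self, rng):
        x = np.random.default_rng(2).normal(size=(20000, 4))
        model = tica_fit(x, lag=3)
        assert np.abs(model.eigenvalues).max() < 0.05

    def test_slow_direction_recovered_for_linear_process(self):
        # two independent AR(1) processes with very different memory,
        # mixed by a known rotation; the slow direction is analytic
        rng = np.random.default_rng(4)
        n = 200000
        a_slow, a_fast = 0.99, 0.2
        slow = np.empty(n)
        fast = np.empty(n)
        s = f = 0.0
        es = rng.normal(size=n)
        ef = rng.normal(size=n)
        for t in range(n):
            s = a_slow * s + np.sqrt(1 - a_slow**2) * es[t]
            f = a_fast * f + np.sqrt(1 - a_fast**2) * ef[t]
            slow[t] = s
            fast[t] = f
        theta = np.deg2rad(30.0)
        mix = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        X = np.stack([slow, fast], axis=1) @ mix.T
        model = tica_fit(X, lag=10)
        lead = model.components[:, 0]
        # the leading IC must align with the slow direction: rows of mix^-T
        slow_dir = np.linalg.inv(mix).T[:, 0]
        cos = abs(lead @ slow_dir) / (np.linalg.norm(lead) * np.linalg.norm(slow_dir))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 5.0

    def test_constant_column_rejected_with_column_index(self, rng):
        x = rng.normal(size=(100, 3))
        x[:, 1] = 4.2
        with pytest.raises(ValueError, match="1"):
            tica_fit(x, lag=2)

    def test_transformer_wrapper_roundtrip(self, rng):
        x = np.cumsum(rng.normal(size=(5000, 4)), axis=0) * 0.05 + rng.normal(size=(5000, 4))
        est = TICA(lag=5, n_components=2).fit(x)
        y = est.transform(x)
        assert y.shape == (5000, 2)
        assert np.allclose(y.mean(axis=0), 0.0, atol=1e-8)
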