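"""Core learner tests: RFF sampling and mapping, incremental ridge vs the
closed-form batch solution, kernel ridge against an independent oracle,
and model persistence."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.kernel_ridge import KernelRidge as SkKernelRidge
from sklearn.linear_model import Ridge as SkRidge

from irffrr.learners import (
    IncrementalRidge,
    IncrementalUnsupportedError,
    KRRLearner,
    RFFMap,
    RFFRidgeLearner,
    RidgeConfig,
    fit_batch_linear,
    fit_krr,
    init_incremental,
    load_model,
    make_learner,
    rbf_kernel,
    sample_rff,
    save_model,
)

# ---------------------------------------------------------------------------
# Random Fourier features
# ---------------------------------------------------------------------------


class TestRFFMap:
    def test_shapes_and_phase_range(self):
        m = sample_rff(3, 1000, 0.5, seed=7)
        assert m.frequencies.shape == (1000, 3)
        assert m.phases.shape == (1000,)
        assert np.all((m.phases >= 0) & (m.phases < 2 * np.pi))

    def test_deterministic_given_seed(self):
        a = sample_rff(3, 1000, 0.5, seed=7)
        b = sample_rff(3, 1000, 0.5, seed=7)
        assert np.array_equal(a.frequencies, b.frequencies)
        assert np.array_equal(a.phases, b.phases)
        c = sample_rff(3, 1000, 0.5, seed=8)
        assert not np.array_equal(a.frequencies, c.frequencies)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_inputs=0), dict(n_features=0), dict(bandwidth=0.0),
         dict(bandwidth=-1.0)],
    )
    def test_invalid_arguments(self, kwargs):
        full = dict(n_inputs=3, n_features=10, bandwidth=1.0, seed=0)
        full.update(kwargs)
        with pytest.raises(ValueError):
            sample_rff(**full)

    def test_frequency_variance_matches_sampling_distribution(self):
        # entries ~ Normal(0, 2*gamma): sample variance of D=1e5 draws must
        # sit within 3 standard errors of 2.0 (SE = sqrt(2/(D-1)) * 2)
        D = 100_000
        m = sample_rff(1, D, 1.0, seed=42)
        v = m.frequencies.var(ddof=1)
        se = np.sqrt(2.0 / (D - 1)) * 2.0
        assert abs(v - 2.0) < 3 * se

    def test_zero_frequencies_quarter_phase_maps_to_zero(self):
        m = RFFMap(
            n_inputs=2, n_features=5, bandwidth=1.0,
            frequencies=np.zeros((5, 2)), phases=np.full(5, np.pi / 2), seed=0,
        )
        z = m.transform(np.array([3.0, -1.0]))
        assert np.allclose(z, 0.0, atol=1e-15)

    def test_component_magnitude_bound(self):
        m = sample_rff(4, 64, 2.0, seed=1)
        rng = np.random.default_rng(0)
        Z = m.transform(rng.normal(size=(100, 4)))
        assert np.all(np.abs(Z) <= np.sqrt(2.0 / 64) + 1e-12)

    def test_dimension_mismatch_rejected(self):
        m = sample_rff(3, 8, 1.0, seed=0)
        with pytest.raises(ValueError):
            m.transform(np.ones(4))

    def test_inner_products_approximate_rbf_kernel(self):
        # mean over 25 maps of z(x).z(y) near exp(-gamma*||x-y||^2) = e^-1
        rng = np.random.default_rng(3)
        x = rng.normal(size=3)
        d = rng.normal(size=3)
        y = x + d / np.linalg.norm(d)  # ||x - y||^2 = 1
        vals = [
            sample_rff(3, 50_000, 1.0, seed=s).transform(x)
            @ sample_rff(3, 50_000, 1.0, seed=s).transform(y)
            for s in range(25)
        ]
        target = np.exp(-1.0)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - target) < 3 * se


# ---------------------------------------------------------------------------
# Incremental ridge
# ---------------------------------------------------------------------------


class TestIncrementalRidge:
    def test_initial_state(self):
        s = init_incremental(RidgeConfig(regularizer=1.0, n_outputs=2), 4)
        assert np.array_equal(s.inv_cov, np.eye(4))
        assert np.array_equal(s.accumulator, np.zeros((4, 2)))
        assert s.n_updates == 0
        s4 = init_incremental(RidgeConfig(regularizer=4.0), 2)
        assert np.array_equal(s4.inv_cov, 0.25 * np.eye(2))

    def test_fresh_state_predicts_zero(self):
        s = init_incremental(RidgeConfig(regularizer=2.0, n_outputs=3), 5)
        assert np.array_equal(s.predict(np.ones(5)), np.zeros(3))

    def test_single_sample_closed_form(self):
        # one sample (z=1, y=1), lambda=1: w = z*y/(lambda + z^2) = 0.5
        s = init_incremental(RidgeConfig(regularizer=1.0), 1)
        s.update([1.0], [1.0])
        assert np.allclose(s.weights, 0.5)
        assert np.allclose(s.predict([1.0]), 0.5)

    @pytest.mark.parametrize("lam", [0.1, 1.0, 10.0])
    def test_matches_batch_solution_any_order(self, lam):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(20, 10))
        Y = rng.normal(size=(20, 3))
        s = init_incremental(RidgeConfig(regularizer=lam, n_outputs=3), 10)
        for z, y in zip(Z, Y):
            s.update(z, y)
        w_batch = fit_batch_linear(Z, Y, lam)
        assert np.allclose(s.weights, w_batch, rtol=1e-8, atol=1e-12)
        # permuting the stream leaves the final solution unchanged
        perm = rng.permutation(20)
        s2 = init_incremental(RidgeConfig(regularizer=lam, n_outputs=3), 10)
        for z, y in zip(Z[perm], Y[perm]):
            s2.update(z, y)
        assert np.allclose(s2.weights, s.weights, rtol=1e-8, atol=1e-12)

    def test_block_update_equals_sequential(self):
        rng = np.random.default_rng(8)
        Z = rng.normal(size=(37, 6))
        Y = rng.normal(size=(37, 2))
        seq = init_incremental(RidgeConfig(regularizer=0.7, n_outputs=2), 6)
        for z, y in zip(Z, Y):
            seq.update(z, y)
        blk = init_incremental(RidgeConfig(regularizer=0.7, n_outputs=2), 6)
        blk.update_many(Z[:20], Y[:20])
        blk.update_many(Z[20:], Y[20:])
        assert blk.n_updates == seq.n_updates == 37
        assert np.allclose(blk.inv_cov, seq.inv_cov, rtol=1e-8, atol=1e-12)
        assert np.allclose(blk.weights, seq.weights, rtol=1e-8, atol=1e-12)

    def test_lazy_and_literal_weight_modes_agree(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(15, 4))
        Y = rng.normal(size=(15, 2))
        lit = init_incremental(RidgeConfig(1.0, 2), 4, weight_mode="literal")
        lazy = init_incremental(RidgeConfig(1.0, 2), 4, weight_mode="lazy")
        for z, y in zip(Z, Y):
            lit.update(z, y)
            lazy.update(z, y)
        assert np.allclose(lit.weights, lazy.weights, rtol=1e-12)

    def test_joint_outputs_equal_independent_learners(self):
        # a p=5 learner equals five single-output learners on the same stream
        rng = np.random.default_rng(11)
        Z = rng.normal(size=(30, 8))
        Y = rng.normal(size=(30, 5))
        joint = init_incremental(RidgeConfig(regularizer=0.3, n_outputs=5), 8)
        singles = [
            init_incremental(RidgeConfig(regularizer=0.3, n_outputs=1), 8)
            for _ in range(5)
        ]
        for z, y in zip(Z, Y):
            joint.update(z, y)
            for d in range(5):
                singles[d].update(z, y[d : d + 1])
        q = rng.normal(size=8)
        joint_pred = joint.predict(q)
        for d in range(5):
            assert abs(joint_pred[d] - singles[d].predict(q)[0]) < 1e-10

    def test_inv_cov_stays_symmetric_over_long_streams(self):
        rng = np.random.default_rng(13)
        s = init_incremental(RidgeConfig(1.0, 1), 30, weight_mode="lazy")
        for _ in range(10_000):
            s.update(rng.normal(size=30), rng.normal(size=1))
        assert np.max(np.abs(s.inv_cov - s.inv_cov.T)) < 1e-8

    def test_constant_memory_footprint(self):
        # allocations depend only on (D, p), never on the update count
        rng = np.random.default_rng(4)
        s = init_incremental(RidgeConfig(1.0, 2), 12)

        def footprint(st):
            return (
                st.inv_cov.nbytes + st.accumulator.nbytes + st.weights.nbytes,
                st.inv_cov.shape, st.accumulator.shape,
            )

        for _ in range(50):
            s.update(rng.normal(size=12), rng.normal(size=2))
        before = footprint(s)
        for _ in range(450):
            s.update(rng.normal(size=12), rng.normal(size=2))
        assert footprint(s) == before

    def test_rejects_bad_input(self):
        s = init_incremental(RidgeConfig(1.0, 1), 3)
        with pytest.raises(ValueError):
            s.update([1.0, np.nan, 0.0], [1.0])
        with pytest.raises(ValueError):
            s.update([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            s.predict(np.ones(4))
        with pytest.raises(ValueError):
            RidgeConfig(regularizer=0.0)


# ---------------------------------------------------------------------------
# Batch baselines
# ---------------------------------------------------------------------------


class TestBatchBaselines:
    def test_linear_hand_example(self):
        w = fit_batch_linear(np.array([[1.0]]), np.array([[1.0]]), 1.0)
        assert np.allclose(w, [[0.5]])

    def test_strong_regularization_shrinks_weights(self):
        rng = np.random.default_rng(0)
        X, Y = rng.normal(size=(40, 5)), rng.normal(size=(40, 2))
        w = fit_batch_linear(X, Y, 1e12)
        assert np.linalg.norm(w) < 1e-9

    def test_linear_matches_sklearn_oracle(self):
        rng = np.random.default_rng(1)
        X, Y = rng.normal(size=(30, 5)), rng.normal(size=(30, 2))
        ours = fit_batch_linear(X, Y, 2.5)
        ref = SkRidge(alpha=2.5, fit_intercept=False).fit(X, Y).coef_.T
        assert np.allclose(ours, ref, rtol=1e-10, atol=1e-12)

    def test_rejects_nonpositive_regularizer(self):
        with pytest.raises(ValueError):
            fit_batch_linear(np.eye(2), np.ones((2, 1)), 0.0)

    def test_rbf_kernel_values(self):
        x = np.array([[0.3, -1.2, 0.7]])
        assert np.allclose(rbf_kernel(x, x, 3.0), 1.0)
        y = x + np.array([[1.0, 0.0, 0.0]])  # squared distance 1
        assert np.allclose(rbf_kernel(x, y, 1.0), np.exp(-1.0))

    def test_krr_matches_sklearn_oracle(self):
        rng = np.random.default_rng(2)
        X, Y = rng.normal(size=(25, 4)), rng.normal(size=(25, 3))
        Xq = rng.normal(size=(10, 4))
        ours = fit_krr(X, Y, regularizer=0.5, bandwidth=1.3).predict(Xq)
        ref = (
            SkKernelRidge(alpha=0.5, kernel="rbf", gamma=1.3)
            .fit(X, Y)
            .predict(Xq)
        )
        assert np.allclose(ours, ref, rtol=1e-8, atol=1e-10)

    def test_krr_rejects_bad_hyperparameters(self):
        X, Y = np.eye(2), np.ones((2, 1))
        with pytest.raises(ValueError):
            fit_krr(X, Y, regularizer=-1.0, bandwidth=1.0)
        with pytest.raises(ValueError):
            fit_krr(X, Y, regularizer=1.0, bandwidth=0.0)

    def test_rff_gap_to_krr_shrinks_with_dimension(self):
        # median |prediction gap| over seeds is non-increasing as D doubles
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, size=(150, 3))
        Y = np.sin(2 * X[:, :1]) + 0.5 * np.cos(X[:, 1:2] * X[:, 2:3])
        Xq = rng.uniform(-1, 1, size=(60, 3))
        krr = fit_krr(X, Y, 0.1, 1.0).predict(Xq)
        med = []
        for D in (50, 100, 250, 500, 1000, 2000):
            gaps = []
            for seed in range(25):
                m = sample_rff(3, D, 1.0, seed=seed)
                w = fit_batch_linear(m.transform(X), Y, 0.1)
                gaps.append(np.mean((m.transform(Xq) @ w - krr) ** 2))
            med.append(np.median(gaps))
        assert all(a >= b - 1e-12 for a, b in zip(med, med[1:]))


# ---------------------------------------------------------------------------
# Adapters and persistence
# ---------------------------------------------------------------------------


class TestAdaptersAndPersistence:
    def test_krr_adapter_refuses_updates(self):
        learner = make_learner("krr", 3, 2, regularizer=1.0, bandwidth=1.0)
        with pytest.raises(IncrementalUnsupportedError):
            learner.update(np.ones((2, 3)), np.ones((2, 2)))

    def test_unknown_learner_kind(self):
        with pytest.raises(ValueError, match="unknown learner"):
            make_learner("svm", 3, 2, regularizer=1.0)

    def test_rff_learner_roundtrip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(9)
        learner = RFFRidgeLearner(
            n_inputs=4, n_outputs=2, regularizer=0.8, bandwidth=1.7,
            n_features=64, seed=5,
        )
        learner.fit(rng.normal(size=(40, 4)), rng.normal(size=(40, 2)))
        path = tmp_path / "model.npz"
        save_model(path, learner)
        back = load_model(path)
        assert np.array_equal(back.map.frequencies, learner.map.frequencies)
        assert np.array_equal(back.map.phases, learner.map.phases)
        assert np.array_equal(back.state.inv_cov, learner.state.inv_cov)
        assert np.array_equal(back.state.weights, learner.state.weights)
        assert back.state.n_updates == learner.state.n_updates
        q = rng.normal(size=(7, 4))
        assert np.array_equal(back.predict(q), learner.predict(q))

    def test_version_mismatch_rejected(self, tmp_path):
        learner = RFFRidgeLearner(2, 1, regularizer=1.0, bandwidth=1.0,
                                  n_features=8, seed=0)
        path = tmp_path / "model.npz"
        save_model(path, learner)
        import numpy as np_

        data = dict(np_.load(path))
        data["format_version"] = np_.int64(99)
        np_.savez(path, **data)
        with pytest.raises(ValueError, match="format version"):
            load_model(path)
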