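"""Gate construction, feature expansion, and the GG-FWC classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.svm import LinearSVC

from micov.ggfwc import GGFWC, GateSet, expand_features, fit_gates, kernel_activations


def double_sum_output(model, x):
    """Brute-force evaluation of the gated double sum
    o(x) = Σ_d Σ_r w_dr·k_r(x)·x_d with x_0 = 1, k_0 ≡ 1."""
    xs = (np.asarray(x) - model.mean_) / model.std_
    k = kernel_activations(xs, model.gates_)
    ka = np.concatenate([[1.0], k])
    xa = np.concatenate([[1.0], xs])
    D = len(xs)
    o = 0.0
    for r in range(len(ka)):
        for d in range(D + 1):
            o += model.weights_[r * (D + 1) + d] * ka[r] * xa[d]
    return o


class TestFitGates:
    def test_distinct_repeated_points_recovered(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        X = np.repeat(pts, 10, axis=0)
        gates = fit_gates(X, R=3, delta=1.0, seed=0)
        recovered = {tuple(np.round(c, 6)) for c in gates.centroids}
        assert recovered == {tuple(p) for p in pts}
        # zero within-cluster scatter -> global-dispersion fallback
        global_disp = np.mean(np.sum((X - X.mean(axis=0)) ** 2, axis=1))
        assert np.allclose(gates.dispersions, global_disp)

    def test_single_gate_is_grand_mean(self, rng):
        X = rng.standard_normal((50, 3))
        gates = fit_gates(X, R=1, delta=2.0, seed=0)
        assert np.allclose(gates.centroids[0], X.mean(axis=0), atol=1e-8)
        expected = np.mean(np.sum((X - X.mean(axis=0)) ** 2, axis=1))
        assert gates.dispersions[0] == pytest.approx(expected, rel=1e-8)

    def test_gaussian_blobs_recovered(self, rng):
        true = np.array([[-3.0, 0.0], [3.0, 0.0]])
        X = np.vstack(
            [t + 0.3 * rng.standard_normal((250, 2)) for t in true]
        )
        gates = fit_gates(X, R=2, delta=1.0, seed=1)
        found = gates.centroids[np.argsort(gates.centroids[:, 0])]
        assert np.abs(found - true).max() < 0.1

    def test_invalid_inputs(self, rng):
        X = rng.standard_normal((5, 2))
        with pytest.raises(ValueError):
            fit_gates(X, R=6, delta=1.0)
        with pytest.raises(ValueError):
            fit_gates(X, R=2, delta=0.0)


class TestKernelActivations:
    def test_unit_at_centroid(self, rng):
        gates = fit_gates(rng.standard_normal((30, 2)), R=3, delta=1.0, seed=0)
        k = kernel_activations(gates.centroids[1], gates)
        assert k[1] == pytest.approx(1.0)

    def test_hand_value(self):
        gates = GateSet(centroids=np.array([[0.0, 0.0]]), dispersions=np.array([1.0]),
                        delta=1.0)
        k = kernel_activations(np.array([np.sqrt(2.0), 0.0]), gates)
        assert k[0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_large_delta_limit(self, rng):
        X = rng.standard_normal((20, 2))
        gates = fit_gates(X, R=2, delta=1e12, seed=0)
        K = kernel_activations(X, gates)
        assert np.all(K > 0.999999)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=2))
    def test_bounded_and_monotone(self, point):
        gates = GateSet(centroids=np.array([[0.0, 0.0]]),
                        dispersions=np.array([2.0]), delta=3.0)
        x = np.array(point)
        k = kernel_activations(x, gates)[0]
        assert 0.0 < k <= 1.0
        k_further = kernel_activations(2.0 * x, gates)[0]
        assert k_further <= k

    def test_dimension_mismatch(self, rng):
        gates = fit_gates(rng.standard_normal((10, 3)), R=2, delta=1.0, seed=0)
        with pytest.raises(ValueError):
            kernel_activations(np.zeros(2), gates)


class TestExpandFeatures:
    def test_layout_small_case(self):
        gates = GateSet(centroids=np.array([[0.0, 0.0]]),
                        dispersions=np.array([1.0]), delta=1.0)
        x = np.array([2.0, -3.0])
        z = expand_features(x, gates)
        k1 = kernel_activations(x, gates)[0]
        assert z.shape == (6,)  # (R+1)(D+1) with R=1, D=2
        assert np.allclose(z, [1.0, 2.0, -3.0, k1, 2.0 * k1, -3.0 * k1])

    def test_linear_block_is_one_then_x(self, rng):
        X = rng.standard_normal((10, 4))
        gates = fit_gates(X, R=3, delta=1.0, seed=0)
        Z = expand_features(X, gates)
        assert Z.shape == (10, 4 * 5)
        assert np.allclose(Z[:, 0], 1.0)
        assert np.array_equal(Z[:, 1:5], X)

    def test_matches_brute_force_products(self, rng):
        X = rng.standard_normal((5, 3))
        gates = fit_gates(X, R=2, delta=2.0, seed=0)
        Z = expand_features(X, gates)
        K = kernel_activations(X, gates)
        for n in range(5):
            ka = np.concatenate([[1.0], K[n]])
            xa = np.concatenate([[1.0], X[n]])
            for r in range(3):
                for d in range(4):
                    assert Z[n, r * 4 + d] == pytest.approx(ka[r] * xa[d], abs=1e-12)


class TestGGFWCFit:
    def test_separable_data_fit_perfectly(self, rng):
        X = np.vstack([rng.standard_normal((40, 2)) + [4, 0],
                       rng.standard_normal((40, 2)) - [4, 0]])
        y = np.repeat([1, 2], 40)
        for R in (1, 3, 8):
            model = GGFWC(R=R, delta=5.0, margin_C=1.0, seed=0).fit(X, y)
            assert model.score(X, y) == 1.0

    def test_xor_needs_gates(self, xor_data):
        X, y = xor_data
        model = GGFWC(R=4, delta=1.0, margin_C=100.0, seed=0).fit(X, y)
        assert model.score(X, y) == 1.0
        best_linear = 0.0
        for C in (0.01, 1.0, 100.0):
            lin = LinearSVC(loss="hinge", C=C, max_iter=50000).fit(X, y)
            best_linear = max(best_linear, lin.score(X, y))
        assert best_linear <= 0.75

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((60, 3))
        y = np.where(X[:, 0] + 0.3 * rng.standard_normal(60) > 0, 1, 2)
        w1 = GGFWC(R=5, delta=2.0, seed=42).fit(X, y).weights_
        w2 = GGFWC(R=5, delta=2.0, seed=42).fit(X, y).weights_
        assert np.array_equal(w1, w2)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            GGFWC(R=2).fit(X, np.ones(10))

    def test_weight_count(self, rng):
        X = rng.standard_normal((50, 4))
        y = np.repeat([1, 2], 25)
        model = GGFWC(R=6, delta=3.0, seed=0).fit(X, y)
        assert model.weights_.shape == ((6 + 1) * (4 + 1),)


class TestDecisionFunction:
    def _fitted(self, rng, R=3, D=4, n=60):
        X = rng.standard_normal((n, D))
        y = np.where(X[:, 0] > 0, 1, 2)
        return GGFWC(R=R, delta=2.0, seed=0).fit(X, y), X

    def test_matches_double_sum(self, rng):
        model, X = self._fitted(rng)
        for x in X[:10]:
            assert model.decision_function(x) == pytest.approx(
                double_sum_output(model, x), abs=1e-10
            )

    def test_zero_weights_zero_output(self, rng):
        model, X = self._fitted(rng)
        model.weights_ = np.zeros_like(model.weights_)
        assert model.decision_function(X[0]) == 0.0
        # tie broken to the positive class (the larger label)
        assert model.predict(X[0]) == model.classes_[1]

    def test_linear_only_weights_give_affine_output(self, rng):
        model, X = self._fitted(rng)
        D = X.shape[1]
        w = np.zeros_like(model.weights_)
        w[: D + 1] = np.arange(1.0, D + 2)
        model.weights_ = w
        x1, x2 = X[0], X[1]
        o = model.decision_function
        # affinity: o(midpoint) == mean of endpoint outputs
        assert o((x1 + x2) / 2) == pytest.approx((o(x1) + o(x2)) / 2, abs=1e-10)

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            GGFWC().decision_function(np.zeros(3))


class TestSerialization:
    def test_json_round_trip_bit_exact(self, rng, tmp_path):
        X = rng.standard_normal((50, 3))
        y = np.where(X[:, 1] > 0, 1, 2)
        model = GGFWC(R=4, delta=2.5, margin_C=10.0, seed=3).fit(X, y)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = GGFWC.load(path)
        assert np.array_equal(loaded.weights_, model.weights_)
        assert np.array_equal(loaded.mean_, model.mean_)
        assert np.array_equal(loaded.std_, model.std_)
        assert np.array_equal(loaded.gates_.centroids, model.gates_.centroids)
        assert np.array_equal(loaded.gates_.dispersions, model.gates_.dispersions)
        Xt = rng.standard_normal((20, 3))
        assert np.array_equal(loaded.decision_function(Xt), model.decision_function(Xt))
        assert np.array_equal(loaded.predict(Xt), model.predict(Xt))
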