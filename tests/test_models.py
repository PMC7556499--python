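"""Kernel, GRNN, RBF and MLP behaviour against closed forms and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citrusann import models as M
from citrusann.dataset import encode_features
from citrusann.evaluation import make_split_context, r_squared
from citrusann.synthetic import generate_table

from conftest import noiseless_config


class TestGaussianKernel:
    def test_zero_distance_gives_one(self):
        x = np.array([0.3, -0.2, 1.0, 0.5])
        assert M.gaussian_kernel(x, x, h=0.7) == 1.0

    def test_half_value_at_distance_h(self):
        # the 0.8326 factor is sqrt(ln 2) to 4 decimals, so k(d=h) = 0.5
        for h in (0.1, 1.0, 3.7):
            k = M.gaussian_kernel(np.array([0.0]), np.array([h]), h=h)
            assert k == pytest.approx(0.5, abs=5e-5)

    def test_vanishes_at_large_distance(self):
        k = M.gaussian_kernel(np.array([0.0]), np.array([100.0]), h=0.5)
        assert k == 0.0

    @pytest.mark.parametrize("h", [0.0, -1.0])
    def test_nonpositive_spread_rejected(self, h):
        with pytest.raises(ValueError, match="positive"):
            M.gaussian_kernel(np.zeros(2), np.ones(2), h)


class TestGRNN:
    def test_single_training_point_returns_its_target(self):
        m = M.grnn_fit(np.array([[0.0, 0.0]]), np.array([3.7]), h=1.0)
        for q in ([0.0, 0.0], [5.0, -2.0], [100.0, 100.0]):
            assert M.grnn_predict(m, np.array(q)) == pytest.approx(3.7)

    def test_tiny_spread_memorizes_unique_nearest_neighbour(self):
        X = np.array([[0.0], [1.0], [2.0]])
        T = np.array([10.0, 20.0, 30.0])
        m = M.grnn_fit(X, T, h=1e-3)
        assert M.grnn_predict(m, np.array([1.05])) == pytest.approx(20.0)

    def test_equidistant_pair_averages(self):
        m = M.grnn_fit(np.array([[0.0], [2.0]]), np.array([0.0, 1.0]), h=0.8)
        assert M.grnn_predict(m, np.array([1.0])) == pytest.approx(0.5)

    def test_predictions_are_convex_combinations_of_targets(self, rng):
        X = rng.uniform(-1, 1, (40, 4))
        T = rng.normal(size=40)
        queries = rng.uniform(-3, 3, (200, 4))
        for h in (0.05, 0.3, 2.0):
            pred = M.grnn_fit(X, T, h).predict(queries)
            assert np.all(pred >= T.min() - 1e-12)
            assert np.all(pred <= T.max() + 1e-12)

    def test_small_spread_reproduces_training_targets(self, rng):
        X = rng.uniform(-1, 1, (30, 3))
        T = rng.normal(size=30)
        m = M.grnn_fit(X, T, h=1e-3)
        np.testing.assert_allclose(m.predict(X), T, atol=1e-10)
        assert r_squared(T, m.predict(X) + rng.normal(0, 1e-9, 30)) > 0.999999

    def test_agrees_with_naive_double_loop(self, rng):
        X = rng.uniform(-1, 1, (25, 4))
        T = rng.normal(size=25)
        h = 0.6
        model = M.grnn_fit(X, T, h)
        queries = rng.uniform(-1.5, 1.5, (30, 4))
        for q in queries:
            num = den = 0.0
            for xb, tb in zip(X, T):
                k = np.exp(-((np.linalg.norm(q - xb) * 0.8326 / h) ** 2))
                num += tb * k
                den += k
            assert M.grnn_predict(model, q) == pytest.approx(num / den, abs=1e-10)

    def test_serialization_round_trip(self, rng):
        m = M.grnn_fit(rng.normal(size=(10, 4)), rng.normal(size=10), 0.4)
        m2 = M.GRNNModel.from_dict(m.to_dict())
        q = rng.normal(size=(5, 4))
        np.testing.assert_array_equal(m.predict(q), m2.predict(q))


class TestSelectSpread:
    def test_single_candidate_returned(self, rng):
        X = rng.normal(size=(10, 2))
        T = rng.normal(size=10)
        assert M.select_spread(X, T, np.array([0.42])) == 0.42

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            M.select_spread(rng.normal(size=(5, 2)), rng.normal(size=5), np.array([]))

    def test_ties_broken_toward_larger_spread(self):
        # with two training points, the LOO prediction is always the other
        # point's target whatever h, so every candidate ties
        X = np.array([[0.0], [1.0]])
        T = np.array([0.0, 1.0])
        assert M.select_spread(X, T, np.array([0.2, 1.0, 3.0])) == 3.0

    def test_beats_grid_endpoints_on_smooth_surface(self):
        table = generate_table(noiseless_config())
        X, Y, _ = encode_features(table)
        ctx = make_split_context(X, Y, seed=0)
        tn = ctx.y_norm.apply_column(ctx.Y_train[:, 0], 0)
        grid = np.geomspace(0.01, 10.0, 25)
        h = M.select_spread(ctx.X_train_n, tn, grid)
        loo = lambda hh: M._grnn_loo_rmse(ctx.X_train_n, tn, hh)
        assert loo(h) < loo(grid[0])
        assert loo(h) < loo(grid[-1])


class TestRBF:
    def test_exact_interpolation_at_zero_ridge(self, rng):
        X = rng.uniform(-1, 1, (20, 3))
        T = rng.normal(size=20)
        m = M.rbf_fit(X, T, h=1.0, ridge=0.0)
        np.testing.assert_allclose(m.predict(X), T, atol=1e-6)

    def test_grnn_smooths_where_rbf_interpolates(self, rng):
        X = rng.uniform(-1, 1, (15, 2))
        T = rng.normal(size=15)
        rbf = M.rbf_fit(X, T, h=0.8, ridge=0.0)
        grnn = M.grnn_fit(X, T, h=0.8)
        np.testing.assert_allclose(rbf.predict(X), T, atol=1e-6)
        assert np.max(np.abs(grnn.predict(X) - T)) > 1e-3

    def test_constant_target_absorbed_by_bias(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        T = np.array([5.0, 5.0, 5.0])
        m = M.rbf_fit(X, T, h=1.0)
        assert m.bias == pytest.approx(5.0)
        np.testing.assert_allclose(m.weights, 0.0, atol=1e-8)
        assert m.predict(np.array([[0.3, 0.3]]))[0] == pytest.approx(5.0)

    def test_far_from_centers_predicts_bias(self, rng):
        X = rng.uniform(-1, 1, (10, 2))
        T = rng.normal(size=10)
        m = M.rbf_fit(X, T, h=0.5)
        far = m.predict(np.array([[50.0, 50.0]]))[0]
        assert far == pytest.approx(m.bias)

    def test_duplicate_points_with_zero_ridge_fail(self):
        X = np.array([[0.0], [0.0], [1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            M.rbf_fit(X, np.array([0.0, 1.0, 2.0]), h=1.0, ridge=0.0)

    def test_serialization_round_trip(self, rng):
        m = M.rbf_fit(rng.normal(size=(8, 2)), rng.normal(size=8), h=0.9)
        m2 = M.RBFModel.from_dict(m.to_dict())
        q = rng.normal(size=(4, 2))
        np.testing.assert_allclose(m.predict(q), m2.predict(q), rtol=1e-15)


class TestMLP:
    def test_zero_weight_network_predicts_zero(self):
        m = M.MLPModel(np.zeros((3, 2)), np.zeros(3), np.zeros(3), 0.0)
        assert M.mlp_predict(m, np.array([4.0, -7.0])) == 0.0

    def test_learns_linear_map(self):
        X = np.linspace(-1, 1, 50)[:, None]
        T = X.ravel()
        m = M.mlp_fit(X, T, m_hidden=4, seed=0)
        train_rmse = float(np.sqrt(np.mean((m.predict(X) - T) ** 2)))
        assert train_rmse < 0.05

    def test_seed_determinism(self, rng):
        X = rng.uniform(-1, 1, (30, 2))
        T = rng.normal(size=30)
        a = M.mlp_fit(X, T, 3, seed=5)
        b = M.mlp_fit(X, T, 3, seed=5)
        np.testing.assert_array_equal(a.W_hidden, b.W_hidden)
        np.testing.assert_array_equal(a.w_out, b.w_out)

    def test_accepted_loss_trajectory_non_increasing(self, rng):
        X = rng.uniform(-1, 1, (40, 2))
        T = np.sin(2 * X[:, 0]) + rng.normal(0, 0.05, 40)
        m = M.mlp_fit(X, T, 4, seed=1)
        hist = np.array(m.loss_history)
        assert len(hist) > 3
        assert np.all(np.diff(hist) <= 1e-10)

    def test_serialization_round_trip(self, rng):
        X = rng.uniform(-1, 1, (20, 2))
        m = M.mlp_fit(X, rng.normal(size=20), 2, seed=0)
        m2 = M.MLPModel.from_dict(m.to_dict())
        np.testing.assert_allclose(m.predict(X), m2.predict(X), rtol=1e-12)

    def test_invalid_hidden_size_rejected(self):
        with pytest.raises(ValueError):
            M.mlp_fit(np.zeros((5, 2)), np.zeros(5), m_hidden=0)


class TestChooseHiddenNeurons:
    def test_standard_heuristics_present(self):
        cands = M.choose_hidden_neurons(4, 96)
        assert {2, 4, 8} <= set(cands)

    def test_sorted_unique(self):
        cands = M.choose_hidden_neurons(2, 1000)
        assert cands == sorted(set(cands))

    @given(st.integers(1, 10), st.integers(2, 10000))
    @settings(deadline=None, max_examples=30)
    def test_always_valid_sizes(self, n, k):
        cands = M.choose_hidden_neurons(n, k)
        assert all(c >= 1 for c in cands)

    def test_single_candidate_selection_returns_it(self, rng):
        X = rng.uniform(-1, 1, (20, 2))
        T = rng.normal(size=20)
        m = M.select_mlp(X, T, candidates=[3], seed=0)
        assert m.m_hidden == 3
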