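import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, strategies as st

from elmseizure.elm import (
    ELMConfig,
    ELMModel,
    NotTrainedError,
    decision_scores,
    default_hidden_neurons,
    default_sweep_grid,
    derive_seed,
    fit,
    hidden_activations,
    init_hidden,
    load_model,
    predict,
    save_model,
    solve_output_weights,
    sweep_hidden_neurons,
)


def svd_pinv_solve(H, Y, rtol=1e-12):
    """Independent oracle: explicit SVD pseudoinverse, beta = V S+ U^T Y."""
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    keep = s > rtol * s[0]
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    return Vt.T @ (s_inv[:, None] * (U.T @ Y))


class TestInitHidden:
    def test_shapes_and_ranges(self):
        m = init_hidden(ELMConfig(n_hidden=3, seed=0), 2)
        assert m.W.shape == (3, 2) and m.b.shape == (3,)
        assert (m.W >= -1).all() and (m.W <= 1).all()
        assert (m.b >= 0).all() and (m.b <= 1).all()

    def test_same_seed_identical(self):
        a = init_hidden(ELMConfig(n_hidden=5, seed=11), 4)
        b = init_hidden(ELMConfig(n_hidden=5, seed=11), 4)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.b, b.b)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ELMConfig(n_hidden=0)
        with pytest.raises(ValueError):
            ELMConfig(n_hidden=2, input_weight_range=(1, -1))
        with pytest.raises(ValueError):
            init_hidden(ELMConfig(n_hidden=2), 0)


class TestHiddenActivations:
    def test_zero_weights_give_half(self):
        m = ELMModel(W=np.zeros((4, 3)), b=np.zeros(4), config=ELMConfig(4), n_features=3)
        H = hidden_activations(m, np.random.default_rng(0).normal(size=(5, 3)))
        np.testing.assert_allclose(H, 0.5)

    def test_large_inputs_saturate_without_overflow(self):
        m = ELMModel(W=np.array([[1.0]]), b=np.array([0.0]), config=ELMConfig(1), n_features=1)
        with np.errstate(over="raise"):
            H = hidden_activations(m, np.array([[0.0], [1000.0], [-1000.0]]))
        np.testing.assert_allclose(H[:, 0], [0.5, 1.0, 0.0], atol=1e-12)

    def test_monotone_in_preactivation(self, rng):
        m = ELMModel(W=np.array([[2.0]]), b=np.array([0.3]), config=ELMConfig(1), n_features=1)
        x = np.sort(rng.normal(size=20)).reshape(-1, 1)
        H = hidden_activations(m, x)[:, 0]
        assert (np.diff(H) > 0).all()

    def test_dimension_mismatch(self, tiny_trained_model):
        model, _, _ = tiny_trained_model
        with pytest.raises(ValueError):
            hidden_activations(model, np.zeros((3, 5)))


class TestFit:
    def test_identity_hidden_matrix_returns_targets(self):
        Y = np.arange(6, dtype=float).reshape(6, 1)
        beta = solve_output_weights(np.eye(6), Y)
        np.testing.assert_allclose(beta, Y, atol=1e-12)

    def test_matches_svd_pseudoinverse_oracle(self, rng):
        H = rng.normal(size=(30, 5))
        Y = rng.normal(size=(30, 1))
        beta = solve_output_weights(H, Y)
        np.testing.assert_allclose(beta, svd_pinv_solve(H, Y), atol=1e-8)
        # residual orthogonal to the column space of H
        assert np.linalg.norm(H.T @ (H @ beta - Y)) <= 1e-8

    def test_interpolates_when_L_equals_n(self, rng):
        n = 20
        X = rng.normal(size=(n, 3))
        y = rng.integers(0, 2, size=n)
        model = fit(init_hidden(ELMConfig(n_hidden=n, seed=5), 3), X, y)
        assert (predict(model, X) == y).all()
        np.testing.assert_allclose(decision_scores(model, X)[:, 0], y, atol=1e-6)

    def test_rejects_empty_and_nonfinite(self):
        m = init_hidden(ELMConfig(n_hidden=2, seed=0), 2)
        with pytest.raises(ValueError):
            fit(m, np.empty((0, 2)), np.empty(0))
        with pytest.raises(ValueError):
            fit(m, np.array([[np.nan, 0.0]]), np.array([1]))

    def test_binary_encoding_requires_01(self, rng):
        m = init_hidden(ELMConfig(n_hidden=2, seed=0), 2)
        with pytest.raises(ValueError):
            fit(m, rng.normal(size=(4, 2)), np.array([1, 2, 3, 4]))

    def test_duplicate_row_leaves_decision_unchanged_when_consistent(self, rng):
        # L >= n makes the linear system consistent (interpolation regime)
        X = rng.normal(size=(10, 2))
        y = rng.integers(0, 2, size=10)
        m0 = init_hidden(ELMConfig(n_hidden=16, seed=2), 2)
        a = fit(m0, X, y)
        Xd = np.vstack([X, X[3]])
        yd = np.r_[y, y[3]]
        b = fit(m0, Xd, yd)
        probe = rng.normal(size=(25, 2))
        np.testing.assert_allclose(
            decision_scores(a, probe), decision_scores(b, probe), atol=1e-6
        )


class TestPredict:
    def test_untrained_model_raises(self):
        m = init_hidden(ELMConfig(n_hidden=2, seed=0), 2)
        with pytest.raises(NotTrainedError):
            decision_scores(m, np.zeros((1, 2)))
        with pytest.raises(NotTrainedError):
            predict(m, np.zeros((1, 2)))

    def test_boundary_score_labels_positive(self):
        # W=0, b=0 -> H = 0.5; beta = [1] -> score exactly 0.5
        m = ELMModel(
            W=np.zeros((1, 1)), b=np.zeros(1), config=ELMConfig(1),
            n_features=1, beta=np.array([[1.0]]), encoding="binary",
        )
        assert predict(m, np.array([[0.0]]), threshold=0.5)[0] == 1

    def test_onehot_argmax_and_tie_break(self):
        m = ELMModel(
            W=np.zeros((1, 1)), b=np.zeros(1), config=ELMConfig(1), n_features=1,
            beta=np.array([[0.4, 1.8, 0.2, 0.0, 0.0]]), encoding="onehot",
            classes_=np.array([1, 2, 3, 4, 5]),
        )
        assert predict(m, np.array([[0.0]]))[0] == 2
        tie = replace(m, beta=np.array([[0.8, 0.8, 0.1, 0.0, 0.0]]))
        assert predict(tie, np.array([[0.0]]))[0] == 1

    def test_invalid_threshold(self, tiny_trained_model):
        model, X, _ = tiny_trained_model
        with pytest.raises(ValueError):
            predict(model, X, threshold=np.inf)

    @given(st.integers(0, 2**16))
    def test_raising_threshold_never_adds_positives(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(int)
        model = fit(init_hidden(ELMConfig(n_hidden=8, seed=seed), 2), X, y)
        counts = [int(predict(model, X, threshold=t).sum()) for t in np.linspace(-1, 2, 13)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_scores_are_rowwise(self, tiny_trained_model, rng):
        model, X, _ = tiny_trained_model
        perm = rng.permutation(len(X))
        np.testing.assert_allclose(
            decision_scores(model, X)[perm], decision_scores(model, X[perm])
        )

    def test_multiclass_onehot_training(self, rng):
        X = rng.normal(size=(60, 3)) + 3 * np.eye(3)[rng.integers(0, 3, 60)]
        y = X.argmax(axis=1) + 1
        model = fit(init_hidden(ELMConfig(n_hidden=60, seed=1), 3), X, y, encoding="onehot")
        assert (predict(model, X) == y).mean() > 0.95


class TestSweep:
    def test_singleton_grid(self, rng):
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] > 0).astype(int)
        res = sweep_hidden_neurons(X, y, X, y, [7], seed=0)
        assert res.best_L == 7 and res.grid == (7,)

    def test_best_is_grid_member_and_curve_full(self, rng):
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] + 0.3 * rng.normal(size=60) > 0).astype(int)
        grid = [2, 5, 10, 20]
        res = sweep_hidden_neurons(X[:40], y[:40], X[40:], y[40:], grid, seed=1)
        assert res.best_L in grid
        assert len(res.accuracies) == len(grid)

    def test_overparameterized_warns(self, rng):
        X = rng.normal(size=(10, 2))
        y = (X[:, 0] > 0).astype(int)
        with pytest.warns(UserWarning, match="overparameterized"):
            sweep_hidden_neurons(X, y, X, y, [150], seed=0)

    def test_default_grid_contains_tenth_anchor(self):
        assert 920 in default_sweep_grid(9200)
        assert 805 in default_sweep_grid(8050)
        assert 690 in default_sweep_grid(6900)
        assert default_hidden_neurons(9200) == 920

    def test_sweep_reproducible(self, rng):
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] > 0).astype(int)
        a = sweep_hidden_neurons(X, y, X, y, [3, 6], seed=4)
        b = sweep_hidden_neurons(X, y, X, y, [3, 6], seed=4)
        assert a == b


class TestSerialization:
    def test_roundtrip_bit_exact(self, tiny_trained_model, tmp_path):
        model, X, _ = tiny_trained_model
        p = tmp_path / "model.npz"
        save_model(model, p)
        loaded = load_model(p)
        np.testing.assert_array_equal(model.W, loaded.W)
        np.testing.assert_array_equal(model.b, loaded.b)
        np.testing.assert_array_equal(model.beta, loaded.beta)
        assert loaded.config == model.config
        np.testing.assert_array_equal(decision_scores(model, X), decision_scores(loaded, X))

    def test_untrained_roundtrip(self, tmp_path):
        m = init_hidden(ELMConfig(n_hidden=3, seed=1), 2)
        p = tmp_path / "m.npz"
        save_model(m, p)
        assert not load_model(p).is_trained


def test_derive_seed_stable_and_bounded():
    assert derive_seed(1, 920) == derive_seed(1, 920)
    assert derive_seed(1, 920) != derive_seed(1, 805)
    assert 0 <= derive_seed(2**20, 12345) < 2**31
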