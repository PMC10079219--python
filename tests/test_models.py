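import numpy as np
import pytest

from linablate import (
    HyperparameterGrid,
    ModelSpec,
    TrainConfig,
    balanced_accuracy,
    build_model,
    load_checkpoint,
    nested_cv_select,
    parameter_count,
    predict,
    save_checkpoint,
    train,
)
from linablate.models import _ovr_hinge, _softmax_xent

ALL_KINDS = ("logreg", "linear_svm", "mlp3", "mlp5")


def _blobs(n_per_class=60, dim=2, shift=6.0, seed=0):
    """Two Gaussian blobs separated by ``shift`` along every axis,
    centred at +/- shift/2 so neither class sits at the origin."""
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(-shift / 2, 1.0, size=(n_per_class, dim)),
        rng.normal(+shift / 2, 1.0, size=(n_per_class, dim)),
    ]).astype(np.float32)
    y = np.repeat([0, 1], n_per_class)
    order = rng.permutation(len(y))
    return X[order], y[order]


class TestArchitecture:
    def test_mlp3_parameter_count_matches_affine_arithmetic(self):
        # widths 2500 / 1250: sum over affine layers of in*out + out
        expected = 5000 * 2500 + 2500 + 2500 * 1250 + 1250 + 1250 * 2 + 2
        assert parameter_count(ModelSpec("mlp3", 5000, 2)) == expected

    @pytest.mark.parametrize("d,L", [(10, 2), (7, 5)])
    def test_linear_kinds_have_affine_parameter_count(self, d, L):
        assert parameter_count(ModelSpec("logreg", d, L)) == d * L + L
        assert parameter_count(ModelSpec("linear_svm", d, L)) == d * L + L

    def test_mlp5_has_batch_norm_parameters(self):
        affine = 10 * 2500 + 2500 + 2 * (2500 * 2500 + 2500) + 2500 * 1250 + 1250 + 1250 * 2 + 2
        bn = 2 * (2500 * 3 + 1250)
        assert parameter_count(ModelSpec("mlp5", 10, 2)) == affine + bn

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            ModelSpec("transformer", 10, 2)

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_same_seed_builds_identical_models(self, kind):
        a = build_model(ModelSpec(kind, 12, 3), seed=5)
        b = build_model(ModelSpec(kind, 12, 3), seed=5)
        for pa, pb in zip(a.state_arrays(), b.state_arrays()):
            np.testing.assert_array_equal(pa, pb)


class TestPredict:
    def test_fresh_model_breaks_ties_to_lowest_class(self):
        # output layer starts at zero, so all scores are equal
        model = build_model(ModelSpec("logreg", 4, 3), seed=0)
        labels, scores = predict(model, np.ones((5, 4), dtype=np.float32))
        np.testing.assert_array_equal(scores, 0.0)
        np.testing.assert_array_equal(labels, 0)

    def test_known_weights_give_sign_rule(self):
        model = build_model(ModelSpec("logreg", 2, 2), seed=0)
        model.layers[0].W[:] = np.array([[-1.0, 1.0], [1.0, -1.0]], dtype=np.float32)
        labels, _ = predict(model, np.array([[2.0, 0.0], [0.0, 2.0]], dtype=np.float32))
        np.testing.assert_array_equal(labels, [1, 0])

    def test_dimension_mismatch_rejected(self):
        model = build_model(ModelSpec("logreg", 3, 2), seed=0)
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.ones((2, 4)))

    def test_prediction_is_deterministic(self):
        X, y = _blobs()
        model = build_model(ModelSpec("mlp3", 2, 2), seed=1)
        train(model, (X, y), (X[:20], y[:20]), TrainConfig(seed=1, max_epochs=2))
        first, s1 = predict(model, X)
        second, s2 = predict(model, X)
        np.testing.assert_array_equal(first, second)
        np.testing.assert_array_equal(s1, s2)


class TestLosses:
    @pytest.mark.parametrize("loss_fn", [_softmax_xent, _ovr_hinge])
    def test_gradient_matches_finite_differences(self, loss_fn):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(6, 3))
        y = rng.integers(0, 3, size=6)
        w = rng.uniform(0.5, 2.0, size=6)
        loss, dz = loss_fn(scores, y, w)
        eps = 1e-6
        for i in range(6):
            for j in range(3):
                bumped = scores.copy()
                bumped[i, j] += eps
                num = (loss_fn(bumped, y, w)[0] - loss) / eps
                assert num == pytest.approx(dz[i, j], abs=1e-4)


class TestTraining:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_separable_blobs_learned_perfectly(self, kind):
        X, y = _blobs()
        model = build_model(ModelSpec(kind, 2, 2), seed=0)
        train(model, (X, y), (X[:24], y[:24]), TrainConfig(seed=0))
        labels, _ = predict(model, X)
        assert balanced_accuracy(y, labels) == 1.0

    def test_log_respects_max_epochs_and_restores_best(self):
        X, y = _blobs(seed=3)
        model = build_model(ModelSpec("logreg", 2, 2), seed=0)
        _, log = train(model, (X, y), (X[:24], y[:24]),
                       TrainConfig(seed=0, max_epochs=7, early_stopping_patience=100))
        assert len(log) <= 7
        assert [e["epoch"] for e in log] == list(range(len(log)))

    def test_early_stopping_halts_on_plateau(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 5)).astype(np.float32)  # pure noise
        y = np.tile([0, 1], 40)
        Xe = rng.normal(size=(20, 5)).astype(np.float32)  # disjoint noise
        ye = np.tile([0, 1], 10)
        model = build_model(ModelSpec("logreg", 5, 2), seed=0)
        _, log = train(model, (X, y), (Xe, ye),
                       TrainConfig(seed=0, early_stopping_patience=3))
        assert len(log) < 50

    def test_training_is_bit_reproducible(self):
        X, y = _blobs(seed=5)
        runs = []
        for _ in range(2):
            model = build_model(ModelSpec("mlp3", 2, 2), seed=2)
            train(model, (X, y), (X[:24], y[:24]), TrainConfig(seed=2, max_epochs=3))
            runs.append([a.copy() for a in model.state_arrays()])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_empty_sets_rejected(self):
        X, y = _blobs()
        model = build_model(ModelSpec("logreg", 2, 2), seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            train(model, (X[:0], y[:0]), (X, y), TrainConfig())

    def test_early_stop_class_missing_from_train_rejected(self):
        X, y = _blobs()
        model = build_model(ModelSpec("logreg", 2, 2), seed=0)
        with pytest.raises(ValueError, match="absent from training"):
            train(model, (X[y == 0], y[y == 0]), (X, y), TrainConfig())

    def test_inverse_frequency_weighting_resists_majority_collapse(self):
        """On a 9:1 problem with a real separating direction the weighted
        model must not fall back to always predicting the majority class."""
        rng = np.random.default_rng(6)
        X = np.vstack([
            rng.normal(-1.0, 1.0, size=(180, 3)),
            rng.normal(+1.0, 1.0, size=(20, 3)),
        ]).astype(np.float32)
        y = np.repeat([0, 1], [180, 20])
        order = rng.permutation(200)
        X, y = X[order], y[order]
        model = build_model(ModelSpec("logreg", 3, 2), seed=0)
        train(model, (X, y), (X[:40], y[:40]), TrainConfig(seed=0))
        labels, _ = predict(model, X)
        minority_recall = (labels[y == 1] == 1).mean()
        assert minority_recall > 0.5


class TestNestedCV:
    def test_single_point_grid_returned_directly(self):
        grid = HyperparameterGrid(learning_rates=(3e-3,), weight_decays=(1e-5,))
        X, y = _blobs(n_per_class=10)
        assert nested_cv_select(ModelSpec("logreg", 2, 2), grid, X, y) == (3e-3, 1e-5)

    def test_absurd_weight_decay_not_selected_on_separable_data(self):
        # off-centre blobs: the decision needs a non-zero bias, which an
        # absurd penalty prevents from ever growing
        rng = np.random.default_rng(7)
        X = np.vstack([
            rng.normal(1.0, 0.3, size=(40, 2)),
            rng.normal(3.0, 0.3, size=(40, 2)),
        ]).astype(np.float32)
        y = np.repeat([0, 1], 40)
        grid = HyperparameterGrid(learning_rates=(1e-2,), weight_decays=(1e-4, 1e6))
        _, wd = nested_cv_select(ModelSpec("logreg", 2, 2), grid, X, y, seed=0)
        assert wd == 1e-4

    def test_tied_scores_break_to_small_lr_large_wd(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(24, 2)).astype(np.float32)
        y = np.tile([0, 1], 12)
        grid = HyperparameterGrid(learning_rates=(1e-7, 1e-8), weight_decays=(0.0, 1e-3))
        # at these learning rates nothing moves: every point scores the same
        lr, wd = nested_cv_select(ModelSpec("logreg", 2, 2), grid, X, y, seed=0)
        assert (lr, wd) == (1e-8, 1e-3)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            HyperparameterGrid(learning_rates=(), weight_decays=(1e-4,)).points()


def test_checkpoint_round_trip(tmp_path):
    X, y = _blobs(seed=9)
    spec = ModelSpec("mlp5", 2, 2)
    model = build_model(spec, seed=3)
    config = TrainConfig(seed=3, max_epochs=2)
    train(model, (X, y), (X[:24], y[:24]), config)
    save_checkpoint(model, tmp_path / "ckpt", config)
    restored = load_checkpoint(tmp_path / "ckpt")
    np.testing.assert_array_equal(predict(model, X)[1], predict(restored, X)[1])
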