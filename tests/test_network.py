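"""FDL network contracts: deterministic construction, probability outputs,
analytic gradients vs central differences, SGD descent, early stopping, and
checkpoint round trips."""

import numpy as np
import pytest

from fuzzsurv.network import (
    FDLConfig,
    FDLNetwork,
    TrainConfig,
    TrainingDiverged,
    build_fdl,
    load_checkpoint,
    save_checkpoint,
    train,
)

TINY = FDLConfig(n_rules=4, n_mfs=2, n_agg_units=3, hidden=(6,), seed=11)


@pytest.fixture()
def tiny_data():
    rng = np.random.default_rng(5)
    X = rng.random((5, 3))
    y = np.array([0, 1, 2, 3, 4])
    return X, y


def central_difference_grads(net, X, y, h=1e-6):
    flat = net.get_flat_params().copy()
    num = np.zeros_like(flat)
    for i in range(flat.size):
        p = flat.copy()
        p[i] += h
        net.set_flat_params(p)
        lp, _ = net.loss_and_grads(X, y)
        p[i] -= 2 * h
        net.set_flat_params(p)
        lm, _ = net.loss_and_grads(X, y)
        num[i] = (lp - lm) / (2 * h)
    net.set_flat_params(flat)
    return num


class TestBuildAndForward:
    def test_same_seed_identical_parameters(self, tiny_data):
        X, _ = tiny_data
        a = build_fdl(3, config=TINY, X_init=X)
        b = build_fdl(3, config=TINY, X_init=X)
        assert np.array_equal(a.get_flat_params(), b.get_flat_params())
        assert np.array_equal(a.A, b.A)

    def test_scores_are_probability_rows(self, tiny_data):
        X, _ = tiny_data
        net = build_fdl(3, config=TINY, X_init=X)
        P = net.forward(X)
        assert P.shape == (5, 6)
        assert np.all(P >= 0) and np.all(P <= 1)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_batched_equals_single_sample(self, tiny_data):
        X, _ = tiny_data
        net = build_fdl(3, config=TINY, X_init=X)
        batch = net.forward(X)
        for i in range(len(X)):
            single = net.forward(X[i : i + 1])
            assert np.allclose(single[0], batch[i], atol=1e-9)

    def test_predictions_in_class_range(self, tiny_data):
        X, _ = tiny_data
        net = build_fdl(3, config=TINY, X_init=X)
        assert set(net.predict(X)) <= set(range(6))

    def test_argmax_ties_break_to_lowest_class(self):
        net = build_fdl(3, config=TINY)
        scores = np.array([[0.1, 0.1, 0.1, 0.1, 0.1, 0.5], [0.3, 0.1, 0.3, 0.1, 0.1, 0.1]])
        assert list(scores.argmax(axis=1)) == [5, 0]
        # network predict is argmax of its own scores
        X = np.random.default_rng(0).random((4, 3))
        assert np.array_equal(net.predict(X), net.predict_scores(X).argmax(axis=1))

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            build_fdl(0)
        net = build_fdl(3, config=TINY)
        with pytest.raises(ValueError):
            net.forward(np.zeros((2, 4)))


class TestGradients:
    def test_analytic_matches_central_differences(self, tiny_data):
        X, y = tiny_data
        net = build_fdl(3, config=TINY, X_init=X)
        _, g = net.loss_and_grads(X, y)
        num = central_difference_grads(net, X, y)
        denom = np.maximum(np.maximum(np.abs(num), np.abs(g)), 1e-8)
        mask = (np.abs(num) + np.abs(g)) > 1e-10
        assert (np.abs(num - g) / denom)[mask].max() < 1e-4

    def test_single_sgd_step_decreases_sample_loss(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            X = rng.random((1, 4))
            y = np.array([rng.integers(0, 6)])
            net = build_fdl(4, config=FDLConfig(n_rules=3, n_mfs=2, n_agg_units=2,
                                                hidden=(5,), seed=trial))
            loss0, g = net.loss_and_grads(X, y)
            net.set_flat_params(net.get_flat_params() - 1e-6 * g)
            loss1, _ = net.loss_and_grads(X, y)
            assert loss1 < loss0


class TestTraining:
    def test_flat_validation_stops_patience_after_best(self, tiny_data):
        X, y = tiny_data
        net = build_fdl(3, config=TINY, X_init=X)
        # learning rate so small that validation accuracy never moves
        cfg = TrainConfig(learning_rate=1e-15, batch_size=2, patience_epochs=12,
                          max_epochs=100, seed=0)
        hist = train(net, X, y, X, y, cfg)
        assert hist.best_epoch == 1
        assert hist.stopped_epoch == hist.best_epoch + 12
        assert len(hist.val_accuracy) == hist.stopped_epoch

    def test_bit_identical_histories_for_same_seed(self, tiny_data):
        X, y = tiny_data
        cfg = TrainConfig(learning_rate=1e-2, batch_size=2, patience_epochs=5,
                          max_epochs=15, seed=3)
        runs = []
        for _ in range(2):
            net = build_fdl(3, config=TINY, X_init=X)
            hist = train(net, X, y, X, y, cfg)
            runs.append((hist.train_loss, hist.val_accuracy, net.get_flat_params()))
        assert runs[0][0] == runs[1][0]
        assert runs[0][1] == runs[1][1]
        assert np.array_equal(runs[0][2], runs[1][2])

    def test_learns_separable_blobs(self):
        from sklearn.datasets import make_blobs

        X, y = make_blobs(n_samples=200, centers=2, cluster_std=1.0, random_state=0)
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        net = build_fdl(2, config=FDLConfig(seed=0), X_init=X)
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=200, patience_epochs=200, seed=0)
        hist = train(net, X, y, X, y, cfg)
        assert max(hist.train_accuracy) >= 0.95

    def test_empty_data_rejected(self, tiny_data):
        X, y = tiny_data
        net = build_fdl(3, config=TINY)
        with pytest.raises(ValueError):
            train(net, X[:0], y[:0], X, y, TrainConfig())

    def test_divergence_reported_with_epoch(self, tiny_data):
        X, y = tiny_data
        net = build_fdl(3, config=TINY, X_init=X)
        net.set_flat_params(net.get_flat_params() * np.nan)
        with pytest.raises(TrainingDiverged, match="epoch 1"):
            train(net, X, y, X, y,
                  TrainConfig(learning_rate=1e-3, max_epochs=5, patience_epochs=5))

    @pytest.mark.parametrize("bad", [
        {"learning_rate": 0.0}, {"batch_size": 0},
        {"patience_epochs": 20, "max_epochs": 10},
    ])
    def test_invalid_train_config_rejected(self, bad):
        with pytest.raises(ValueError):
            TrainConfig(**bad)


def test_checkpoint_round_trip(tmp_path, tiny_data):
    X, y = tiny_data
    net = build_fdl(3, config=TINY, X_init=X)
    train(net, X, y, X, y, TrainConfig(learning_rate=1e-3, max_epochs=3,
                                       patience_epochs=3, seed=0))
    p = tmp_path / "model.json"
    save_checkpoint(net, p)
    back = load_checkpoint(p)
    assert isinstance(back, FDLNetwork)
    assert np.array_equal(back.forward(X), net.forward(X))
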