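"""Baseline-recognition MLP: architecture, training, metrics, persistence."""

import numpy as np
import pytest

from neurostat.mlp import (
    DO_SCALE,
    BaselineRecognition,
    EvalMetrics,
    ModelConfig,
    TrainingConfig,
    build_model,
    evaluate,
    load_model,
    predict_baseline,
    save_model,
    train,
)
from neurostat.synth import GeneratorParams, SyntheticDataset, generate_dataset


class TestBuild:
    def test_default_layer_widths(self):
        model = build_model(seed=0)
        shapes = [w.shape for w in model.weights]
        assert shapes == [(60, 1024), (1024, 512), (512, 256), (256, 128), (128, 1)]
        assert [b.shape for b in model.biases] == [(1024,), (512,), (256,), (128,), (1,)]

    def test_zero_parameters_give_zero_output(self):
        model = build_model(ModelConfig(hidden_sizes=(8, 4)), seed=0)
        for w in model.weights:
            w[:] = 0
        assert predict_baseline(model, np.zeros(60)) == 0.0
        assert predict_baseline(model, np.full(60, 50.0)) == 0.0

    def test_seeded_initialization_reproducible(self):
        a = build_model(seed=5)
        b = build_model(seed=5)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)
        c = build_model(seed=6)
        assert not np.array_equal(a.weights[0], c.weights[0])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_sizes=())
        with pytest.raises(ValueError):
            ModelConfig(output_size=2)
        with pytest.raises(ValueError):
            ModelConfig(activation="tanh")


class TestTrain:
    def test_memorizes_constant_map(self):
        X = np.tile(np.linspace(20, 40, 60), (64, 1))
        y = np.full(64, 31.5)
        ds = SyntheticDataset(X, y)
        model = build_model(ModelConfig(hidden_sizes=(32,)), seed=0)
        train(model, ds, TrainingConfig(epochs=200, batch_size=64, val_fraction=0.0, seed=0))
        # normalized-scale loss below 1e-4 <=> raw MSE below 1 (%DO)^2
        assert model.training_meta["final_train_loss_normalized"] < 1e-4
        assert predict_baseline(model, X[0]) == pytest.approx(31.5, abs=0.5)

    def test_empty_dataset_rejected(self):
        model = build_model(ModelConfig(hidden_sizes=(8,)), seed=0)
        ds = SyntheticDataset(np.empty((0, 60)), np.empty(0))
        with pytest.raises(ValueError):
            train(model, ds, TrainingConfig())

    def test_shuffled_labels_cannot_generalize(self):
        ds = generate_dataset(1500, seed=13)
        rng = np.random.default_rng(0)
        shuffled = SyntheticDataset(ds.X, rng.permutation(ds.y))
        recognition = BaselineRecognition(shuffled, ModelConfig(hidden_sizes=(64, 32)))
        fit = recognition.fit(TrainingConfig(epochs=30, seed=0))
        assert fit.test_metrics.r2 <= 0.2

    def test_no_gross_overfitting(self, small_fit):
        assert small_fit.train_metrics.r2 >= small_fit.test_metrics.r2 - 0.01

    def test_noise_robustness(self, small_fit):
        """Extra sensor noise of <= 1 %DO degrades test R^2 only marginally."""
        test_set = small_fit.recognition.test_set
        rng = np.random.default_rng(99)
        noisy = SyntheticDataset(
            np.clip(test_set.X + rng.normal(0, 1.0, test_set.X.shape), 0, 100),
            test_set.y,
        )
        noisy_r2 = evaluate(small_fit.model, noisy).r2
        assert noisy_r2 >= small_fit.test_metrics.r2 - 0.01


class TestPredict:
    def test_flat_window_recovered_to_half_percent(self, flat_model):
        """On noise-free flat baselines the recogniser is accurate to 0.5 %DO."""
        model = flat_model.model
        for level in (15.0, 30.0, 55.0):
            window = np.full(60, level)
            assert predict_baseline(model, window) == pytest.approx(level, abs=0.5)
        # mean absolute error over held-out windows whose label is unobscured
        te = flat_model.recognition.test_set
        clean = ~te.spike_at_label
        err = np.abs(model.predict(te.X[clean]) - te.y[clean])
        assert err.mean() <= 0.5

    def test_batch_equals_single(self, small_model):
        X = generate_dataset(20, seed=21).X
        batch = small_model.predict(X)
        singles = np.array([predict_baseline(small_model, row) for row in X])
        # float32 GEMM vs GEMV accumulation differ in the last bits only
        np.testing.assert_allclose(batch, singles, rtol=0, atol=1e-3)

    def test_stateless_predictions(self, small_model):
        w = np.full(60, 42.0)
        first = predict_baseline(small_model, w)
        for _ in range(3):
            predict_baseline(small_model, np.linspace(0, 100, 60))
        assert predict_baseline(small_model, w) == first

    def test_input_validation(self, small_model):
        with pytest.raises(ValueError):
            predict_baseline(small_model, np.zeros(59))
        bad = np.zeros(60)
        bad[10] = np.nan
        with pytest.raises(ValueError):
            predict_baseline(small_model, bad)


class TestEvaluate:
    def test_hand_computed_three_sample_case(self):
        metrics = _metrics_for(labels=[1.0, 2.0, 3.0], preds=[1.0, 2.0, 4.0])
        assert metrics.mse == pytest.approx(1 / 3, abs=1e-12)
        assert metrics.r2 == pytest.approx(0.5, abs=1e-12)

    def test_perfect_and_mean_predictors(self):
        m = _metrics_for([3.0, 5.0, 9.0], [3.0, 5.0, 9.0])
        assert (m.mse, m.r2) == (0.0, 1.0)
        m = _metrics_for([2.0, 4.0, 6.0], [4.0, 4.0, 4.0])
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_labels_flagged(self):
        m = _metrics_for([5.0, 5.0, 5.0], [5.0, 6.0, 4.0])
        assert not m.r2_defined
        assert np.isnan(m.r2)
        assert m.mse == pytest.approx(2 / 3)

    def test_agrees_with_brute_force_on_random_pairs(self):
        """Independent elementwise computation of MSE and R^2 to 1e-10."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            labels = rng.uniform(0, 100, n)
            preds = labels + rng.normal(0, 5, n)
            m = _metrics_for(labels, preds)
            mse_bf = sum((l - p) ** 2 for l, p in zip(labels, preds)) / n
            mean = sum(labels) / n
            ss_tot = sum((l - mean) ** 2 for l in labels)
            ss_res = sum((l - p) ** 2 for l, p in zip(labels, preds))
            assert abs(m.mse - mse_bf) < 1e-10
            assert abs(m.r2 - (1 - ss_res / ss_tot)) < 1e-10


def _metrics_for(labels, preds) -> EvalMetrics:
    """Evaluate via a stub model whose output is forced to ``preds``."""
    labels = np.asarray(labels, dtype=float)
    preds = np.asarray(preds, dtype=float)

    class _Stub:
        def predict(self, X):
            return preds

    from neurostat.mlp import evaluate as _evaluate

    ds = SyntheticDataset(np.zeros((len(labels), 60)), labels)
    return _evaluate(_Stub(), ds)


class TestPersistence:
    def test_round_trip_preserves_predictions(self, small_model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(small_model, path)
        loaded = load_model(path)
        X = generate_dataset(10, seed=5).X
        np.testing.assert_array_equal(loaded.predict(X), small_model.predict(X))
        assert loaded.x_scale == small_model.x_scale

    def test_truncated_file_rejected(self, small_model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(small_model, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError):
            load_model(path)

    def test_garbage_file_rejected(self, tmp_path):
        path = tmp_path / "junk.npz"
        path.write_bytes(b"this is not a checkpoint")
        with pytest.raises(ValueError):
            load_model(path)


def test_forward_pass_matches_sklearn_mlp(small_model):
    """Cross-check the network forward pass against scikit-learn's MLP.

    The trained weights are transplanted into an MLPRegressor; both
    implementations must produce the same normalised outputs.
    """
    sklearn = pytest.importorskip("sklearn.neural_network")
    reg = sklearn.MLPRegressor(
        hidden_layer_sizes=tuple(small_model.config.hidden_sizes),
        activation="relu",
        max_iter=1,
    )
    X = generate_dataset(30, seed=9).X / DO_SCALE
    y = np.zeros(len(X))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reg.fit(X, y)  # only to allocate internals
    reg.coefs_ = [w.astype(float) for w in small_model.weights]
    reg.intercepts_ = [b.astype(float) for b in small_model.biases]
    ours = small_model.predict(X * DO_SCALE) / DO_SCALE
    theirs = reg.predict(X)
    np.testing.assert_allclose(ours, theirs, rtol=0, atol=1e-5)
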