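import numpy as np
import pytest

import semgrec as sg
from semgrec.model import (
    Adam,
    ModelSpec,
    TrainConfig,
    build_model,
    cross_entropy,
    load_checkpoint,
    save_checkpoint,
    softmax,
)

GRAD_SPEC = ModelSpec(
    conv_blocks=((3, 3), (4, 4)),
    gru_units=(5, 4),
    conv_dropout=0.0,
    gru_dropout=0.0,
    n_classes=4,
)


class TestConstruction:
    def test_default_temporal_trace(self):
        assert ModelSpec().temporal_trace(188) == [188, 186, 184, 61, 59, 57]

    def test_too_short_input_raises_with_minimum(self):
        spec = ModelSpec()
        with pytest.raises(ValueError, match=str(spec.min_input_length())):
            build_model(spec, input_length=10)

    def test_min_input_length_is_tight(self):
        spec = ModelSpec()
        n = spec.min_input_length()
        build_model(spec, input_length=n)  # must not raise
        with pytest.raises(ValueError):
            build_model(spec, input_length=n - 1)

    def test_parameter_count_matches_hand_computation(self):
        # conv: (3*8)*64+64, (3*64)*64+64, (3*64)*128+128, (3*128)*128+128
        # gru1 (in 128, H 150): 128*450 + 150*300 + 150*150 + 450
        # gru2 (in 150, H 150): 150*450 + 150*300 + 150*150 + 450
        # head: 150*7 + 7
        expected = (
            (24 * 64 + 64) + (192 * 64 + 64) + (192 * 128 + 128) + (384 * 128 + 128)
            + (128 * 450 + 150 * 300 + 150 * 150 + 450)
            + (150 * 450 + 150 * 300 + 150 * 150 + 450)
            + (150 * 7 + 7)
        )
        assert build_model(ModelSpec(), 188, 8).n_parameters() == expected == 349_993


class TestForward:
    def test_softmax_rows_sum_to_one(self):
        model = build_model(ModelSpec.reduced(), 188, 8, seed=0)
        x = np.random.default_rng(0).integers(-128, 128, size=(5, 188, 8)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (5, 7)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_all_zero_window_is_finite(self):
        model = build_model(ModelSpec.reduced(), 188, 8, seed=0)
        probs = model.predict_proba(np.zeros((1, 188, 8), dtype=np.float32))
        assert np.isfinite(probs).all()

    def test_duplicated_window_gives_identical_rows(self):
        model = build_model(ModelSpec.reduced(), 188, 8, seed=1)
        x = np.random.default_rng(1).integers(-128, 128, size=(1, 188, 8)).astype(np.float32)
        probs = model.predict_proba(np.repeat(x, 3, axis=0))
        assert np.array_equal(probs[0], probs[1]) and np.array_equal(probs[1], probs[2])

    def test_prediction_invariant_to_batch_partitioning(self):
        model = build_model(ModelSpec.reduced(), 188, 8, seed=2)
        x = np.random.default_rng(2).integers(-128, 128, size=(7, 188, 8)).astype(np.float32)
        whole = model.predict_proba(x, batch_size=7)
        split = np.concatenate(
            [model.predict_proba(x[:3], batch_size=3), model.predict_proba(x[3:], batch_size=4)]
        )
        assert np.allclose(whole, split, atol=1e-6)

    def test_two_inference_passes_identical(self):
        model = build_model(ModelSpec.reduced(), 188, 8, seed=3)
        x = np.random.default_rng(3).integers(-128, 128, size=(4, 188, 8)).astype(np.float32)
        assert np.array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_dropout_active_only_in_training_mode(self):
        spec = ModelSpec(conv_blocks=((4, 4), (4, 4)), gru_units=(8,),
                         conv_dropout=0.5, gru_dropout=0.5)
        model = build_model(spec, 40, 8, seed=0)
        x = np.random.default_rng(0).normal(size=(2, 40, 8)).astype(np.float32)
        rng = np.random.default_rng(9)
        a = model.logits(x, train=True, rng=rng)
        b = model.logits(x, train=True, rng=rng)
        assert not np.array_equal(a, b)  # dropout masks differ
        assert np.array_equal(model.logits(x), model.logits(x))

    def test_shape_mismatch_rejected(self):
        model = build_model(ModelSpec.reduced(), 188, 8)
        with pytest.raises(ValueError, match="shape"):
            model.logits(np.zeros((2, 100, 8), dtype=np.float32))


class TestGradients:
    """Backprop checked against central finite differences (float64)."""

    def _loss(self, model, x, y):
        return cross_entropy(softmax(model.logits(x)), y)

    def test_all_parameter_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        model = build_model(GRAD_SPEC, input_length=26, channels=3, seed=0,
                            dtype=np.float64)
        x = rng.normal(scale=1.0, size=(3, 26, 3))
        y = np.eye(4)[rng.integers(0, 4, size=3)]
        # guard: no ReLU pre-activation near its kink, so central differences
        # measure the same linearization the backward pass uses
        model.logits(x)
        for layer in model.layers:
            if hasattr(layer, "_cols"):
                z = layer._cols @ layer.params["W"] + layer.params["b"]
                assert np.abs(z).min() > 1e-4
        probs = softmax(model.logits(x, train=True, rng=rng))
        model.backward((probs - y) / len(x))
        analytic = {key: model.layers[key[0]].grads[key[1]].copy()
                    for key, _ in model.parameters()}
        eps = 1e-6
        for (i, name), arr in model.parameters():
            flat = arr.ravel()
            idx = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for j in idx:
                orig = flat[j]
                flat[j] = orig + eps
                up = self._loss(model, x, y)
                flat[j] = orig - eps
                down = self._loss(model, x, y)
                flat[j] = orig
                numeric = (up - down) / (2 * eps)
                assert analytic[(i, name)].ravel()[j] == pytest.approx(
                    numeric, rel=1e-4, abs=1e-7
                ), f"gradient mismatch at layer {i} param {name}[{j}]"


class TestTraining:
    def test_history_length_matches_epochs(self):
        rng = np.random.default_rng(0)
        x = rng.normal(scale=20, size=(50, 26, 3)).astype(np.float32)
        y = np.eye(4)[rng.integers(0, 4, size=50)]
        model = build_model(GRAD_SPEC, 26, 3, seed=0)
        trained = sg.train(model, x, y, TrainConfig(learning_rate=1e-3, batch_size=16,
                                                    epochs=2, seed=0),
                           validation_fraction=0.2)
        assert len(trained.history["loss"]) == 2
        assert len(trained.history["val_accuracy"]) == 2

    def test_untrained_loss_is_log_k_on_balanced_data(self):
        rng = np.random.default_rng(1)
        x = rng.integers(-128, 128, size=(70, 188, 8)).astype(np.float32)
        y = np.eye(7)[np.repeat(np.arange(7), 10)]
        model = build_model(ModelSpec.reduced(), 188, 8, seed=1)
        loss = cross_entropy(model.predict_proba(x), y)
        assert loss == pytest.approx(np.log(7), rel=0.2)

    def test_learns_linearly_separable_two_gesture_data(self):
        # two "gestures" with disjoint active channel sets, amplitude-coded
        rng = np.random.default_rng(2)
        n = 120
        x = rng.normal(scale=4.0, size=(n, 26, 3)).astype(np.float32)
        labels = rng.integers(0, 2, size=n)
        x[labels == 0, :, 0] *= 10  # class 0: strong channel 0
        x[labels == 1, :, 2] *= 10  # class 1: strong channel 2
        y = np.eye(2)[labels]
        spec = ModelSpec(conv_blocks=((8, 8), (16, 16)), gru_units=(16,),
                         conv_dropout=0.0, gru_dropout=0.0, n_classes=2)
        model = build_model(spec, 26, 3, seed=2)
        trained = sg.train(
            model, x, y,
            TrainConfig(learning_rate=3e-3, batch_size=32, epochs=30, seed=2),
            validation_fraction=0.0,
        )
        assert trained.history["accuracy"][-1] >= 0.95

    def test_empty_training_set_rejected(self):
        model = build_model(GRAD_SPEC, 26, 3)
        with pytest.raises(ValueError, match="empty"):
            sg.train(model, np.zeros((0, 26, 3)), np.zeros((0, 4)),
                     TrainConfig(epochs=1))

    def test_same_seed_reproduces_history(self):
        rng = np.random.default_rng(3)
        x = rng.normal(scale=10, size=(60, 26, 3)).astype(np.float32)
        y = np.eye(4)[rng.integers(0, 4, size=60)]
        cfg = TrainConfig(learning_rate=1e-3, batch_size=16, epochs=3, seed=7)
        h1 = sg.train(build_model(GRAD_SPEC, 26, 3, seed=7), x, y, cfg,
                      validation_fraction=0.2).history
        h2 = sg.train(build_model(GRAD_SPEC, 26, 3, seed=7), x, y, cfg,
                      validation_fraction=0.2).history
        assert h1 == h2


class TestCheckpoint:
    def test_round_trip_preserves_predictions_and_history(self, tmp_path, tiny_trained):
        path = tmp_path / "model.ckpt"
        save_checkpoint(tiny_trained, path)
        back = load_checkpoint(path)
        x = np.random.default_rng(0).integers(-128, 128, size=(4, 188, 8)).astype(np.float32)
        assert np.allclose(back.model.predict_proba(x),
                           tiny_trained.model.predict_proba(x), atol=1e-6)
        assert back.history == tiny_trained.history
        assert back.spec == tiny_trained.spec
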