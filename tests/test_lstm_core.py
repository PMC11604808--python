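"""The stacked-LSTM core: cell recurrence, pooling, BPTT, training contract."""

import numpy as np
import pytest

from seizurecast.lstm_core import (
    GateParameters,
    LstmConfig,
    StackedLstmClassifier,
    lstm_cell_step,
    mse_floor,
    one_hot,
)


class TestCellStep:
    def test_zero_weights_fixed_point(self):
        """All-zero weights: gates sit at 0.5, candidate at 0, so h = C = 0."""
        p = GateParameters(U=np.zeros((3, 8)), W=np.zeros((2, 8)))
        h, c = lstm_cell_step(np.ones(3), np.zeros(2), np.zeros(2), p)
        np.testing.assert_array_equal(h, 0.0)
        np.testing.assert_array_equal(c, 0.0)

    def test_hand_computed_single_unit(self):
        """Unit weights, x=0, h=0, C_prev=1: gates 0.5, candidate 0,
        C = 0.5, h = tanh(0.5) * 0.5."""
        p = GateParameters(U=np.ones((1, 4)), W=np.ones((1, 4)))
        h, c = lstm_cell_step(np.array([0.0]), np.array([0.0]), np.array([1.0]), p)
        assert c == pytest.approx(0.5)
        assert h == pytest.approx(np.tanh(0.5) * 0.5, abs=1e-12)

    def test_state_bounded_with_bounded_inputs(self):
        rng = np.random.default_rng(0)
        p = GateParameters(
            U=rng.normal(size=(2, 12)), W=rng.normal(size=(3, 12))
        )
        h = np.zeros(3)
        c = np.zeros(3)
        for t in range(200):
            h, c = lstm_cell_step(rng.normal(size=2), h, c, p)
            # |C_t| <= f|C_{t-1}| + i|c~| with gates < 1: geometric bound
            assert np.all(np.abs(c) <= 200)
            assert np.all(np.abs(h) <= 1.0)

    def test_batched_training_forward_matches_reference_cell(self):
        """The vectorised layer used in training reproduces the naive
        per-step reference recurrence to well below 1e-5."""
        cfg = LstmConfig(
            layer_units=(6, 4, 3, 3), pool_size=2, n_labels=2,
            recurrent_dropout=0.0, activation="tanh", seed=12,
        )
        model = StackedLstmClassifier(cfg, (10, 3))
        layer = model.layers[0]
        rng = np.random.default_rng(5)
        X = rng.normal(size=(4, 10, 3))
        Hs, _ = model._layer_forward(X, layer)
        h = np.zeros((4, 6))
        c = np.zeros((4, 6))
        for t in range(10):
            h, c = lstm_cell_step(X[:, t], h, c, layer, activation="tanh")
            np.testing.assert_allclose(Hs[:, t], h, atol=1e-5, rtol=0)


class TestBackprop:
    def test_analytic_gradient_matches_directional_derivative(self):
        cfg = LstmConfig(
            layer_units=(5, 4, 3, 3), pool_size=2, n_labels=2,
            recurrent_dropout=0.0, seed=3,
        )
        m = StackedLstmClassifier(cfg, (16, 2))
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 16, 2))
        T = one_hot(np.array([0, 1, 0]), 2)
        _, grads = m._loss_and_grads(X, T, training=False)
        params = m._params()
        dirs = [np.random.default_rng(42 + i).normal(size=p.shape)
                for i, p in enumerate(params)]
        ana = sum(float((g * d).sum()) for g, d in zip(grads, dirs))
        eps = 1e-5
        for p, d in zip(params, dirs):
            p += eps * d
        lp, _ = m._loss_and_grads(X, T, training=False)
        for p, d in zip(params, dirs):
            p -= 2 * eps * d
        lm, _ = m._loss_and_grads(X, T, training=False)
        num = (lp - lm) / (2 * eps)
        assert abs(num - ana) / abs(ana) < 1e-6


class TestPoolingAndStructure:
    def test_pool_invariant_to_permutation_within_windows(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2, 12, 5))
        out, _ = StackedLstmClassifier._pool_forward(X, 4)
        Xp = X.copy()
        for w in range(3):
            perm = rng.permutation(4)
            Xp[:, w * 4 : (w + 1) * 4] = Xp[:, w * 4 + perm]
        outp, _ = StackedLstmClassifier._pool_forward(Xp, 4)
        np.testing.assert_array_equal(out, outp)

    def test_temporal_lengths_down_the_stack(self):
        cfg = LstmConfig(layer_units=(8, 6, 4, 3), pool_size=4, n_labels=2)
        m = StackedLstmClassifier(cfg, (4000, 16))
        assert m.temporal_lengths() == [4000, 1000, 250, 62]

    def test_structure_report_counts(self):
        cfg = LstmConfig(layer_units=(8, 6, 4, 3), pool_size=4, n_labels=4)
        m = StackedLstmClassifier(cfg, (200, 4))
        rep = m.structure_report()
        assert rep["n_lstm_layers"] == 4
        assert rep["n_pool_layers"] == 3
        assert rep["layers"][-1] == {
            "kind": "dense", "units": 4, "activation": "sigmoid",
        }
        seq_flags = [l["return_sequences"] for l in rep["layers"]
                     if l["kind"] == "lstm"]
        assert seq_flags == [True, True, True, False]

    @pytest.mark.parametrize("n_labels", [2, 4, 5])
    def test_output_width_matches_label_count(self, n_labels):
        cfg = LstmConfig(layer_units=(4, 3, 3, 3), pool_size=2, n_labels=n_labels)
        m = StackedLstmClassifier(cfg, (16, 2))
        out = m.predict(np.zeros((3, 16, 2)))
        assert out.shape == (3, n_labels)
        assert ((out >= 0) & (out <= 1)).all()


class TestTrainingContract:
    def _tiny(self, seed=0, epochs=4):
        return LstmConfig(
            layer_units=(4, 3, 3, 3), pool_size=2, n_labels=2,
            learning_rate=1e-2, epochs=epochs, batch_size=8,
            patience=epochs, seed=seed,
        )

    def test_same_seed_same_final_loss(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(24, 16, 2))
        y = rng.integers(0, 2, size=24)
        runs = []
        for _ in range(2):
            m = StackedLstmClassifier(self._tiny(seed=5), (16, 2))
            m.fit(X, y)
            runs.append(m.history["loss"][-1])
        assert runs[0] == runs[1]

    def test_constant_target_converges_to_mse_floor_of_zero(self):
        """All-identical targets carry zero variance, so the loss can fall
        well below the balanced-set floor."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(32, 16, 2))
        y = np.zeros(32, dtype=int)
        m = StackedLstmClassifier(self._tiny(epochs=25), (16, 2))
        m.fit(X, y)
        assert m.history["loss"][-1] < 0.5 * mse_floor(2)

    def test_empty_dataset_rejected(self):
        m = StackedLstmClassifier(self._tiny(), (16, 2))
        with pytest.raises(ValueError, match="empty"):
            m.fit(np.empty((0, 16, 2)), np.empty(0, dtype=int))

    def test_inference_is_deterministic_despite_dropout_config(self):
        cfg = LstmConfig(layer_units=(4, 3, 3, 3), pool_size=2, n_labels=2,
                         recurrent_dropout=0.5, seed=1)
        m = StackedLstmClassifier(cfg, (16, 2))
        x = np.random.default_rng(0).normal(size=(1, 16, 2))
        np.testing.assert_array_equal(m.predict(x), m.predict(x))

    def test_save_load_round_trip(self, tmp_path):
        cfg = self._tiny(seed=9)
        m = StackedLstmClassifier(cfg, (16, 2))
        x = np.random.default_rng(1).normal(size=(2, 16, 2))
        m.save(tmp_path / "m.npz")
        back = StackedLstmClassifier.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(m.predict(x), back.predict(x))
        assert back.checksum() == m.checksum()


def test_config_validation():
    with pytest.raises(ValueError, match="four"):
        LstmConfig(layer_units=(8, 4, 2))
    with pytest.raises(ValueError, match="recurrent_dropout"):
        LstmConfig(recurrent_dropout=1.0)
    with pytest.raises(ValueError, match="n_labels"):
        LstmConfig(n_labels=1)
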