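"""Network estimator: activations, parameter count, training, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hurstnn import (
    FNNArchitecture,
    FNNModel,
    TrainingConfig,
    build_model,
    estimate_m3,
    sigmoid,
    swish,
    theoretical_acvf_vector,
    train,
)


class TestActivations:
    def test_swish_at_zero(self):
        assert swish(0.0) == 0.0

    def test_swish_approaches_identity(self):
        assert abs(swish(20.0) - 20.0) < 1e-6

    def test_swish_at_minus_one(self):
        assert swish(-1.0) == pytest.approx(-1.0 / (1.0 + np.e), abs=1e-12)

    def test_swish_overflow_safe(self):
        assert np.isfinite(swish(np.array([-1e4, 1e4]))).all()

    def test_sigmoid_midpoint(self):
        assert sigmoid(0.0) == 0.5

    @pytest.mark.parametrize("x", [0.1, 1.0, 10.0])
    def test_sigmoid_symmetry(self, x):
        assert sigmoid(-x) + sigmoid(x) == pytest.approx(1.0, abs=1e-15)

    def test_sigmoid_of_log3(self):
        assert sigmoid(np.log(3.0)) == pytest.approx(0.75, abs=1e-12)

    def test_sigmoid_stable_at_large_arguments(self):
        assert sigmoid(700.0) == 1.0
        assert sigmoid(-700.0) == pytest.approx(0.0, abs=1e-300)


class TestArchitecture:
    def test_default_parameter_count(self):
        assert FNNArchitecture().parameter_count() == 8385

    def test_default_count_per_layer_arithmetic(self):
        # 33·64 + 65·64 + 65·32 + 33·1
        assert FNNArchitecture().parameter_count() == 2112 + 4160 + 2080 + 33

    def test_no_hidden_layer_count(self):
        assert FNNArchitecture(input_size=32, hidden_sizes=()).parameter_count() == 33

    @given(
        st.integers(1, 16),
        st.lists(st.integers(1, 16), min_size=0, max_size=4),
    )
    @settings(derandomize=True, max_examples=50)
    def test_count_matches_weight_enumeration(self, input_size, hidden):
        arch = FNNArchitecture(input_size=input_size, hidden_sizes=tuple(hidden))
        model = build_model(arch, seed=0)
        brute = sum(w.size for w in model.weights) + sum(b.size for b in model.biases)
        assert arch.parameter_count() == brute == model.parameter_count()


class TestForwardPass:
    def test_two_unit_toy_network_hand_computed(self):
        """Fixed weights, one input, checked against a hand-evaluated oracle."""
        arch = FNNArchitecture(input_size=2, hidden_sizes=(2,))
        model = build_model(arch, seed=0)
        model.weights[0][:] = np.array([[1.0, -1.0], [0.5, 2.0]])
        model.biases[0][:] = np.array([0.1, -0.2])
        model.weights[1][:] = np.array([[1.5], [-0.7]])
        model.biases[1][:] = np.array([0.3])
        x = np.array([[0.4, -1.2]])

        z1 = np.array([0.4 * 1.0 + (-1.2) * 0.5 + 0.1, 0.4 * (-1.0) + (-1.2) * 2.0 - 0.2])
        a1 = z1 / (1.0 + np.exp(-z1))
        z2 = a1[0] * 1.5 + a1[1] * (-0.7) + 0.3
        expected = 1.0 / (1.0 + np.exp(-z2))
        assert model.predict(x)[0] == pytest.approx(expected, abs=1e-12)

    def test_prediction_range_is_open_unit_interval(self):
        model = build_model(seed=1)
        x = np.random.default_rng(1).uniform(-10, 10, size=(10_000, 32))
        pred = model.predict(x)
        assert np.all((pred > 0.0) & (pred < 1.0))

    def test_batch_order_preserved(self):
        model = build_model(seed=2)
        x = np.random.default_rng(2).standard_normal((5, 32))
        batch = model.predict(x)
        singles = np.array([model.predict(row[None, :])[0] for row in x])
        # BLAS accumulation order differs between batch sizes: ulp tolerance
        assert batch == pytest.approx(singles, rel=1e-12)

    def test_wrong_input_width_rejected(self):
        model = build_model(seed=0)
        with pytest.raises(ValueError):
            model.predict(np.zeros((1, 16)))


@pytest.fixture(scope="module")
def toy_sets():
    """Small in-model training data: exact ACVFs for random H, D = 1."""
    rng = np.random.default_rng(42)

    def make(m):
        hs = rng.uniform(0.02, 0.98, size=m)
        x = np.vstack([theoretical_acvf_vector(31, h).values for h in hs])
        return x, hs

    return make(512), make(128)


class TestTraining:
    def test_constant_target_fits_via_output_bias(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((256, 32))
        y = np.full(256, 0.5)
        model = build_model(seed=0)
        fitted = train(model, (x, y), (x[:64], y[:64]),
                       TrainingConfig(seed=0, max_epochs=50))
        val_mse = float(np.mean((fitted.predict(x) - y) ** 2))
        assert val_mse < 1e-4

    def test_training_is_deterministic(self, toy_sets):
        train_set, val_set = toy_sets
        cfg = TrainingConfig(seed=7, max_epochs=3)
        a = train(build_model(seed=7), train_set, val_set, cfg)
        b = train(build_model(seed=7), train_set, val_set, cfg)
        for wa, wb in zip(a.weights + a.biases, b.weights + b.biases):
            assert np.array_equal(wa, wb)

    def test_learns_noiseless_mapping(self, toy_sets):
        train_set, val_set = toy_sets
        fitted = train(build_model(seed=1), train_set, val_set,
                       TrainingConfig(seed=1, max_epochs=60, early_stop_patience=10))
        mae = float(np.mean(np.abs(fitted.predict(val_set[0]) - val_set[1])))
        assert mae < 0.1

    def test_training_loss_mostly_decreasing(self, toy_sets):
        train_set, val_set = toy_sets
        fitted = train(build_model(seed=3), train_set, val_set,
                       TrainingConfig(seed=3, max_epochs=20, early_stop_patience=20))
        losses = [h["train_mse"] for h in fitted.training_meta["history"]]
        drops = np.sum(np.diff(losses) < 0)
        assert drops / (len(losses) - 1) >= 0.9

    def test_empty_dataset_rejected(self):
        model = build_model(seed=0)
        with pytest.raises(ValueError):
            train(model, (np.empty((0, 32)), np.empty(0)),
                  (np.empty((0, 32)), np.empty(0)), TrainingConfig())

    def test_targets_outside_unit_interval_rejected(self):
        model = build_model(seed=0)
        x = np.zeros((4, 32))
        with pytest.raises(ValueError):
            train(model, (x, np.array([0.2, 0.5, 1.0, 0.3])),
                  (x, np.full(4, 0.5)), TrainingConfig())

    def test_early_stopping_restores_best_epoch(self, toy_sets):
        train_set, val_set = toy_sets
        fitted = train(build_model(seed=5), train_set, val_set,
                       TrainingConfig(seed=5, max_epochs=30))
        meta = fitted.training_meta
        val_mse = float(np.mean((fitted.predict(val_set[0]) - val_set[1]) ** 2))
        assert val_mse == pytest.approx(meta["best_val_mse"], rel=1e-12)
        assert meta["best_epoch"] <= meta["epochs_run"]


class TestEstimateM3:
    def test_output_in_unit_interval(self):
        model = build_model(seed=0)
        est = estimate_m3(np.zeros(32), model)
        assert est.method == "M3"
        assert est.valid
        assert 0.0 < est.hurst_hat < 1.0

    def test_wrong_length_rejected(self):
        model = build_model(seed=0)
        with pytest.raises(ValueError):
            estimate_m3(np.zeros(16), model)

    def test_accepts_acvf_vector(self):
        model = build_model(seed=0)
        est = estimate_m3(theoretical_acvf_vector(31, 0.5), model)
        assert 0.0 < est.hurst_hat < 1.0


class TestSerialization:
    def test_save_load_round_trip_bitwise(self, tmp_path, toy_sets):
        train_set, val_set = toy_sets
        fitted = train(build_model(seed=9), train_set, val_set,
                       TrainingConfig(seed=9, max_epochs=2))
        path = tmp_path / "model.json"
        fitted.save(path)
        loaded = FNNModel.load(path)
        x = np.random.default_rng(0).standard_normal((16, 32))
        assert np.array_equal(fitted.predict(x), loaded.predict(x))
        for a, b in zip(fitted.weights + fitted.biases,
                        loaded.weights + loaded.biases):
            assert np.array_equal(a, b)
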