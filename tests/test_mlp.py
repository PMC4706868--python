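"""Unit tests for the single-hidden-layer perceptron core."""

import json

import numpy as np
import pytest

from ocgapfill.experiments import finite_difference_jacobian
from ocgapfill.mlp import (
    Architecture,
    MLPParams,
    TrainingOptions,
    error_function,
    init_weights,
    load_model,
    mlp_forward,
    mlp_jacobian,
    save_model,
    train_mlp,
)


def make_1_1_1(a0, a1, b0, b1):
    """Tiny 1:1:1 network with explicit weights."""
    return MLPParams(Architecture(1, 1, 1), np.array([[b0, b1]]), np.array([[a0, a1]]))


class TestInitWeights:
    def test_deterministic_given_seed(self):
        arch = Architecture(23, 30, 1)
        w1, w2 = init_weights(arch, seed=1), init_weights(arch, seed=1)
        assert np.array_equal(w1.hidden_weights, w2.hidden_weights)
        assert np.array_equal(w1.output_weights, w2.output_weights)

    def test_distinct_seeds_differ(self):
        arch = Architecture(23, 30, 1)
        w1, w2 = init_weights(arch, seed=1), init_weights(arch, seed=2)
        assert not np.array_equal(w1.hidden_weights, w2.hidden_weights)

    def test_shapes(self):
        p = init_weights(Architecture(1, 1, 1), seed=0)
        assert p.output_weights.shape == (1, 2)
        assert p.hidden_weights.shape == (1, 2)

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, 0, 1), (1, 1, 0), (-3, 2, 1)])
    def test_rejects_nonpositive_counts(self, bad):
        with pytest.raises(ValueError):
            Architecture(*bad)


class TestForward:
    def test_zero_network_outputs_zero(self):
        p = MLPParams(Architecture(3, 4, 2), np.zeros((4, 4)), np.zeros((2, 5)))
        assert np.array_equal(mlp_forward(p, np.ones(3)), np.zeros(2))

    def test_dead_hidden_unit(self):
        # a=(0, 2), b=(0, 0): hidden input is 0 regardless of x
        p = make_1_1_1(0.0, 2.0, 0.0, 0.0)
        assert mlp_forward(p, np.array([5.0]))[0] == 0.0

    def test_hand_evaluated_tanh(self):
        p = make_1_1_1(0.0, 1.0, 0.0, 1.0)
        assert mlp_forward(p, np.array([1.0]))[0] == pytest.approx(np.tanh(1.0), abs=1e-12)

    def test_batch_matches_single(self):
        p = init_weights(Architecture(5, 4, 2), seed=3)
        x = np.random.default_rng(0).normal(size=(7, 5))
        batch = mlp_forward(p, x)
        for i in range(7):
            assert np.allclose(batch[i], mlp_forward(p, x[i]))

    def test_dimension_mismatch_raises(self):
        p = init_weights(Architecture(5, 4, 1), seed=0)
        with pytest.raises(ValueError):
            mlp_forward(p, np.ones(4))

    def test_output_bounded_by_weight_sums(self):
        # tanh is bounded by 1, so |y_q - a_q0| <= sum_j |a_qj| for any input
        rng = np.random.default_rng(11)
        p = init_weights(Architecture(4, 9, 2), seed=5)
        bound = np.abs(p.output_weights[:, 1:]).sum(axis=1)
        for _ in range(50):
            y = mlp_forward(p, rng.normal(scale=100.0, size=4))
            assert np.all(np.abs(y - p.output_weights[:, 0]) <= bound + 1e-12)


class TestJacobian:
    def test_constant_network_zero_jacobian(self):
        p = MLPParams(
            Architecture(3, 2, 1),
            np.random.default_rng(0).normal(size=(2, 4)),
            np.array([[4.2, 0.0, 0.0]]),  # bias only
        )
        assert np.array_equal(mlp_jacobian(p, np.ones(3)), np.zeros((1, 3)))

    def test_unit_slope_at_origin(self):
        p = make_1_1_1(0.0, 1.0, 0.0, 1.0)
        assert mlp_jacobian(p, np.array([0.0]))[0, 0] == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("arch", [(1, 1, 1), (3, 2, 1), (23, 30, 1), (4, 5, 3)])
    def test_matches_finite_differences(self, arch):
        arch = Architecture(*arch)
        rng = np.random.default_rng(hash(arch) % 2**31)
        for trial in range(10):
            p = init_weights(arch, seed=trial)
            x = rng.normal(size=arch.n_inputs)
            dev = np.abs(mlp_jacobian(p, x) - finite_difference_jacobian(p, x))
            assert dev.max() < 1e-6


class TestErrorFunction:
    def test_perfect_network_zero_error(self):
        p = init_weights(Architecture(2, 3, 1), seed=0)
        x = np.random.default_rng(1).normal(size=(10, 2))
        y = mlp_forward(p, x)
        assert error_function(p, x, y) == 0.0

    def test_single_record_unit_residual(self):
        p = MLPParams(Architecture(1, 1, 1), np.zeros((1, 2)), np.zeros((1, 2)))
        assert error_function(p, np.array([[0.0]]), np.array([1.0])) == 1.0

    def test_hand_mean_of_squares(self):
        # zero network, targets equal to the residuals (0.1, -0.3)
        p = MLPParams(Architecture(1, 1, 1), np.zeros((1, 2)), np.zeros((1, 2)))
        e = error_function(p, np.zeros((2, 1)), np.array([0.1, -0.3]))
        assert e == pytest.approx(0.05, abs=1e-15)

    def test_empty_records_raise(self):
        p = init_weights(Architecture(1, 1, 1), seed=0)
        with pytest.raises(ValueError):
            error_function(p, np.empty((0, 1)), np.empty(0))


class TestTraining:
    def test_learns_linear_target(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, size=(2000, 1))
        y = 0.5 * x[:, 0]
        opts = TrainingOptions(max_epochs=300, patience=100, seed=0, batch_size=128)
        _, hist = train_mlp(x[0::2], y[0::2], x[1::2], y[1::2], Architecture(1, 5, 1), opts)
        assert hist.final_test_rmse < 0.01

    def test_pure_noise_is_not_fit(self):
        # target independent of input: early stopping keeps RMSE at ~std(y)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3000, 3))
        y = rng.normal(size=3000)
        opts = TrainingOptions(max_epochs=60, patience=60, seed=0)
        _, hist = train_mlp(x[0::2], y[0::2], x[1::2], y[1::2], Architecture(3, 8, 1), opts)
        assert hist.final_test_rmse >= 0.95 * np.std(y[1::2])

    def test_returned_model_no_worse_than_initial(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(500, 2))
        y = np.tanh(x[:, 0]) + 0.1 * rng.normal(size=500)
        opts = TrainingOptions(max_epochs=20, patience=20, seed=3)
        params, hist = train_mlp(x[0::2], y[0::2], x[1::2], y[1::2], Architecture(2, 4, 1), opts)
        assert hist.test_errors[hist.best_epoch] <= hist.test_errors[0]
        assert error_function(params, x[1::2], y[1::2]) == pytest.approx(
            hist.test_errors[hist.best_epoch]
        )

    def test_seed_determinism_bitwise(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(400, 2))
        y = x[:, 0] * x[:, 1]
        opts = TrainingOptions(max_epochs=15, patience=15, seed=9)
        p1, h1 = train_mlp(x[0::2], y[0::2], x[1::2], y[1::2], Architecture(2, 4, 1), opts)
        p2, h2 = train_mlp(x[0::2], y[0::2], x[1::2], y[1::2], Architecture(2, 4, 1), opts)
        assert np.array_equal(p1.hidden_weights, p2.hidden_weights)
        assert np.array_equal(p1.output_weights, p2.output_weights)
        assert h1.test_errors == h2.test_errors

    def test_target_error_stops_early(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, size=(1000, 1))
        y = 0.3 * x[:, 0]
        opts = TrainingOptions(max_epochs=500, patience=500, seed=0, target_error=1e-3)
        _, hist = train_mlp(x[0::2], y[0::2], x[1::2], y[1::2], Architecture(1, 4, 1), opts)
        assert len(hist.test_errors) - 1 < 500
        assert min(hist.test_errors) <= 1e-3

    def test_invalid_options_rejected(self):
        with pytest.raises(ValueError):
            TrainingOptions(max_epochs=10, patience=20)
        with pytest.raises(ValueError):
            TrainingOptions(learning_rate=0.0)

    def test_empty_train_set_raises(self):
        with pytest.raises(ValueError):
            train_mlp(np.empty((0, 1)), np.empty(0), np.ones((2, 1)), np.ones(2),
                      Architecture(1, 2, 1), TrainingOptions())


class TestSerialization:
    def test_roundtrip_bit_exact(self, tmp_path):
        from ocgapfill.features import fit_standardizer

        p = init_weights(Architecture(3, 4, 2), seed=13)
        std = fit_standardizer(np.random.default_rng(0).normal(size=(20, 3)),
                               np.random.default_rng(1).normal(size=20))
        path = tmp_path / "model.json"
        save_model(path, p, standardizer=std, meta={"note": "test"})
        q, std2, meta = load_model(path)
        assert q.arch == p.arch
        assert np.array_equal(q.hidden_weights, p.hidden_weights)
        assert np.array_equal(q.output_weights, p.output_weights)
        assert np.array_equal(std2.x_mean, std.x_mean)
        assert std2.y_scale == std.y_scale
        assert meta == {"note": "test"}

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text(json.dumps({"format": "something-else"}))
        with pytest.raises(ValueError):
            load_model(path)
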