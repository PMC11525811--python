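"""Loss, backpropagation against finite differences, optimizer behavior, and
the two pruning mechanisms."""

import numpy as np
import pytest

from raybnn.network import forward
from raybnn.training import (
    TrainConfig,
    backprop,
    count_trainable_params,
    delete_connections_probabilistic,
    delete_redundant_neurons,
    loss_mse,
    optimizer_step,
    train,
)

from conftest import make_linear_model, make_random_model
from test_network import W_EXAMPLE


class TestLoss:
    def test_zero_when_equal(self, rng):
        y = rng.standard_normal((3, 2))
        assert loss_mse(y, y) == 0.0

    def test_single_step_value(self):
        assert loss_mse(np.array([[1.0, -1.0]]), np.zeros((1, 2))) == 2.0

    def test_matches_loop_oracle(self, rng):
        yhat = rng.standard_normal((4, 3))
        y = rng.standard_normal((4, 3))
        manual = sum(
            float((yhat[t] - y[t]) @ (yhat[t] - y[t])) for t in range(4)
        ) / 4
        assert loss_mse(yhat, y) == pytest.approx(manual, rel=1e-14)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            loss_mse(np.zeros((2, 2)), np.zeros((2, 3)))


class TestBackprop:
    def test_worked_example_zero_residual(self):
        model = make_linear_model(W_EXAMPLE, n_input=2, n_output=2, k=1)
        x = np.array([[-2.1, 0.3]])
        yhat = forward(model, x)
        j, grads = backprop(model, x, yhat)
        assert j == 0.0
        np.testing.assert_array_equal(grads.dW, 0.0)
        np.testing.assert_array_equal(grads.dH, 0.0)

    def test_worked_example_gradient_value(self):
        # zero target: dJ/dw_{2,0} = 2 * (-2.31) * (-2.1) = 9.702
        model = make_linear_model(W_EXAMPLE, n_input=2, n_output=2, k=1)
        x = np.array([[-2.1, 0.3]])
        _, grads = backprop(model, x, np.zeros((1, 2)))
        w = model.weights
        entry = np.flatnonzero((w.rows == 2) & (w.cols == 0))[0]
        assert grads.dW[entry] == pytest.approx(9.702, rel=1e-12)

    @pytest.mark.parametrize("seed,n,n_input,n_output,k,i_t", [
        (0, 8, 2, 2, 1, 1),
        (1, 10, 3, 2, 2, 2),
        (2, 12, 3, 3, 2, 3),
        (3, 12, 4, 2, 3, 3),
    ])
    def test_matches_finite_differences(self, seed, n, n_input, n_output, k, i_t):
        model = make_random_model(seed, n=n, n_input=n_input, n_output=n_output, k=k)
        rng = np.random.default_rng(seed + 100)
        x = rng.standard_normal((i_t, n_input))
        y = rng.standard_normal((i_t, n_output))
        _, grads = backprop(model, x, y)
        h = 1e-6

        def loss_now():
            return loss_mse(forward(model, x), y)

        for e in range(model.weights.nnz):
            v0 = model.weights.vals[e]
            model.weights.vals[e] = v0 + h
            model.weights.invalidate()
            jp = loss_now()
            model.weights.vals[e] = v0 - h
            model.weights.invalidate()
            jm = loss_now()
            model.weights.vals[e] = v0
            model.weights.invalidate()
            fd = (jp - jm) / (2 * h)
            assert grads.dW[e] == pytest.approx(fd, rel=1e-4, abs=1e-7)
        for i in range(n_input, n):
            v0 = model.H[i]
            model.H[i] = v0 + h
            jp = loss_now()
            model.H[i] = v0 - h
            jm = loss_now()
            model.H[i] = v0
            fd = (jp - jm) / (2 * h)
            assert grads.dH[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)
        for i in range(n):
            for p in range(5):
                v0 = model.uaf.c_eff[i, p]
                model.uaf.c_eff[i, p] = v0 + h
                jp = loss_now()
                model.uaf.c_eff[i, p] = v0 - h
                jm = loss_now()
                model.uaf.c_eff[i, p] = v0
                fd = (jp - jm) / (2 * h)
                assert grads.dC[i, p] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_c_kink_one_sided(self):
        # |C| has a kink at 0; with C slightly off zero the analytic gradient
        # matches the one-sided finite difference
        model = make_random_model(7, n=8, n_input=2, n_output=2, k=1)
        model.uaf.c_eff[:, 2] = 1e-3
        rng = np.random.default_rng(8)
        x = rng.standard_normal((1, 2))
        y = rng.standard_normal((1, 2))
        _, grads = backprop(model, x, y)
        h = 1e-5

        def loss_now():
            return loss_mse(forward(model, x), y)

        for i in range(8):
            v0 = model.uaf.c_eff[i, 2]
            model.uaf.c_eff[i, 2] = v0 + h
            jp = loss_now()
            model.uaf.c_eff[i, 2] = v0
            fd = (jp - loss_now()) / h
            assert grads.dC[i, 2] == pytest.approx(fd, rel=1e-2, abs=1e-6)


class TestOptimizer:
    def test_zero_gradient_no_change(self):
        model = make_random_model(1)
        before = model.weights.vals.copy()
        _, grads = backprop(
            model,
            np.zeros((1, model.n_input)),
            forward(model, np.zeros((1, model.n_input))),
        )
        cfg = TrainConfig(optimizer="sgd", learning_rate=1.0)
        optimizer_step(model, grads, cfg)
        np.testing.assert_array_equal(model.weights.vals, before)

    def test_sgd_single_weight(self):
        from raybnn.training import Gradients

        model = make_random_model(2)
        model.weights.vals[:] = 0.5
        g = Gradients(
            dW=np.zeros(model.weights.nnz), dH=np.zeros(model.n), dC=np.zeros((model.n, 5))
        )
        g.dW[0] = 1.0
        optimizer_step(model, g, TrainConfig(optimizer="sgd", learning_rate=1.0))
        assert model.weights.vals[0] == -0.5
        assert np.all(model.weights.vals[1:] == 0.5)

    def test_adam_trajectory_deterministic(self, rng):
        x = rng.standard_normal((2, 3))
        y = rng.standard_normal((2, 2))
        finals = []
        for _ in range(2):
            model = make_random_model(3, n=10, n_input=3, n_output=2, k=2)
            cfg = TrainConfig(optimizer="adam", learning_rate=0.05, epochs=20)
            train(model, x, y, cfg)
            finals.append(model.weights.vals.copy())
        np.testing.assert_array_equal(finals[0], finals[1])

    def test_structural_zeros_preserved_through_training(self, rng):
        model = make_random_model(4, n=10, n_input=3, n_output=2, k=2)
        x = rng.standard_normal((2, 3))
        y = rng.standard_normal((2, 2))
        cfg = TrainConfig(epochs=30, learning_rate=0.05, prune_every=10,
                          delete_fraction=0.1)
        train(model, x, y, cfg, rng=np.random.default_rng(0))
        assert np.all(model.weights.rows >= model.n_input)
        assert np.all(model.weights.cols < model.n - model.n_output)
        assert np.all(model.H[: model.n_input] == 0.0)


class TestProbabilisticDeletion:
    def test_exact_count(self, rng):
        model = make_random_model(5, n=20, n_input=3, n_output=2, density=0.5)
        nnz0 = model.weights.nnz
        removed = delete_connections_probabilistic(model.weights, 0.05, rng)
        assert len(removed) == int(np.ceil(0.05 * nnz0))
        assert model.weights.nnz == nnz0 - len(removed)

    def test_zero_weights_removed_first(self, rng):
        model = make_random_model(6, n=20, n_input=3, n_output=2, density=0.5)
        zero_entries = np.arange(3)
        model.weights.vals[zero_entries] = 0.0
        zero_pairs = {
            (int(model.weights.rows[e]), int(model.weights.cols[e])) for e in zero_entries
        }
        removed = delete_connections_probabilistic(model.weights, 3 / model.weights.nnz, rng)
        assert {(r, c) for r, c, _ in removed} == zero_pairs

    def test_deletion_probability_nonincreasing_in_magnitude(self):
        # many trials: larger |w| must not be deleted more often than smaller
        vals = np.array([0.01, 0.1, 0.5, 1.0, 2.0])
        counts = np.zeros(len(vals))
        trials = 4000
        master = np.random.default_rng(123)
        for _ in range(trials):
            from raybnn.network import SparseWeights

            w = SparseWeights(8, np.arange(1, 6), np.zeros(5, int), vals.copy())
            removed = delete_connections_probabilistic(w, 0.2, master)
            for r, _, v in removed:
                counts[r - 1] += 1
        p = counts / trials
        assert np.all(np.diff(p) <= 0.03)  # non-increasing up to MC noise
        assert p[0] > p[-1]


class TestRedundantNeurons:
    def test_no_removal_when_all_reach_output(self):
        w = np.zeros((5, 5))
        w[1, 0] = 0.3  # input -> hidden 1
        w[2, 1] = 0.4  # hidden 1 -> hidden 2
        w[4, 2] = 0.5  # hidden 2 -> output 4
        w[4, 3] = 0.1  # hidden 3 -> output 4
        w[3, 0] = 0.2  # input -> hidden 3
        model = make_linear_model(w, n_input=1, n_output=1, k=3)
        removed = delete_redundant_neurons(model)
        assert removed == []

    def test_dead_end_removed_outputs_bitwise_identical(self, rng):
        model = make_random_model(9, n=14, n_input=3, n_output=2, k=2, density=0.5)
        # make hidden slot 5 a dead end: it keeps incoming, loses outgoing
        keep = model.weights.cols != 5
        model.weights.rows = model.weights.rows[keep]
        model.weights.cols = model.weights.cols[keep]
        model.weights.vals = model.weights.vals[keep]
        model.weights.invalidate()
        has_in = np.any(model.weights.rows == 5)
        xs = [rng.standard_normal((3, 3)) for _ in range(10)]
        before = [forward(model, x) for x in xs]
        removed = delete_redundant_neurons(model)
        assert 5 in [int(s) for s in np.flatnonzero(model.slot_cell < 0)] or not has_in or removed
        after = [forward(model, x) for x in xs]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)

    def test_cascade(self):
        # input -> a -> b, b dead-ended: both a and b removed
        w = np.zeros((6, 6))
        w[1, 0] = 0.3  # input -> a
        w[2, 1] = 0.4  # a -> b
        w[5, 0] = 0.2  # input -> output (keeps the graph alive)
        model = make_linear_model(w, n_input=1, n_output=1, k=1)
        removed = delete_redundant_neurons(model)
        # a and b go in cascade; the edge-less hidden slots 3, 4 go too
        assert set(removed) == {1, 2, 3, 4}
        assert model.weights.triples() == {(5, 0, 0.2)}


class TestParameterCount:
    def test_empty(self):
        model = make_linear_model(np.zeros((3, 3)), n_input=2, n_output=1, k=1)
        model.weights.drop(np.arange(model.weights.nnz))
        model.slot_cell[:] = -1
        assert count_trainable_params(model) == 0

    def test_single_connection_single_neuron(self):
        w = np.zeros((2, 2))
        w[1, 0] = 0.5
        model = make_linear_model(w, n_input=1, n_output=1, k=1)
        assert count_trainable_params(model) == 1 + 1 + 5

    def test_decreases_after_deletion(self, rng):
        model = make_random_model(10, n=16, n_input=3, n_output=2, density=0.5)
        before = count_trainable_params(model)
        delete_connections_probabilistic(model.weights, 0.1, rng)
        assert count_trainable_params(model) < before


def test_training_reduces_loss_on_localization_task():
    """Seeded training halves the loss within 200 epochs on the synthetic
    localization task (majority over three seeds)."""
    from raybnn.experiments import prepare_features, synth_localization
    from raybnn.experiments import _build_for

    wins = 0
    for seed in (0, 1, 2):
        data = synth_localization(6, 150, seed=seed)
        x = prepare_features(data.rssi).T[None]
        y = (data.targets / data.arena).T[None]
        model = _build_for(6, 40, 40, 40.0, seed=seed)
        cfg = TrainConfig(epochs=200, learning_rate=0.02)
        log = train(model, x, y, cfg)
        if log[-1]["loss"] <= 0.5 * log[0]["loss"]:
            wins += 1
    assert wins >= 2
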