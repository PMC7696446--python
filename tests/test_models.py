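"""Recurrent forecasters: gradients, capacity, training and persistence."""

import numpy as np
import pytest

from cgmforecast import (FramingSpec, ModelSpec, SampleSet, TrainConfig,
                         ValidationError, build_model, fit_scaler, frame,
                         persistence_baseline, predict, rmse, simulate_trace,
                         train)
from cgmforecast import nn
from cgmforecast.models import load_predictor, save_predictor


def make_samples(inputs, targets, spec=None):
    inputs = np.asarray(inputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    return SampleSet("P", spec or FramingSpec(lookback=inputs.shape[1]),
                     inputs, targets, np.arange(len(targets)) + 100)


def numerical_gradient(net, x, y, param, eps=1e-6):
    grad = np.zeros_like(param)
    it = np.nditer(param, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = param[i]
        param[i] = orig + eps
        up = np.mean((net.forward(x) - y) ** 2)
        param[i] = orig - eps
        down = np.mean((net.forward(x) - y) ** 2)
        param[i] = orig
        grad[i] = (up - down) / (2 * eps)
        it.iternext()
    return grad


class TestGradients:
    @pytest.mark.parametrize("cell", ["simple_rnn", "gru", "lstm"])
    @pytest.mark.parametrize("activation", ["linear", "tanh"])
    @pytest.mark.parametrize("bidirectional,layers", [(False, 1), (False, 2), (True, 1)])
    def test_backprop_matches_numerical_gradient(self, cell, activation,
                                                 bidirectional, layers):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 5, 1))
        y = rng.normal(size=(4, 1))
        spec = ModelSpec(cell=cell, recurrent_layers=layers,
                         bidirectional=bidirectional, recurrent_units=3,
                         recurrent_activation=activation, dense_hidden_units=2,
                         dense_hidden_activation="relu")
        net = build_model(spec, 5, seed=1).network
        net.zero_grads()
        resid = net.forward(x) - y
        net.backward(2.0 * resid / resid.size)
        for layer in net.layers:
            children = ([layer.fwd, layer.bwd] if isinstance(layer, nn.Bidirectional)
                        else [layer])
            for child in children:
                for name, param in child.params.items():
                    num = numerical_gradient(net, x, y, param)
                    scale = max(np.max(np.abs(num)), 1e-8)
                    assert np.max(np.abs(num - child.grads[name])) / scale < 1e-5, \
                        f"{type(child).__name__}.{name}"


class TestCapacity:
    def test_two_layers_have_strictly_more_parameters(self):
        one = build_model(ModelSpec(recurrent_layers=1), 7)
        two = build_model(ModelSpec(recurrent_layers=2), 7)
        assert two.n_params > one.n_params

    @pytest.mark.parametrize("cell,gates", [("simple_rnn", 1), ("gru", 3), ("lstm", 4)])
    def test_parameter_count_closed_form(self, cell, gates):
        units, dense = 32, 16
        uni = build_model(ModelSpec(cell=cell), 7)
        recurrent = gates * (1 * units + units * units + units)
        head = (units * dense + dense) + (dense * 1 + 1)
        assert uni.n_params == recurrent + head

    @pytest.mark.parametrize("cell", ["simple_rnn", "gru", "lstm"])
    def test_bidirectional_doubles_recurrent_parameters(self, cell):
        uni = build_model(ModelSpec(cell=cell), 7)
        bi = build_model(ModelSpec(cell=cell, bidirectional=True), 7)
        units, dense = 32, 16
        uni_head = units * dense + dense + dense + 1
        bi_head = 2 * units * dense + dense + dense + 1
        assert bi.n_params - bi_head == 2 * (uni.n_params - uni_head)

    def test_untrained_output_finite(self):
        pred = build_model(ModelSpec(), 7, seed=0)
        out = pred(np.full((3, 7), 1e3))
        assert np.all(np.isfinite(out))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec(cell="transformer")
        with pytest.raises(ValidationError):
            ModelSpec(recurrent_layers=3)
        with pytest.raises(ValidationError):
            ModelSpec(recurrent_activation="relu")


class TestTraining:
    def test_zero_epochs_is_identity(self):
        pred = build_model(ModelSpec(), 7, seed=0)
        before = {k: v.copy() for k, v in pred.network.get_weights().items()}
        samples = make_samples(np.random.default_rng(0).normal(size=(30, 7)),
                               np.zeros(30))
        _, history = train(pred, samples, TrainConfig(epochs=0))
        assert history == []
        after = pred.network.get_weights()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_loss_decreases_on_learnable_task(self, learnable_params):
        trace = simulate_trace(learnable_params, 3)
        samples = frame(trace, FramingSpec())
        scaler = fit_scaler(np.concatenate([samples.inputs.ravel(), samples.targets]))
        pred = build_model(ModelSpec(), 7, seed=0)
        _, history = train(pred, samples.scaled(scaler), TrainConfig(epochs=5))
        assert history[-1] < history[0]

    def test_fixed_seed_reproduces_loss_history(self, learnable_params):
        trace = simulate_trace(learnable_params, 2)
        samples = frame(trace, FramingSpec())
        scaler = fit_scaler(np.concatenate([samples.inputs.ravel(), samples.targets]))
        histories = []
        for _ in range(2):
            pred = build_model(ModelSpec(), 7, seed=7)
            _, h = train(pred, samples.scaled(scaler),
                         TrainConfig(epochs=3, shuffle=True, seed=7))
            histories.append(h)
        assert histories[0] == histories[1]

    def test_nan_loss_aborts_with_diagnostic(self):
        # a corrupt (non-finite) sample must abort with a helpful message
        inputs = np.ones((40, 7))
        inputs[3, 2] = np.nan
        samples = make_samples(inputs, np.ones(40))
        pred = build_model(ModelSpec(), 7, seed=0)
        with pytest.raises(FloatingPointError, match="scaling"):
            train(pred, samples, TrainConfig(epochs=1))

    def test_adamax_optimizer_trains(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(60, 7))
        samples = make_samples(x, x[:, -1])
        pred = build_model(ModelSpec(), 7, seed=1)
        _, history = train(pred, samples, TrainConfig(optimizer="adamax", epochs=8))
        assert history[-1] < history[0]


class TestPredict:
    def test_empty_sampleset_gives_empty_predictions(self):
        pred = build_model(ModelSpec(), 7)
        empty = SampleSet("P", FramingSpec(), np.empty((0, 7)), np.empty(0),
                          np.empty(0, dtype=np.int64))
        assert predict(pred, empty).size == 0

    def test_shape_mismatch_rejected(self):
        pred = build_model(ModelSpec(), 7)
        bad = make_samples(np.zeros((3, 9)), np.zeros(3),
                           spec=FramingSpec(lookback=9))
        with pytest.raises(ValidationError):
            predict(pred, bad)

    def test_converged_persistence_task_predicts_last_value(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(400, 7))
        samples = make_samples(x, x[:, -1])  # target == last window value
        pred = build_model(ModelSpec(), 7, seed=2)
        train(pred, samples, TrainConfig(epochs=30))
        out = pred(x[:50])
        assert rmse(x[:50, -1] + 3.0, out + 3.0) < 0.1  # shift keeps values positive

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(50, 7))
        samples = make_samples(x, x[:, -1])
        pred = build_model(ModelSpec(cell="lstm", bidirectional=True), 7, seed=4)
        train(pred, samples, TrainConfig(epochs=2))
        path = tmp_path / "model.npz"
        save_predictor(pred, path)
        loaded = load_predictor(path)
        assert np.allclose(pred(x), loaded(x))


class TestPersistenceBaseline:
    def test_prediction_is_window_last_value(self):
        samples = make_samples([[1, 2, 3, 4, 5, 6, 150.0]], [160.0])
        assert persistence_baseline(samples)[0] == 150.0

    def test_zero_error_on_constant_trace(self, flat_trace, default_spec):
        samples = frame(flat_trace, default_spec)
        assert rmse(samples.targets, persistence_baseline(samples)) == 0.0

    def test_sinusoid_error_matches_closed_form(self):
        # persistence on a sinusoid of amplitude A, period P, horizon h has
        # RMSE A*sqrt(2)*|sin(pi*h/P)| over whole periods
        amp, period_min, horizon_min = 35.0, 240.0, 30.0
        # sample over whole periods so the discrete mean of sin^2 is exact
        t = np.arange(0, 4 * period_min, 5.0)
        pred = 200.0 + amp * np.sin(2 * np.pi * t / period_min)
        ref = 200.0 + amp * np.sin(2 * np.pi * (t + horizon_min) / period_min)
        expected = amp * np.sqrt(2.0) * abs(np.sin(np.pi * horizon_min / period_min))
        assert rmse(ref, pred) == pytest.approx(expected, rel=1e-9)
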