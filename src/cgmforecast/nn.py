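"""Minimal numpy recurrent-network engine: forward passes, backprop through
time, and the two optimizers used in the experiments (RMSprop, Adamax).

Only what the glucose forecasters need is implemented: simple RNN / GRU /
LSTM layers (optionally stacked or bidirectional) followed by dense layers,
trained by mini-batch gradient descent on mean-squared error.  Conventions
mirror the common deep-learning-framework ones so architecture descriptions
transfer directly:

* GRU: ``h_t = z*h_{t-1} + (1-z)*\\tilde h`` with sigmoid update/reset gates
  and a configurable candidate activation ("linear" or "tanh").
* LSTM: sigmoid input/forget/output gates; the configurable activation
  applies to the candidate and the cell output.
* "linear" recurrent activation means the candidate/state nonlinearity is
  the identity while the gates stay sigmoid.

Every layer exposes ``params``/``grads`` dicts, ``forward`` (caching what
``backward`` needs) and ``backward`` returning the gradient w.r.t. its
input, so the whole network is checkable against numerical differentiation.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ValidationError

__all__ = ["Dense", "SimpleRNNLayer", "GRULayer", "LSTMLayer",
           "Bidirectional", "RMSprop", "Adamax", "Network"]


# ---------------------------------------------------------------------------
# activations

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "linear":
        return x
    if name == "tanh":
        return np.tanh(x)
    if name == "relu":
        return np.maximum(x, 0.0)
    raise ValidationError(f"unsupported activation {name!r}")


def _act_grad_from_output(name: str, h: np.ndarray) -> np.ndarray:
    """d act(a) / d a expressed through the activation *output* h."""
    if name == "linear":
        return np.ones_like(h)
    if name == "tanh":
        return 1.0 - h * h
    if name == "relu":
        return (h > 0.0).astype(h.dtype)
    raise ValidationError(f"unsupported activation {name!r}")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


# ---------------------------------------------------------------------------
# layers

class Layer:
    """Base layer: named parameters plus matching gradient slots."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Dense(Layer):
    """Fully connected layer ``act(x @ W + b)``."""

    def __init__(self, n_in: int, n_out: int, activation: str = "linear",
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if activation not in ("linear", "relu", "tanh"):
            raise ValidationError(f"unsupported dense activation {activation!r}")
        self.activation = activation
        self.params = {"W": _glorot(rng, n_in, n_out), "b": np.zeros(n_out)}
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._h = _act(self.activation, x @ self.params["W"] + self.params["b"])
        return self._h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        da = dout * _act_grad_from_output(self.activation, self._h)
        self.grads["W"] += self._x.T @ da
        self.grads["b"] += da.sum(axis=0)
        return da @ self.params["W"].T


class RecurrentBase(Layer):
    """Shared plumbing for the recurrent layers.

    ``forward`` takes (batch, timesteps, features); with
    ``return_sequences`` it emits the full state sequence (for stacking),
    otherwise only the final state.
    """

    def __init__(self, n_in: int, units: int, activation: str = "linear",
                 return_sequences: bool = False) -> None:
        super().__init__()
        if activation not in ("linear", "tanh"):
            raise ValidationError(
                f"recurrent activation must be 'linear' or 'tanh', got {activation!r}")
        self.n_in = n_in
        self.units = units
        self.activation = activation
        self.return_sequences = return_sequences

    def forward(self, x: np.ndarray) -> np.ndarray:
        h_seq = self._forward_seq(x)
        return h_seq if self.return_sequences else h_seq[:, -1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.return_sequences:
            d_seq = dout
        else:
            d_seq = np.zeros(self._h_seq_shape)
            d_seq[:, -1] = dout
        return self._backward_seq(d_seq)


class SimpleRNNLayer(RecurrentBase):
    """Elman recurrence ``h_t = act(x_t Wx + h_{t-1} Wh + b)``."""

    def __init__(self, n_in: int, units: int, activation: str = "linear",
                 return_sequences: bool = False,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__(n_in, units, activation, return_sequences)
        rng = rng or np.random.default_rng(0)
        self.params = {
            "Wx": _glorot(rng, n_in, units),
            "Wh": _glorot(rng, units, units),
            "b": np.zeros(units),
        }
        self.zero_grads()

    def _forward_seq(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        U = self.units
        h = np.zeros((B, U))
        hs = np.zeros((B, T, U))
        for t in range(T):
            h = _act(self.activation,
                     x[:, t] @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b"])
            hs[:, t] = h
        self._x, self._hs = x, hs
        self._h_seq_shape = hs.shape
        return hs

    def _backward_seq(self, d_seq: np.ndarray) -> np.ndarray:
        x, hs = self._x, self._hs
        B, T, _ = x.shape
        dx = np.zeros_like(x)
        carry = np.zeros((B, self.units))
        for t in range(T - 1, -1, -1):
            dh = d_seq[:, t] + carry
            da = dh * _act_grad_from_output(self.activation, hs[:, t])
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, self.units))
            self.grads["Wx"] += x[:, t].T @ da
            self.grads["Wh"] += h_prev.T @ da
            self.grads["b"] += da.sum(axis=0)
            dx[:, t] = da @ self.params["Wx"].T
            carry = da @ self.params["Wh"].T
        return dx


class GRULayer(RecurrentBase):
    """Gated recurrent unit with update gate z and reset gate r.

    ``h_t = z*h_{t-1} + (1-z)*act(x W_h + (r*h_{t-1}) U_h + b_h)``.
    """

    def __init__(self, n_in: int, units: int, activation: str = "linear",
                 return_sequences: bool = False,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__(n_in, units, activation, return_sequences)
        rng = rng or np.random.default_rng(0)
        self.params = {}
        for gate in ("z", "r", "h"):
            self.params[f"W{gate}"] = _glorot(rng, n_in, units)
            self.params[f"U{gate}"] = _glorot(rng, units, units)
            self.params[f"b{gate}"] = np.zeros(units)
        self.zero_grads()

    def _forward_seq(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        U = self.units
        p = self.params
        h = np.zeros((B, U))
        hs = np.zeros((B, T, U))
        self._zs = np.zeros((B, T, U))
        self._rs = np.zeros((B, T, U))
        self._gs = np.zeros((B, T, U))
        for t in range(T):
            xt = x[:, t]
            z = _sigmoid(xt @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(xt @ p["Wr"] + h @ p["Ur"] + p["br"])
            g = _act(self.activation, xt @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"])
            h = z * h + (1.0 - z) * g
            self._zs[:, t], self._rs[:, t], self._gs[:, t] = z, r, g
            hs[:, t] = h
        self._x, self._hs = x, hs
        self._h_seq_shape = hs.shape
        return hs

    def _backward_seq(self, d_seq: np.ndarray) -> np.ndarray:
        x, hs = self._x, self._hs
        p, gr = self.params, self.grads
        B, T, _ = x.shape
        U = self.units
        dx = np.zeros_like(x)
        carry = np.zeros((B, U))
        for t in range(T - 1, -1, -1):
            dh = d_seq[:, t] + carry
            z, r, g = self._zs[:, t], self._rs[:, t], self._gs[:, t]
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, U))
            xt = x[:, t]

            dz = dh * (h_prev - g)
            dg = dh * (1.0 - z)
            dh_prev = dh * z

            dag = dg * _act_grad_from_output(self.activation, g)
            gr["Wh"] += xt.T @ dag
            d_rh = dag @ p["Uh"].T
            gr["Uh"] += (r * h_prev).T @ dag
            gr["bh"] += dag.sum(axis=0)
            dr = d_rh * h_prev
            dh_prev = dh_prev + d_rh * r

            dar = dr * r * (1.0 - r)
            daz = dz * z * (1.0 - z)
            gr["Wr"] += xt.T @ dar
            gr["Ur"] += h_prev.T @ dar
            gr["br"] += dar.sum(axis=0)
            gr["Wz"] += xt.T @ daz
            gr["Uz"] += h_prev.T @ daz
            gr["bz"] += daz.sum(axis=0)

            dx[:, t] = dag @ p["Wh"].T + dar @ p["Wr"].T + daz @ p["Wz"].T
            carry = dh_prev + dar @ p["Ur"].T + daz @ p["Uz"].T
        return dx


class LSTMLayer(RecurrentBase):
    """LSTM with input/forget/output gates and a carried cell state."""

    def __init__(self, n_in: int, units: int, activation: str = "linear",
                 return_sequences: bool = False,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__(n_in, units, activation, return_sequences)
        rng = rng or np.random.default_rng(0)
        # gate order along the last axis: i, f, o, g
        self.params = {
            "W": _glorot(rng, n_in, 4 * units),
            "U": _glorot(rng, units, 4 * units),
            "b": np.zeros(4 * units),
        }
        # forget-gate bias 1: standard trick for stable early training
        self.params["b"][units:2 * units] = 1.0
        self.zero_grads()

    def _forward_seq(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        U = self.units
        p = self.params
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        hs = np.zeros((B, T, U))
        self._cs = np.zeros((B, T, U))
        self._gates = np.zeros((B, T, 4 * U))
        self._hcs = np.zeros((B, T, U))
        for t in range(T):
            a = x[:, t] @ p["W"] + h @ p["U"] + p["b"]
            i = _sigmoid(a[:, :U])
            f = _sigmoid(a[:, U:2 * U])
            o = _sigmoid(a[:, 2 * U:3 * U])
            g = _act(self.activation, a[:, 3 * U:])
            c = f * c + i * g
            hc = _act(self.activation, c)
            h = o * hc
            self._gates[:, t] = np.concatenate([i, f, o, g], axis=1)
            self._cs[:, t] = c
            self._hcs[:, t] = hc
            hs[:, t] = h
        self._x, self._hs = x, hs
        self._h_seq_shape = hs.shape
        return hs

    def _backward_seq(self, d_seq: np.ndarray) -> np.ndarray:
        x, hs = self._x, self._hs
        p, gr = self.params, self.grads
        B, T, _ = x.shape
        U = self.units
        dx = np.zeros_like(x)
        carry_h = np.zeros((B, U))
        carry_c = np.zeros((B, U))
        for t in range(T - 1, -1, -1):
            dh = d_seq[:, t] + carry_h
            gates = self._gates[:, t]
            i, f, o, g = gates[:, :U], gates[:, U:2 * U], gates[:, 2 * U:3 * U], gates[:, 3 * U:]
            hc = self._hcs[:, t]
            c_prev = self._cs[:, t - 1] if t > 0 else np.zeros((B, U))
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, U))

            do = dh * hc
            dc = dh * o * _act_grad_from_output(self.activation, hc) + carry_c
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            carry_c = dc * f

            da = np.concatenate(
                [di * i * (1.0 - i), df * f * (1.0 - f),
                 do * o * (1.0 - o), dg * _act_grad_from_output(self.activation, g)],
                axis=1)
            gr["W"] += x[:, t].T @ da
            gr["U"] += h_prev.T @ da
            gr["b"] += da.sum(axis=0)
            dx[:, t] = da @ p["W"].T
            carry_h = da @ p["U"].T
        return dx


class Bidirectional(Layer):
    """Runs a forward and a time-reversed copy of a recurrent layer and
    concatenates their outputs along the feature axis."""

    def __init__(self, fwd: RecurrentBase, bwd: RecurrentBase) -> None:
        super().__init__()
        if fwd.return_sequences != bwd.return_sequences:
            raise ValidationError("both directions must agree on return_sequences")
        self.fwd = fwd
        self.bwd = bwd
        self.return_sequences = fwd.return_sequences

    @property
    def params(self) -> dict[str, np.ndarray]:  # type: ignore[override]
        out = {f"fwd_{k}": v for k, v in self.fwd.params.items()}
        out.update({f"bwd_{k}": v for k, v in self.bwd.params.items()})
        return out

    @params.setter
    def params(self, value) -> None:  # base-class __init__ assigns {}
        if value:
            raise ValidationError("Bidirectional params are owned by its children")

    @property
    def grads(self) -> dict[str, np.ndarray]:  # type: ignore[override]
        out = {f"fwd_{k}": v for k, v in self.fwd.grads.items()}
        out.update({f"bwd_{k}": v for k, v in self.bwd.grads.items()})
        return out

    @grads.setter
    def grads(self, value) -> None:
        if value:
            raise ValidationError("Bidirectional grads are owned by its children")

    def zero_grads(self) -> None:
        self.fwd.zero_grads()
        self.bwd.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        out_f = self.fwd.forward(x)
        out_b = self.bwd.forward(x[:, ::-1])
        if self.return_sequences:
            out_b = out_b[:, ::-1]
        return np.concatenate([out_f, out_b], axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        U = self.fwd.units
        d_f, d_b = dout[..., :U], dout[..., U:]
        if self.return_sequences:
            d_b = d_b[:, ::-1]
        dx = self.fwd.backward(d_f)
        dx = dx + self.bwd.backward(d_b)[:, ::-1]
        return dx


# ---------------------------------------------------------------------------
# optimizers

class Optimizer:
    def __init__(self, learning_rate: float) -> None:
        self.learning_rate = learning_rate
        self._slots: dict[tuple, dict[str, np.ndarray]] = {}

    def _slot(self, key: tuple, like: np.ndarray, names: tuple[str, ...]):
        if key not in self._slots:
            self._slots[key] = {n: np.zeros_like(like) for n in names}
        return self._slots[key]


class RMSprop(Optimizer):
    """RMSprop with the customary defaults (lr 1e-3, rho 0.9)."""

    def __init__(self, learning_rate: float = 1e-3, rho: float = 0.9,
                 epsilon: float = 1e-7) -> None:
        super().__init__(learning_rate)
        self.rho = rho
        self.epsilon = epsilon

    def update(self, key: tuple, param: np.ndarray, grad: np.ndarray) -> None:
        s = self._slot(key, param, ("ms",))
        s["ms"] *= self.rho
        s["ms"] += (1.0 - self.rho) * grad * grad
        param -= self.learning_rate * grad / (np.sqrt(s["ms"]) + self.epsilon)


class Adamax(Optimizer):
    """Adamax (Adam with an infinity-norm second moment)."""

    def __init__(self, learning_rate: float = 1e-3, beta_1: float = 0.9,
                 beta_2: float = 0.999, epsilon: float = 1e-7) -> None:
        super().__init__(learning_rate)
        self.beta_1 = beta_1
        self.beta_2 = beta_2
        self.epsilon = epsilon
        self._t = 0

    def begin_step(self) -> None:
        self._t += 1

    def update(self, key: tuple, param: np.ndarray, grad: np.ndarray) -> None:
        s = self._slot(key, param, ("m", "u"))
        s["m"] *= self.beta_1
        s["m"] += (1.0 - self.beta_1) * grad
        np.maximum(self.beta_2 * s["u"], np.abs(grad), out=s["u"])
        lr_t = self.learning_rate / (1.0 - self.beta_1 ** self._t)
        param -= lr_t * s["m"] / (s["u"] + self.epsilon)


def make_optimizer(name: str, learning_rate: float | None = None) -> Optimizer:
    if name == "rmsprop":
        return RMSprop(learning_rate or 1e-3)
    if name == "adamax":
        return Adamax(learning_rate or 1e-3)
    raise ValidationError(f"unsupported optimizer {name!r}")


# ---------------------------------------------------------------------------
# network

class Network:
    """A stack of layers trained with mini-batch MSE gradient descent.

    Recurrent layers consume (batch, timesteps, features); the first
    non-recurrent (dense) layer receives the final recurrent state.
    """

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    @property
    def n_params(self) -> int:
        return int(sum(layer.n_params for layer in self.layers))

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def train_batch(self, x: np.ndarray, y: np.ndarray, optimizer: Optimizer) -> float:
        """One gradient step on MSE; returns the batch loss."""
        self.zero_grads()
        pred = self.forward(x)
        resid = pred - y.reshape(pred.shape)
        loss = float(np.mean(resid ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                "NaN/inf training loss — check input scaling or lower the learning rate")
        self.backward(2.0 * resid / resid.size)
        if isinstance(optimizer, Adamax):
            optimizer.begin_step()
        for li, layer in enumerate(self.layers):
            children = [layer.fwd, layer.bwd] if isinstance(layer, Bidirectional) else [layer]
            for ci, child in enumerate(children):
                for name, param in child.params.items():
                    optimizer.update((li, ci, name), param, child.grads[name])
        return loss

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        if x.shape[0] == 0:
            return np.empty(0)
        outs = [self.forward(x[i:i + batch_size])
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0).ravel()

    # -- weight (de)serialization -----------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for li, layer in enumerate(self.layers):
            for name, param in layer.params.items():
                out[f"layer{li}/{name}"] = param.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                key = f"layer{li}/{name}"
                src = np.asarray(weights[key])
                if isinstance(layer, Bidirectional):
                    side, pname = name.split("_", 1)
                    child = layer.fwd if side == "fwd" else layer.bwd
                    np.copyto(child.params[pname], src)
                else:
                    np.copyto(layer.params[name], src)
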