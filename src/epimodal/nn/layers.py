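"""Neural network layers on the autodiff core.

Parameters are named, so checkpoints can be saved/loaded as flat dicts and
warm starts can restore a sub-module (e.g. the sequence encoder only) by
name prefix.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: tracks parameters and training mode."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = False

    def register(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + name: t for name, t in self._params.items()}
        for cname, child in self._children.items():
            out.update(child.parameters(prefix=f"{prefix}{cname}."))
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for t in self.parameters().values():
            t.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        params = self.parameters()
        for name, t in params.items():
            key = prefix + name
            if key not in state:
                raise KeyError(f"checkpoint missing parameter {key!r}")
            if state[key].shape != t.data.shape:
                raise ValueError(
                    f"parameter {key!r}: checkpoint shape {state[key].shape} "
                    f"!= model shape {t.data.shape}"
                )
            t.data = np.array(state[key], dtype=np.float64)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.w = self.register("weight", _glorot(rng, (in_dim, out_dim), in_dim, out_dim))
        self.b = self.register("bias", np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.shape[-1] != self.in_dim:
            raise ValueError(
                f"Linear expected last dim {self.in_dim}, got {x.data.shape}"
            )
        return x @ self.w + self.b


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels, self.out_channels, self.kernel_size = in_channels, out_channels, kernel_size
        fan_in = in_channels * kernel_size
        self.w = self.register(
            "weight", _glorot(rng, (out_channels, in_channels, kernel_size), fan_in, out_channels)
        )
        self.b = self.register("bias", np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.ndim != 3 or x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"Conv1d expected (N, {self.in_channels}, L), got {x.data.shape}"
            )
        return ag.conv1d(x, self.w, self.b)


class BiLSTM(Module):
    """Single-layer bidirectional LSTM returning per-step hidden states.

    Input (N, T, D) -> output (N, T, 2*hidden).  Gate order in the stacked
    weight matrices is input, forget, cell, output.
    """

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        self.input_dim, self.hidden_dim = input_dim, hidden_dim
        for direction in ("fw", "bw"):
            self.register(
                f"w_ih_{direction}",
                _glorot(rng, (input_dim, 4 * hidden_dim), input_dim, hidden_dim),
            )
            self.register(
                f"w_hh_{direction}",
                _glorot(rng, (hidden_dim, 4 * hidden_dim), hidden_dim, hidden_dim),
            )
            bias = np.zeros(4 * hidden_dim)
            bias[hidden_dim : 2 * hidden_dim] = 1.0  # forget-gate bias
            self.register(f"b_{direction}", bias)

    def _run(self, x: Tensor, direction: str) -> list[Tensor]:
        N, T, _ = x.data.shape
        H = self.hidden_dim
        w_ih = self._params[f"w_ih_{direction}"]
        w_hh = self._params[f"w_hh_{direction}"]
        b = self._params[f"b_{direction}"]
        h = Tensor(np.zeros((N, H)))
        c = Tensor(np.zeros((N, H)))
        steps = range(T) if direction == "fw" else range(T - 1, -1, -1)
        outputs: dict[int, Tensor] = {}
        for t in steps:
            xt = x[:, t, :]
            gates = xt @ w_ih + h @ w_hh + b
            i = ag.sigmoid(gates[:, 0:H])
            f = ag.sigmoid(gates[:, H : 2 * H])
            g = ag.tanh(gates[:, 2 * H : 3 * H])
            o = ag.sigmoid(gates[:, 3 * H : 4 * H])
            c = f * c + i * g
            h = o * ag.tanh(c)
            outputs[t] = h
        return [outputs[t] for t in range(T)]

    def __call__(self, x: Tensor) -> Tensor:
        fw = self._run(x, "fw")
        bw = self._run(x, "bw")
        per_step = [
            ag.reshape(ag.concat([f, b], axis=1), (x.data.shape[0], 1, 2 * self.hidden_dim))
            for f, b in zip(fw, bw)
        ]
        return ag.concat(per_step, axis=1)


class MLP(Module):
    """Affine+ReLU stack; no activation after the last layer."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        super().__init__()
        self.dims = list(dims)
        self.layers = [
            self.add_child(f"fc{i}", Linear(d_in, d_out, rng))
            for i, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:]))
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = ag.relu(x)
        return x


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
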