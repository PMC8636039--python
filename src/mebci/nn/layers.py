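"""Layers with explicit forward/backward passes.

Tensors are float64 numpy arrays shaped (batch, length, channels) for
temporal layers and (batch, features) for dense layers. Each layer stores
what it needs for the backward pass; ``backward`` returns the gradient with
respect to its input and accumulates parameter gradients in ``grads``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Conv1D",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "Dropout",
    "Flatten",
    "Sequential",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64) -> None:
        super().__init__()
        self.dtype = dtype
        self.params = {
            "W": glorot_uniform(rng, (n_in, n_out), n_in, n_out).astype(dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=self.dtype)
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class Conv1D(Layer):
    """Temporal convolution, stride 1, padding 'same' or 'valid'.

    Implemented by unfolding the input to (batch, out_len, kernel*channels)
    and a single matmul; the backward pass scatters the column gradient back
    with one vectorized slice-add per kernel offset.
    """

    def __init__(self, c_in: int, filters: int, kernel: int,
                 rng: np.random.Generator, padding: str = "same",
                 dtype=np.float64) -> None:
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        self.c_in, self.filters, self.kernel, self.padding = c_in, filters, kernel, padding
        self.dtype = dtype
        fan_in = kernel * c_in
        self.params = {
            "W": glorot_uniform(
                rng, (fan_in, filters), fan_in, kernel * filters
            ).astype(dtype),
            "b": np.zeros(filters, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _pad(self, x):
        if self.padding == "valid":
            return x, 0
        total = self.kernel - 1
        left = total // 2
        return np.pad(x, ((0, 0), (left, total - left), (0, 0))), left

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=self.dtype)
        xp, _ = self._pad(x)
        b, lp, c = xp.shape
        out_len = lp - self.kernel + 1
        s0, s1, s2 = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, shape=(b, out_len, self.kernel, c), strides=(s0, s1, s1, s2)
        ).reshape(b, out_len, self.kernel * c)
        self._cols = cols
        self._in_shape = x.shape
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        dout = np.asarray(dout, dtype=self.dtype)
        b, out_len, _ = dout.shape
        cols2 = self._cols.reshape(-1, self.kernel * self.c_in)
        self.grads["W"] += cols2.T @ dout.reshape(-1, self.filters)
        self.grads["b"] += dout.sum(axis=(0, 1))
        dcols = (dout @ self.params["W"].T).reshape(
            b, out_len, self.kernel, self.c_in
        )
        lp = self._in_shape[1] + (self.kernel - 1 if self.padding == "same" else 0)
        dxp = np.zeros((b, lp, self.c_in), dtype=self.dtype)
        for k in range(self.kernel):
            dxp[:, k: k + out_len, :] += dcols[:, :, k, :]
        if self.padding == "same":
            left = (self.kernel - 1) // 2
            return dxp[:, left: left + self._in_shape[1], :]
        return dxp


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = self.rng.random(x.shape) >= self.rate
        return x * self._mask / (1.0 - self.rate)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask / (1.0 - self.rate)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential:
    """Ordered container with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                out.append((f"{i}:{k}", layer.params[k], layer.grads[k]))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.parameters():
            p[...] = state[name]
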