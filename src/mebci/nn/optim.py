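"""RMSprop with gradient clipping and learning-rate decay; BCE loss."""

from __future__ import annotations

import numpy as np

__all__ = ["RMSprop", "binary_cross_entropy", "bce_grad"]

_EPS = 1e-7


class RMSprop:
    """Keras-style RMSprop: elementwise gradient clipping, inverse-time decay.

    lr_t = lr / (1 + decay * t); accumulator rho defaults to 0.9.
    """

    def __init__(self, lr: float, rho: float = 0.9, clipvalue: float | None = 1.0,
                 decay: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.lr, self.rho, self.clipvalue, self.decay = lr, rho, clipvalue, decay
        self.t = 0
        self._acc: dict[str, np.ndarray] = {}

    def step(self, parameters) -> None:
        lr_t = self.lr / (1.0 + self.decay * self.t)
        self.t += 1
        for name, p, g in parameters:
            if self.clipvalue is not None:
                g = np.clip(g, -self.clipvalue, self.clipvalue)
            acc = self._acc.setdefault(name, np.zeros_like(p))
            acc *= self.rho
            acc += (1.0 - self.rho) * g * g
            p -= lr_t * g / (np.sqrt(acc) + _EPS)


def binary_cross_entropy(pred: np.ndarray, target: np.ndarray) -> float:
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def bce_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d(BCE)/d(pred), averaged over the batch."""
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    return (p - target) / (p * (1.0 - p)) / target.size
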