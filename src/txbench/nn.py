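"""Minimal feed-forward network machinery (numpy, hand-written backprop).

Supports the small architectures used here: dense layers, tanh/relu/selu
activations, SGD with heavy-ball momentum and l2 weight decay.  Gradients
follow the convention that the incoming gradient is d(loss)/d(output) for
the *mean* batch loss, so parameter updates are batch-size independent.
"""

from __future__ import annotations

import numpy as np

SELU_ALPHA = 1.6732632423543772
SELU_SCALE = 1.0507009873554805


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._vW = np.zeros_like(self.W)
        self._vb = np.zeros_like(self.b)
        self._x = None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.W.T

    def step(self, lr: float, momentum: float, weight_decay: float) -> None:
        self._vW = momentum * self._vW - lr * (self.gW + 2.0 * weight_decay * self.W)
        self._vb = momentum * self._vb - lr * self.gb
        self.W += self._vW
        self.b += self._vb

    def l2(self) -> float:
        return float(np.sum(self.W * self.W))

    def state(self):
        return (self.W.copy(), self.b.copy())

    def load(self, state) -> None:
        self.W, self.b = state[0].copy(), state[1].copy()


class Activation:
    def __init__(self, kind: str):
        self.kind = kind
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        if self.kind == "linear":
            return x
        if self.kind == "tanh":
            return np.tanh(x)
        if self.kind == "relu":
            return np.maximum(x, 0.0)
        if self.kind == "selu":
            return SELU_SCALE * np.where(x > 0, x, SELU_ALPHA * np.expm1(x))
        raise ValueError(f"unknown activation {self.kind!r}")

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        if self.kind == "linear":
            return g
        if self.kind == "tanh":
            return g * (1.0 - np.tanh(x) ** 2)
        if self.kind == "relu":
            return g * (x > 0)
        if self.kind == "selu":
            return g * SELU_SCALE * np.where(x > 0, 1.0, SELU_ALPHA * np.exp(x))
        raise ValueError(f"unknown activation {self.kind!r}")

    def step(self, lr, momentum, weight_decay) -> None:  # stateless
        pass

    def l2(self) -> float:
        return 0.0

    def state(self):
        return None

    def load(self, state) -> None:
        pass


class Sequential:
    """A plain layer stack with forward/backward/step over all layers."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def step(self, lr: float, momentum: float, weight_decay: float = 0.0) -> None:
        for layer in self.layers:
            layer.step(lr, momentum, weight_decay)

    def l2(self) -> float:
        return sum(layer.l2() for layer in self.layers)

    def state(self):
        return [layer.state() for layer in self.layers]

    def load(self, state) -> None:
        for layer, s in zip(self.layers, state):
            layer.load(s)


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Seeded random minibatch index iterator over one epoch."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]
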