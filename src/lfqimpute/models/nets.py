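"""Minimal dense neural-network machinery: a leaky-ReLU MLP with hand-written
backpropagation and an Adam optimizer. Everything is plain numpy and fully
deterministic given a seeded Generator, which keeps training reproducible
bit-for-bit on one CPU."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "MLP", "leaky_relu"]

LEAK = 0.01


def leaky_relu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, LEAK * x)


def _leaky_relu_grad(pre: np.ndarray) -> np.ndarray:
    return np.where(pre > 0, 1.0, LEAK)


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class MLP:
    """Fully connected net with leaky-ReLU hidden activations, linear output.

    ``sizes`` gives layer widths input -> ... -> output. ``forward`` caches
    activations for ``backward``, which returns the gradient w.r.t. the input
    and fills ``grads`` (same structure as ``params``).
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 out_bias_init: np.ndarray | None = None):
        self.sizes = list(sizes)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He init suits the leaky-ReLU hidden layers
            w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            self.weights.append(w)
            self.biases.append(np.zeros(fan_out))
        if out_bias_init is not None:
            self.biases[-1][: len(out_bias_init)] = out_bias_init
        self._cache: list[tuple[np.ndarray, np.ndarray]] = []

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        saved = []
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            pre = h @ w + b
            saved.append((h, pre))
            h = pre if i == last else leaky_relu(pre)
        if cache:
            self._cache = saved
        return h

    def backward(self, d_out: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Backprop ``d_out`` (gradient at the linear output) through the net."""
        d_weights: list[np.ndarray] = [np.empty(0)] * len(self.weights)
        d_biases: list[np.ndarray] = [np.empty(0)] * len(self.biases)
        grad = d_out
        last = len(self.weights) - 1
        for i in range(last, -1, -1):
            h_in, pre = self._cache[i]
            if i != last:
                grad = grad * _leaky_relu_grad(pre)
            d_weights[i] = h_in.T @ grad
            d_biases[i] = grad.sum(axis=0)
            grad = grad @ self.weights[i].T
        return grad, [*d_weights, *d_biases]

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_params(self, params: list[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [p.copy() for p in params[:n]]
        self.biases = [p.copy() for p in params[n:]]
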