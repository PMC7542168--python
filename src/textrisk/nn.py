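"""Minimal feed-forward building blocks (numpy, manual backprop).

Only what the risk models need: dense layers with ReLU and inverted
dropout, a stable binary cross-entropy on logits, mean-squared error, and
Adam.  Everything is float64 and seeded, which keeps training trajectories
bit-reproducible and makes finite-difference gradient checks sharp.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "MLPBlock", "Adam", "sigmoid",
           "bce_with_logits", "mse_loss"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray,
                    pos_weight: float | None = None
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    logits = logits.ravel()
    y = y.ravel().astype(float)
    # log(1 + e^z) computed stably as max(z,0) + log1p(e^-|z|)
    softplus = np.maximum(logits, 0.0) + np.log1p(np.exp(-np.abs(logits)))
    per = softplus - y * logits
    p = sigmoid(logits)
    grad = p - y
    if pos_weight is not None:
        w = np.where(y == 1.0, pos_weight, 1.0)
        per = per * w
        # d/dz [-w y log p - (1-y) log(1-p)] = w y (p-1) + (1-y) p
        grad = np.where(y == 1.0, pos_weight * (p - 1.0), p)
    n = len(y)
    return float(per.mean()), (grad / n).reshape(-1, 1)


def mse_loss(pred: np.ndarray, target: np.ndarray
             ) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        if n_in < 1 or n_out < 1:
            raise ValueError("layer widths must be positive")
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ gout
        self.gb += gout.sum(axis=0)
        return gout @ self.W.T


class MLPBlock:
    """Dense stack with ReLU between layers and optional ReLU/dropout on
    hidden activations; the final projection is linear unless
    ``relu_out=True`` (used for the shared trunk, whose output feeds other
    subnetworks as an activation)."""

    def __init__(self, n_in: int, hidden: list[int], n_out: int,
                 rng: np.random.Generator, dropout: float = 0.0,
                 relu_out: bool = False):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        sizes = [n_in] + list(hidden) + [n_out]
        self.layers = [Dense(sizes[i], sizes[i + 1], rng)
                       for i in range(len(sizes) - 1)]
        self.dropout = dropout
        self.relu_out = relu_out
        self._rng = rng
        self._caches: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._caches = []
        h = x
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            z = layer.forward(h)
            if i < last or self.relu_out:
                mask_relu = z > 0
                h = z * mask_relu
                if train and self.dropout > 0.0:
                    keep = (self._rng.random(h.shape) >= self.dropout)
                    h = h * keep / (1.0 - self.dropout)
                    self._caches.append((mask_relu, keep))
                else:
                    self._caches.append((mask_relu, None))
            else:
                h = z
                self._caches.append((None, None))
        return h

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = gout
        for layer, (mask_relu, keep) in zip(reversed(self.layers),
                                            reversed(self._caches)):
            if mask_relu is not None:
                if keep is not None:
                    g = g * keep / (1.0 - self.dropout)
                g = g * mask_relu
            g = layer.backward(g)
        return g

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(p, g) for layer in self.layers
                for p, g in ((layer.W, layer.gW), (layer.b, layer.gb))]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.gW[:] = 0.0
            layer.gb[:] = 0.0


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
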