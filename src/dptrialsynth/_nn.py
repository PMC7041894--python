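"""Minimal fully connected network machinery with hand-written backprop.

Written for small tabular GANs: a few dense layers, explicit caches, and —
the part ordinary autodiff stacks make awkward — vectorized *per-example*
parameter gradients, which DP-SGD needs for per-participant clipping.
Parameters live in per-layer arrays but every consumer addresses them as a
single flat vector, so global-norm clipping and flat optimizer state are
trivial.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "bce_with_logits", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Elementwise binary cross-entropy on logits, numerically stable."""
    logits = np.asarray(logits, dtype=float)
    targets = np.asarray(targets, dtype=float)
    return np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))


_ACTS = {
    "linear": (lambda z: z, lambda z: np.ones_like(z)),
    "relu": (lambda z: np.maximum(z, 0), lambda z: (z > 0).astype(float)),
    "lrelu": (
        lambda z: np.where(z > 0, z, 0.2 * z),
        lambda z: np.where(z > 0, 1.0, 0.2),
    ),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
}


class MLP:
    """Dense feed-forward net: sizes[0] -> ... -> sizes[-1] with named activations."""

    def __init__(self, sizes, activations, rng: np.random.Generator):
        if len(activations) != len(sizes) - 1:
            raise ValueError("need one activation per layer")
        for a in activations:
            if a not in _ACTS:
                raise ValueError(f"unknown activation {a!r}")
        self.sizes = tuple(sizes)
        self.activations = tuple(activations)
        self.Ws: list[np.ndarray] = []
        self.bs: list[np.ndarray] = []
        for fan_in, fan_out, act in zip(sizes[:-1], sizes[1:], activations):
            scale = np.sqrt(2.0 / fan_in) if act in ("relu", "lrelu") else np.sqrt(1.0 / fan_in)
            self.Ws.append(rng.normal(0.0, scale, (fan_in, fan_out)))
            self.bs.append(np.zeros(fan_out))

    # -- parameter vector ---------------------------------------------------

    @property
    def n_params(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.Ws, self.bs))

    def get_flat(self) -> np.ndarray:
        return np.concatenate([a.ravel() for pair in zip(self.Ws, self.bs) for a in pair])

    def set_flat(self, flat: np.ndarray) -> None:
        i = 0
        for layer, (W, b) in enumerate(zip(self.Ws, self.bs)):
            self.Ws[layer] = flat[i : i + W.size].reshape(W.shape).copy()
            i += W.size
            self.bs[layer] = flat[i : i + b.size].copy()
            i += b.size
        if i != flat.size:
            raise ValueError("flat vector size mismatch")

    def copy(self) -> "MLP":
        clone = object.__new__(MLP)
        clone.sizes = self.sizes
        clone.activations = self.activations
        clone.Ws = [W.copy() for W in self.Ws]
        clone.bs = [b.copy() for b in self.bs]
        return clone

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.sizes[0]:
            raise ValueError(f"expected input dim {self.sizes[0]}, got {x.shape[1]}")
        cache = []
        a = x
        for W, b, act in zip(self.Ws, self.bs, self.activations):
            z = a @ W + b
            cache.append((a, z))
            a = _ACTS[act][0](z)
        return (a, cache) if want_cache else a

    def backward(self, cache, delta_out: np.ndarray):
        """Batch-summed parameter gradients (flat) plus the input delta."""
        grads = []
        delta = np.atleast_2d(delta_out)
        for (a_prev, z), W, act in zip(cache[::-1], self.Ws[::-1], self.activations[::-1]):
            dz = delta * _ACTS[act][1](z)
            grads.append((a_prev.T @ dz, dz.sum(axis=0)))
            delta = dz @ W.T
        flat = np.concatenate([g.ravel() for gW, gb in grads[::-1] for g in (gW, gb)])
        return flat, delta

    def per_example_backward(self, cache, delta_out: np.ndarray):
        """Per-example flat parameter gradients, shape (batch, n_params)."""
        delta = np.atleast_2d(delta_out)
        B = delta.shape[0]
        pieces = []
        for (a_prev, z), W, act in zip(cache[::-1], self.Ws[::-1], self.activations[::-1]):
            dz = delta * _ACTS[act][1](z)
            gW = np.einsum("bi,bo->bio", a_prev, dz).reshape(B, -1)
            pieces.append((gW, dz))
            delta = dz @ W.T
        flat = np.concatenate(
            [g for gW, gb in pieces[::-1] for g in (gW, gb)], axis=1
        )
        return flat, delta


class Adam:
    """Adam on a flat parameter vector (beta1 = 0.5 is the usual GAN setting)."""

    def __init__(self, n_params: int, lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n_params)
        self.v = np.zeros(n_params)
        self.t = 0

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad * grad
        m_hat = self.m / (1 - self.beta1**self.t)
        v_hat = self.v / (1 - self.beta2**self.t)
        return params - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
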