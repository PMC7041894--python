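"""Differentially private gradient machinery: per-example clipping, Gaussian
noising of lot sums, and Poisson lot subsampling.

The privacy contract is the clip-and-noise mechanism of DP-SGD: each
participant's gradient contribution is clipped to global L2 norm ``C``
(bounding the influence of any single record), the clipped gradients of a
Poisson-sampled lot are summed, spherical Gaussian noise of scale
``sigma * C`` is added to the sum, and the result is divided by the
expected lot size ``L``.  Poisson sampling (each record independently with
probability ``q = L / n``) is used, not fixed-size shuffling, because the
moments accountant's privacy-amplification analysis assumes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LotSpec", "clip_gradient", "noisy_lot_gradient", "sample_lot"]


@dataclass(frozen=True)
class LotSpec:
    """Sampling geometry of one training run: dataset size and expected lot size."""

    n: int
    L: int

    def __post_init__(self) -> None:
        if self.n <= 0 or self.L <= 0:
            raise ValueError("n and L must be positive")
        if self.L > self.n:
            raise ValueError(f"lot size L={self.L} exceeds dataset size n={self.n}")

    @property
    def q(self) -> float:
        """Per-record sampling rate L/n."""
        return self.L / self.n


def clip_gradient(g: np.ndarray, C: float) -> np.ndarray:
    """Scale ``g`` to L2 norm at most ``C``: returns ``g * min(1, C / ||g||)``.

    ``C = inf`` is permitted (identity); clipping is idempotent.
    """
    if not C > 0:
        raise ValueError("clip norm C must be positive")
    g = np.asarray(g, dtype=float)
    if np.isinf(C):
        return g.copy()
    norm = float(np.linalg.norm(g))
    if norm <= C:
        return g.copy()
    return g * (C / norm)


def noisy_lot_gradient(
    clipped: np.ndarray,
    C: float,
    sigma: float,
    rng: np.random.Generator,
    L: int | None = None,
) -> np.ndarray:
    """Average the lot's clipped gradients with Gaussian noise on the sum.

    Computes ``(sum_i g_i + xi) / L`` with ``xi ~ Normal(0, sigma^2 C^2 I)``.
    Noise is added to the *sum* and then divided by the expected lot size
    ``L`` (default: the number of rows), following the convention under
    which the accountant's (q, sigma) analysis applies.  Inputs must
    already be clipped; an unclipped row is a contract violation.
    """
    clipped = np.atleast_2d(np.asarray(clipped, dtype=float))
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not C > 0:
        raise ValueError("clip norm C must be positive")
    if np.isfinite(C):
        norms = np.linalg.norm(clipped, axis=1)
        if norms.size and norms.max() > C * (1 + 1e-9) + 1e-12:
            raise ValueError(
                f"contract violation: gradient norm {norms.max():.6g} exceeds clip norm {C}"
            )
    if L is None:
        L = clipped.shape[0]
    if L <= 0:
        raise ValueError("L must be positive")
    total = clipped.sum(axis=0)
    if sigma > 0:
        if not np.isfinite(C):
            raise ValueError("noise scale sigma*C requires a finite clip norm")
        total = total + rng.normal(0.0, sigma * C, size=total.shape)
    return total / L


def sample_lot(spec: LotSpec, rng: np.random.Generator) -> np.ndarray:
    """Poisson-sample a lot: each index included independently with probability q.

    Expected lot size is ``spec.L``; the realized size varies, which is
    exactly the sampling model the moments accountant assumes.
    """
    q = spec.q
    if q >= 1.0:
        return np.arange(spec.n)
    mask = rng.random(spec.n) < q
    return np.flatnonzero(mask)
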