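"""(epsilon, delta) bookkeeping for DP-SGD: the moments accountant.

Each noisy lot step is a subsampled Gaussian mechanism with sampling rate
``q`` and noise multiplier ``sigma``.  The accountant tracks, for a grid of
integer moment orders ``lambda``, the accumulated log moments of the
privacy-loss random variable::

    alpha(lambda) = T * alpha_step(lambda)          (additive under composition)

and converts them to (epsilon, delta) statements with the tail bound::

    delta(epsilon) = min_lambda exp(alpha(lambda) - lambda * epsilon)

The per-step moment compares the noise distribution ``mu0 = N(0, sigma^2)``
with the subsampled mixture ``mu = (1 - q) mu0 + q N(1, sigma^2)`` and takes
the larger of the two directed moments::

    I1 = E_{z~mu0}[(mu0(z) / mu(z))^lambda]     (numerical quadrature)
    I2 = E_{z~mu} [(mu(z) / mu0(z))^lambda]     (exact binomial expansion)

``I2`` has a closed form because ``mu/mu0 = (1-q) + q exp((2z-1)/(2 sigma^2))``
and Gaussian moments of ``exp(k z / sigma^2)`` are known; it is evaluated in
log space with log-sum-exp.  In the un-subsampled limit ``q = 1`` both
moments reduce to ``lambda (lambda + 1) / (2 sigma^2)``.

The module also carries two small worked-example calculators translating an
epsilon guarantee into a bound on an adversary's posterior event probability
and on an insurance premium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import integrate
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

__all__ = [
    "InfiniteMomentsError",
    "MomentsLedger",
    "PrivacyBudget",
    "log_moment_step",
    "accumulate",
    "delta_at_epsilon",
    "epsilon_at_delta",
    "compose_budgets",
    "dp_probability_bound",
    "premium_bound",
    "delta_curve",
]

DEFAULT_LAMBDAS = tuple(range(1, 33))


class InfiniteMomentsError(ValueError):
    """sigma = 0 with q > 0 gives unbounded privacy-loss moments."""


def _log_binom(lam: int, k: np.ndarray) -> np.ndarray:
    return gammaln(lam + 1) - gammaln(k + 1) - gammaln(lam - k + 1)


def _log_I2(q: float, sigma: float, lam: int) -> float:
    """Exact log of E_{z~mu}[(mu/mu0)^lambda] via the binomial expansion.

    Expanding ((1-q) + q r)^lambda with r = exp((2z-1)/(2 sigma^2)) and using
    E_{mu0}[r^k] = exp((k^2-k)/(2 sigma^2)),
    E_{mu1}[r^k] = exp((k^2+k)/(2 sigma^2)).
    """
    k = np.arange(lam + 1, dtype=float)
    with np.errstate(divide="ignore"):
        log_q = np.log(q) if q > 0 else -np.inf
        log_1q = np.log1p(-q) if q < 1 else -np.inf
    base = _log_binom(lam, k)
    # term from the (1-q) mu0 mixture component, and from the q mu1 component
    with np.errstate(invalid="ignore"):
        t_a = base + (lam - k + 1) * log_1q + k * log_q + (k * k - k) / (2 * sigma**2)
        t_b = base + (lam - k) * log_1q + (k + 1) * log_q + (k * k + k) / (2 * sigma**2)
    # 0 * (-inf) from q in {0,1} must read as 0, not nan
    t_a = np.where(np.isnan(t_a), -np.inf, t_a)
    t_b = np.where(np.isnan(t_b), -np.inf, t_b)
    if q == 0:
        t_a[0] = 0.0
    if q == 1:
        t_b[-1] = (lam * lam + lam) / (2 * sigma**2)
    return float(logsumexp(np.concatenate([t_a, t_b])))


def _log_I1(q: float, sigma: float, lam: int) -> float:
    """log of E_{z~mu0}[(mu0/mu)^lambda] by adaptive quadrature."""
    if q == 0:
        return 0.0
    if q == 1:
        return lam * (lam + 1) / (2 * sigma**2)

    def integrand(z: float) -> float:
        log_ratio = -math.log((1 - q) + q * math.exp((2 * z - 1) / (2 * sigma**2)))
        return norm.pdf(z, scale=sigma) * math.exp(lam * log_ratio)

    # integrand is a Gaussian times a bounded-ish ratio; 40 sigma covers the mass
    span = 40.0 * sigma + 2.0
    val, _ = integrate.quad(integrand, -span, span, points=[0.0, 1.0], limit=200)
    return math.log(max(val, np.finfo(float).tiny))


def log_moment_step(q: float, sigma: float, lam: int) -> float:
    """Per-step log moment alpha_step(lambda) for the subsampled Gaussian."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    if sigma <= 0:
        if q == 0:
            return 0.0
        raise InfiniteMomentsError("sigma = 0 with q > 0: privacy-loss moments are infinite")
    if lam < 1:
        raise ValueError("moment order lambda must be >= 1")
    return max(_log_I1(q, sigma, lam), _log_I2(q, sigma, lam))


@dataclass(frozen=True)
class MomentsLedger:
    """Accountant state: (q, sigma), steps taken, accumulated log moments."""

    q: float
    sigma: float
    steps: int = 0
    lambdas: tuple[int, ...] = DEFAULT_LAMBDAS
    log_moments: tuple[float, ...] | None = None
    step_moments: tuple[float, ...] | None = None
    tracks_moments: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must be in [0, 1]")
        if self.steps < 0:
            raise ValueError("steps must be non-negative")
        if self.tracks_moments and self.step_moments is None:
            per_step = tuple(log_moment_step(self.q, self.sigma, lam) for lam in self.lambdas)
            object.__setattr__(self, "step_moments", per_step)
        if self.log_moments is None:
            zeros = tuple(0.0 for _ in self.lambdas)
            object.__setattr__(self, "log_moments", zeros)
        if len(self.log_moments) != len(self.lambdas):
            raise ValueError("log_moments length must match lambdas")

    # -- constructors -------------------------------------------------------

    @classmethod
    def create(
        cls, q: float, sigma: float, lambdas: Iterable[int] = DEFAULT_LAMBDAS
    ) -> "MomentsLedger":
        """Fresh ledger for a (q, sigma) mechanism; raises if sigma = 0 with q > 0."""
        if sigma <= 0 and q > 0:
            raise InfiniteMomentsError(
                "sigma = 0 with q > 0: privacy-loss moments are infinite"
            )
        return cls(q=q, sigma=sigma, lambdas=tuple(lambdas))

    @classmethod
    def nonprivate(cls, q: float = 1.0) -> "MomentsLedger":
        """Step-counting ledger for a nonprivate run: no moments, epsilon = inf."""
        return cls(q=q, sigma=0.0, tracks_moments=False)

    # -- queries ------------------------------------------------------------

    @property
    def epsilon_is_infinite(self) -> bool:
        return not self.tracks_moments and self.steps > 0


def accumulate(ledger: MomentsLedger, steps: int) -> MomentsLedger:
    """Advance the ledger by ``steps`` mechanism invocations (log moments add)."""
    if steps < 0:
        raise ValueError("steps must be non-negative")
    if steps == 0:
        return ledger
    if not ledger.tracks_moments:
        return replace(ledger, steps=ledger.steps + steps)
    if ledger.sigma <= 0 and ledger.q > 0:
        raise InfiniteMomentsError("sigma = 0 with q > 0: privacy-loss moments are infinite")
    new_moments = tuple(
        m + steps * s for m, s in zip(ledger.log_moments, ledger.step_moments)
    )
    return replace(ledger, steps=ledger.steps + steps, log_moments=new_moments)


def delta_at_epsilon(ledger: MomentsLedger, epsilon: float) -> float:
    """Tail bound delta(epsilon) = min_lambda exp(alpha(lambda) - lambda*epsilon).

    A ledger with zero steps has accessed no data: delta = 0 for any
    epsilon >= 0.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if ledger.steps == 0:
        return 0.0
    if not ledger.tracks_moments:
        return 1.0
    exponents = [a - lam * epsilon for a, lam in zip(ledger.log_moments, ledger.lambdas)]
    return float(min(1.0, math.exp(min(exponents))))


def epsilon_at_delta(ledger: MomentsLedger, delta: float, tol: float = 1e-4) -> float:
    """Smallest epsilon with delta_at_epsilon(ledger, epsilon) <= delta (bisection)."""
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    if ledger.steps == 0:
        return 0.0
    if not ledger.tracks_moments:
        return math.inf
    if delta_at_epsilon(ledger, 0.0) <= delta:
        return 0.0
    hi = 1.0
    while delta_at_epsilon(ledger, hi) > delta:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError(f"delta = {delta} unreachable under the moment tail bound")
    lo = hi / 2.0 if hi > 1.0 else 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if delta_at_epsilon(ledger, mid) <= delta:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# Budgets


@dataclass(frozen=True)
class PrivacyBudget:
    """An (epsilon, delta) differential-privacy guarantee."""

    epsilon: float
    delta: float

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")


def compose_budgets(budgets: Sequence[PrivacyBudget]) -> PrivacyBudget:
    """Basic composition: component-wise sums of (epsilon, delta)."""
    if not budgets:
        raise ValueError("budget list must be non-empty")
    return PrivacyBudget(
        epsilon=float(sum(b.epsilon for b in budgets)),
        delta=min(1.0, float(sum(b.delta for b in budgets))),
    )


# ---------------------------------------------------------------------------
# Worked-example bound calculators


def dp_probability_bound(prior: float, epsilon: float, exact: bool = False) -> float:
    """Bound an adversary's updated event-probability estimate after an
    epsilon-DP release.

    Default is the linearized convention ``min(1, prior * (1 + epsilon))``
    (a small-epsilon reading of the exp(epsilon) factor, which makes the
    customary back-of-envelope arithmetic exact); ``exact=True`` uses
    ``min(1, prior * exp(epsilon))``.
    """
    if not 0.0 <= prior <= 1.0:
        raise ValueError("prior must be a probability")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    factor = math.exp(epsilon) if exact else (1.0 + epsilon)
    return min(1.0, prior * factor)


def premium_bound(base_premium: float, event_cost: float, event_probability: float) -> float:
    """Premium upper bound: base plus the bounded expected event cost."""
    if min(base_premium, event_cost) < 0 or not 0.0 <= event_probability <= 1.0:
        raise ValueError("inputs must be non-negative; probability in [0, 1]")
    return base_premium + event_cost * event_probability


# ---------------------------------------------------------------------------
# Privacy-spend curves


def delta_curve(
    q: float,
    sigma: float,
    lots_per_epoch: int,
    epochs: int,
    epsilons: Sequence[float] = (0.5, 1.0, 2.0, 3.5),
) -> "np.ndarray":
    """delta as a function of epoch for several epsilon values.

    Returns an array of shape ``(epochs, 1 + len(epsilons))`` whose first
    column is the epoch index (1-based) and remaining columns are
    delta(epsilon) after that many epochs of training.
    """
    base = MomentsLedger.create(q, sigma)
    out = np.empty((epochs, 1 + len(epsilons)))
    ledger = base
    for e in range(1, epochs + 1):
        ledger = accumulate(ledger, lots_per_epoch)
        out[e - 1, 0] = e
        for j, eps in enumerate(epsilons):
            out[e - 1, 1 + j] = delta_at_epsilon(ledger, eps)
    return out
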