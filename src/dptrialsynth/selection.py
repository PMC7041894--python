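"""Differentially private selection of generator checkpoints across epochs.

A single GAN run yields many generator snapshots of varying quality.
Rather than privately tuning on one, k checkpoints are chosen by the
exponential mechanism — each draw an (epsilon, 0) release with probability
proportional to exp(epsilon * utility / (2 * sensitivity)) — and synthetic
data is pooled across the selected generators.  With the default
epsilon = 0.05 per draw and k = 10 the selection stage costs (0.5, 0),
which composes with the training ledger's budget by plain addition.

The only real-data touchpoint is the bounded utility scorer; everything
else operates on synthetic samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .accountant import PrivacyBudget
from .acgan import Checkpoint, generate
from .cohort import Cohort, normalize

__all__ = [
    "SelectionConfig",
    "arm_classification_utility",
    "score_checkpoints",
    "select_models",
    "selection_budget",
    "pool_generate",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Private model-selection parameters.

    ``utility_sensitivity`` is the worst-case change in the utility when one
    training participant is replaced; for an accuracy-style score evaluated
    on n_train real records it is 1/n_train.
    """

    k: int = 10
    epsilon_per_selection: float = 0.05
    utility_sensitivity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.epsilon_per_selection <= 0:
            raise ValueError("epsilon_per_selection must be positive")
        if self.utility_sensitivity <= 0:
            raise ValueError("utility_sensitivity must be positive")


def arm_classification_utility(
    synthetic: Cohort, real: Cohort, seed: int = 0
) -> float:
    """Default checkpoint utility: arm-classification agreement in [0, 1].

    Trains a lightweight logistic regression on the checkpoint's synthetic
    cohort and scores its arm-label accuracy on the real training cohort.
    Replacing one real participant moves the score by at most 1/n_real, so
    the utility's sensitivity is 1/n_real.
    """
    y_syn = synthetic.arms
    if len(np.unique(y_syn)) < 2:
        return 0.5  # degenerate single-arm synthetic data carries no signal
    clf = LogisticRegression(max_iter=500, random_state=seed)
    clf.fit(normalize(synthetic), y_syn)
    return float(clf.score(normalize(real), real.arms))


def score_checkpoints(
    checkpoints: Sequence[Checkpoint],
    real: Cohort,
    scorer: Callable[[Cohort, Cohort], float] = arm_classification_utility,
    n_synthetic: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Bounded utility per checkpoint; deterministic given seeds."""
    utilities = np.empty(len(checkpoints))
    for i, ckpt in enumerate(checkpoints):
        synthetic = generate(ckpt.generator, n_synthetic, arm_mix=0.5, seed=seed,
                             schema=real.schema)
        u = float(scorer(synthetic, real))
        if not 0.0 <= u <= 1.0:
            raise ValueError(
                f"utility {u} outside [0, 1]; sensitivity control requires a bounded score"
            )
        utilities[i] = u
    return utilities


def select_models(
    utilities: np.ndarray,
    config: SelectionConfig,
    rng: np.random.Generator,
) -> list[int]:
    """Draw k checkpoint indices without replacement via the exponential mechanism.

    Each draw selects index i with probability proportional to
    exp(epsilon * u_i / (2 * sensitivity)) among the remaining candidates,
    at (epsilon_per_selection, 0) privacy cost per draw.
    """
    utilities = np.asarray(utilities, dtype=float)
    if config.k > utilities.size:
        raise ValueError(f"k={config.k} exceeds number of checkpoints {utilities.size}")
    scores = config.epsilon_per_selection * utilities / (2.0 * config.utility_sensitivity)
    remaining = list(range(utilities.size))
    chosen: list[int] = []
    for _ in range(config.k):
        s = scores[remaining]
        w = np.exp(s - s.max())
        p = w / w.sum()
        pick = rng.choice(len(remaining), p=p)
        chosen.append(remaining.pop(int(pick)))
    return chosen


def selection_budget(config: SelectionConfig) -> PrivacyBudget:
    """Total selection cost under basic composition: (k * epsilon, 0)."""
    return PrivacyBudget(epsilon=config.k * config.epsilon_per_selection, delta=0.0)


def pool_generate(
    checkpoints: Sequence[Checkpoint],
    n_total: int,
    arm_mix: float = 0.5,
    seed: int = 0,
) -> Cohort:
    """Generate ``n_total`` records split as evenly as possible across checkpoints.

    The first ``n_total mod k`` checkpoints contribute one extra record.
    Pure post-processing: no ledger access.
    """
    if not checkpoints:
        raise ValueError("at least one selected checkpoint is required")
    k = len(checkpoints)
    base, extra = divmod(n_total, k)
    counts = [base + (1 if i < extra else 0) for i in range(k)]
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]
    parts = []
    schema = None
    for i, (ckpt, m) in enumerate(zip(checkpoints, counts)):
        if m == 0:
            continue
        cohort = generate(ckpt.generator, m, arm_mix=arm_mix, seed=seeds[i])
        schema = cohort.schema
        parts.append(cohort)
    records = []
    for i, part in enumerate(parts):
        for r in part.records:
            records.append(
                type(r)(f"pool{i:02d}-{r.id}", r.arm, r.values, r.visit_labels)
            )
    from .cohort import Cohort as _Cohort

    return _Cohort(tuple(records), schema)
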