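"""Synthetic-data generators for a two-arm blood-pressure trial and an EHR vitals table.

These fixtures stand in for access-restricted sources.  ``simulate_trial``
emulates the statistical structure of an intensive-vs-standard systolic
blood-pressure trial: arm-specific treatment targets, physician medication
titration when a participant is above goal, mean-reverting trajectories and
measurement noise — which together produce the time-decaying cross-visit
correlation seen in real trial data.  ``simulate_ehr`` emulates a
critical-care vitals table (9 variables, >= 5 timepoints for most patients)
with a binary heart-failure label.

All numeric defaults are declared fixture constants, not estimates of any
real trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import (
    ARMS,
    DEFAULT_SCHEMA,
    Cohort,
    CohortSchema,
    EventTable,
    cohort_from_arrays,
)

__all__ = ["TrialSimParams", "simulate_trial", "EHR_VARIABLES", "HF_CODES", "simulate_ehr"]

#: Goal thresholds triggering medication titration, mmHg (intensive <120, standard <140).
TITRATION_GOALS = {"standard": 140.0, "intensive": 120.0}


@dataclass(frozen=True)
class TrialSimParams:
    """Generative parameters for the two-arm trial fixture.

    The physician titrates (adds a medication with probability
    ``p_add_med``) whenever the observed SBP is above the arm's *goal*
    (120/140 mmHg), while the underlying trajectory mean-reverts at rate
    ``reversion_rate`` toward the arm's *treatment target*
    (``arm_targets``, default 120/135) — slightly below goal, so
    above-goal titration events keep occurring at a controllable rate.
    """

    n_participants: int = 6000
    p_intensive: float = 0.5
    baseline_sbp_mean: float = 140.0  # mmHg
    baseline_sbp_sd: float = 15.0
    arm_targets: Mapping[str, float] = field(
        default_factory=lambda: {"standard": 135.0, "intensive": 120.0}
    )
    reversion_rate: float = 0.35  # per-visit pull toward target, in (0, 1]
    measurement_noise_sd: float = 6.0  # mmHg
    p_add_med: float = 0.30
    dbp_slope: float = 0.45  # DBP = slope * SBP + intercept + noise
    dbp_intercept: float = 15.0  # mmHg
    dbp_noise_sd: float = 5.0
    med0_mean: float = 1.8  # Poisson mean of the baseline medication count
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_intensive <= 1.0:
            raise ValueError("p_intensive must be in [0, 1]")
        if not 0.0 <= self.p_add_med <= 1.0:
            raise ValueError("p_add_med must be in [0, 1]")
        if not 0.0 <= self.reversion_rate <= 1.0:
            raise ValueError("reversion_rate must be in [0, 1]")
        if min(self.baseline_sbp_sd, self.measurement_noise_sd, self.dbp_noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Draw by redrawing out-of-bound samples (bounds are several sds wide)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_trial(params: TrialSimParams, schema: CohortSchema = DEFAULT_SCHEMA) -> Cohort:
    """Simulate a complete two-arm trial cohort; deterministic for a fixed seed.

    Per participant: arm ~ Bernoulli(p_intensive); baseline SBP ~ Normal
    truncated to [90, 200]; baseline medications ~ Poisson truncated to
    [0, 6].  Per visit transition, a medication is added with probability
    ``p_add_med`` if SBP is above the arm goal (capped at 10), and SBP
    mean-reverts toward the arm target with Gaussian innovation noise.
    DBP is a linear function of concurrent SBP plus noise.
    """
    rng = np.random.default_rng(params.seed)
    n, n_visits = params.n_participants, schema.n_visits

    arm_idx = (rng.random(n) < params.p_intensive).astype(int)
    arm_names = [ARMS[a] for a in arm_idx]
    goals = np.array([TITRATION_GOALS[a] for a in arm_names])
    targets = np.array([params.arm_targets[a] for a in arm_names])

    sbp = np.empty((n, n_visits))
    meds = np.empty((n, n_visits))
    sbp[:, 0] = _truncated_normal(
        rng, params.baseline_sbp_mean, params.baseline_sbp_sd, 90.0, 200.0, n
    )
    meds[:, 0] = np.minimum(rng.poisson(params.med0_mean, n), 6)

    kappa = params.reversion_rate
    for t in range(n_visits - 1):
        above = sbp[:, t] > goals
        add = above & (rng.random(n) < params.p_add_med)
        meds[:, t + 1] = np.minimum(meds[:, t] + add, 10)
        noise = rng.normal(0.0, params.measurement_noise_sd, n)
        sbp[:, t + 1] = sbp[:, t] + kappa * (targets - sbp[:, t]) + noise

    dbp = params.dbp_slope * sbp + params.dbp_intercept + rng.normal(
        0.0, params.dbp_noise_sd, (n, n_visits)
    )

    values = np.stack([sbp, dbp, meds], axis=2)  # (n, visits, [SBP, DBP, MED])
    ids = [f"sim-{i:05d}" for i in range(n)]
    return cohort_from_arrays(values, arm_idx, schema, ids)


# ---------------------------------------------------------------------------
# EHR vitals fixture

#: Nine critical-care vital-sign variables: (name, control mean, within-patient sd).
EHR_VARIABLES = (
    ("map_arterial", 85.0, 10.0),
    ("sbp_arterial", 120.0, 14.0),
    ("dbp_arterial", 62.0, 10.0),
    ("heart_rate", 86.0, 12.0),
    ("resp_rate", 18.0, 4.0),
    ("spo2", 96.5, 2.0),
    ("map_noninvasive", 84.0, 10.0),
    ("sbp_mean", 119.0, 13.0),
    ("dbp_mean", 61.0, 9.0),
)

#: Heart-failure ICD-9 codes used to label simulated cases.
HF_CODES = (
    "402.01", "402.11", "402.91", "404.01", "404.03", "404.11", "404.13",
    "404.91", "404.93", "428", "281.1", "428.20", "428.21", "428.22",
    "428.23", "428.30", "428.31", "428.32", "428.33", "428.40", "428.41",
    "428.42", "428.43", "428.9",
)

#: Non-qualifying comparison codes assigned to simulated controls.
_CONTROL_CODES = ("401.9", "250.00", "272.4", "414.01")


def simulate_ehr(
    n_patients: int,
    p_case: float,
    effect_size: float = 0.5,
    seed: int = 0,
    p_complete: float = 0.9,
    min_timepoints: int = 5,
    max_timepoints: int = 8,
) -> tuple[EventTable, pd.Series]:
    """Simulate a long-format vitals table with a heart-failure case label.

    Cases (probability ``p_case``) have each vital shifted by
    ``effect_size`` within-patient standard deviations.  A fraction
    ``1 - p_complete`` of patients receive fewer than ``min_timepoints``
    measurements and are therefore dropped by the complete-case rule of
    :func:`~dptrialsynth.cohort.first_k_measurements`.  Cases carry one
    heart-failure ICD-9 code; controls carry a non-qualifying code.
    Returns the event table and the generating case labels (all patients).
    """
    if not 0.0 <= p_case <= 1.0:
        raise ValueError("p_case must be in [0, 1]")
    if not 0.0 <= p_complete <= 1.0:
        raise ValueError("p_complete must be in [0, 1]")
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")

    rng = np.random.default_rng(seed)
    case = (rng.random(n_patients) < p_case).astype(int)
    complete = rng.random(n_patients) < p_complete

    rows: dict[str, list] = {"patient_id": [], "variable": [], "time": [], "value": []}
    dx: dict[str, list] = {"patient_id": [], "code": []}
    pids = [f"pt-{i:06d}" for i in range(n_patients)]
    for i, pid in enumerate(pids):
        n_t = (
            int(rng.integers(min_timepoints, max_timepoints + 1))
            if complete[i]
            else int(rng.integers(1, min_timepoints))
        )
        for name, mu, sd in EHR_VARIABLES:
            level = mu + case[i] * effect_size * sd + rng.normal(0.0, 0.6 * sd)
            vals = level + rng.normal(0.0, 0.5 * sd, n_t)
            rows["patient_id"].extend([pid] * n_t)
            rows["variable"].extend([name] * n_t)
            rows["time"].extend(range(n_t))
            rows["value"].extend(vals)
        dx["patient_id"].append(pid)
        dx["code"].append(
            str(rng.choice(HF_CODES)) if case[i] else str(rng.choice(_CONTROL_CODES))
        )

    events = EventTable(pd.DataFrame(rows), pd.DataFrame(dx))
    labels = pd.Series(case, index=pd.Index(pids, name="patient_id"), name="label")
    return events, labels
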