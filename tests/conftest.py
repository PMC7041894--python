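import numpy as np
import pytest

from dptrialsynth.cohort import (
    DEFAULT_SCHEMA,
    Cohort,
    ParticipantRecord,
    cohort_from_arrays,
)
from dptrialsynth.fixtures import TrialSimParams, simulate_trial


@pytest.fixture(scope="session")
def trial_cohort():
    """Mid-sized simulated trial cohort shared across read-only tests."""
    return simulate_trial(TrialSimParams(n_participants=2000, seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_trial(TrialSimParams(n_participants=300, seed=5))


def make_record(id_, arm, sbp, dbp=None, med=None, schema=DEFAULT_SCHEMA):
    """Hand-build a record from per-visit SBP (DBP/MED default constant)."""
    n = schema.n_visits
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.full(n, 80.0) if dbp is None else np.asarray(dbp, dtype=float)
    med = np.zeros(n) if med is None else np.asarray(med, dtype=float)
    values = np.stack([sbp, dbp, med], axis=1)
    return ParticipantRecord(id_, arm, values, schema.schedule)


@pytest.fixture
def toy_cohort():
    """Four hand-built records, two per arm."""
    sched = DEFAULT_SCHEMA.schedule
    recs = (
        make_record("a", "standard", np.linspace(150, 140, 12)),
        make_record("b", "standard", np.linspace(145, 130, 12)),
        make_record("c", "intensive", np.linspace(140, 118, 12)),
        make_record("d", "intensive", np.linspace(138, 121, 12)),
    )
    return Cohort(recs, DEFAULT_SCHEMA)
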