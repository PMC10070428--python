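import random

import pytest

from polypharm import (
    MedicationEpisode,
    PatientRecord,
    SOCVocabulary,
    SyntheticConfig,
    simulate_cohort,
)


def ep(pid, name, start, end=None, **kw):
    return MedicationEpisode(patient_id=pid, generic_name=name, start_day=start, end_day=end, **kw)


@pytest.fixture(scope="session")
def vocabulary():
    return SOCVocabulary.default()


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 30-patient trial-flavor cohort used across tests."""
    config = SyntheticConfig(n_patients=30, seed=123)
    return simulate_cohort(config)


def random_cohort(rng: random.Random, max_patients=50, max_eps_per_patient=8, horizon=60):
    """Random episode set for oracle-equivalence tests (independent of the
    synthetic generator, so generator bugs cannot mask exposure bugs)."""
    n = rng.randint(1, max_patients)
    meds = [f"m{i}" for i in range(rng.randint(1, 12))]
    pids = [f"p{i}" for i in range(n)]
    episodes = []
    for pid in pids:
        for _ in range(rng.randint(0, max_eps_per_patient)):
            start = rng.randint(1, horizon + 5)
            if rng.random() < 0.2:
                end = None
            else:
                end = start + rng.randint(0, 20)
            episodes.append(ep(pid, rng.choice(meds), start, end))
    return pids, episodes


def brute_force_active(episodes, pids, horizon, missing_end="single_day"):
    """Day-by-day membership scan: the oracle for all exposure computations."""
    active = {pid: {d: set() for d in range(1, horizon + 1)} for pid in pids}
    for e in episodes:
        if e.patient_id not in active:
            continue
        if e.end_day is not None:
            end = e.end_day
        elif missing_end == "censor":
            end = horizon
        else:
            end = e.start_day
        for d in range(1, horizon + 1):
            if e.start_day <= d <= end:
                active[e.patient_id][d].add(e.generic_name)
    return active
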