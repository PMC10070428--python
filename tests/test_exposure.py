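"""Daily exposure, windowed counts and prevalence against brute-force oracles."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polypharm import (
    daily_exposure,
    medication_frequency,
    point_prevalence,
    prevalence_by_stratum,
    unique_meds_in_window,
    window_summary,
    PatientRecord,
)

from conftest import brute_force_active, ep, random_cohort


def test_inclusive_interval_endpoints():
    daily = daily_exposure([ep("p", "A", 1, 3)], horizon=10)
    for d in (1, 2, 3):
        assert daily["p"].active_on(d) == {"A"}
    for d in (4, 10):
        assert daily["p"].active_on(d) == set()


def test_multi_episode_day_sets():
    eps = [ep("p", "A", 1, 3), ep("p", "A", 10, 12), ep("p", "B", 2, 2)]
    daily = daily_exposure(eps, horizon=20)
    assert daily["p"].active_on(2) == {"A", "B"}
    assert daily["p"].active_on(5) == set()
    assert daily["p"].active_on(11) == {"A"}


def test_missing_end_policies():
    daily = daily_exposure([ep("p", "A", 5)], horizon=10)
    assert daily["p"].active_on(5) == {"A"}
    assert daily["p"].active_on(6) == set()
    censored = daily_exposure([ep("p", "A", 5)], horizon=10, missing_end="censor")
    assert all(censored["p"].active_on(d) == {"A"} for d in range(5, 11))


def test_overlapping_same_medication_not_double_counted():
    daily = daily_exposure([ep("p", "A", 1, 5), ep("p", "A", 3, 8)], horizon=10)
    assert point_prevalence(daily["p"])[4] == 1


def test_window_counts_examples():
    eps = [ep("p", "A", 1, 3), ep("p", "B", 2, 10), ep("p", "A", 20, 25)]
    assert unique_meds_in_window(eps, 7)["p"] == 2
    assert unique_meds_in_window(eps, 21)["p"] == 2  # A counted once
    assert unique_meds_in_window([ep("p", "C", 6, 9)], 7)["p"] == 1  # partial overlap


def test_zero_exposure_patients_retained():
    counts = unique_meds_in_window([], 7, patient_ids=["p1", "p2"])
    assert counts == {"p1": 0, "p2": 0}
    daily = daily_exposure([], 10, ["p1"])
    assert point_prevalence(daily["p1"]) == {d: 0 for d in range(1, 11)}


def test_window_summary_hand_computed():
    s = window_summary({"a": 2, "b": 4}, 7)
    assert s.mean == 3.0
    assert s.sd == pytest.approx(2 ** 0.5)
    assert (s.min, s.max) == (2, 4)
    assert s.format() == "3.0 ± 1.4 (range 2–4)"


def test_window_summary_single_patient_sd_na():
    s = window_summary({"a": 5})
    assert s.sd is None
    assert s.format() == "5.0 ± NA (range 5–5)"


def test_window_summary_empty_errors():
    with pytest.raises(ValueError):
        window_summary({})


def test_medication_frequency_distinct_patients():
    eps = [
        ep("p1", "A", 1, 2), ep("p1", "A", 9, 9), ep("p1", "B", 1, 1),
        ep("p2", "A", 3, 4),
    ]
    assert medication_frequency(eps, 60) == [("A", 2), ("B", 1)]


def test_medication_frequency_tiebreak_lexicographic():
    eps = [ep("p1", "zed", 1, 1), ep("p1", "abc", 1, 1)]
    assert medication_frequency(eps, 60) == [("abc", 1), ("zed", 1)]


def test_prevalence_by_stratum_hand_computed():
    patients = [
        PatientRecord("p1", "t", ais_grade="A"),
        PatientRecord("p2", "t", ais_grade="A"),
        PatientRecord("p3", "t"),  # unknown stratum retained
    ]
    daily = daily_exposure(
        [ep("p1", "A", 1, 1), ep("p1", "B", 1, 1), ep("p2", "A", 1, 4),
         ep("p2", "B", 1, 4), ep("p2", "C", 1, 4), ep("p2", "D", 1, 4)],
        horizon=5,
        patient_ids=["p1", "p2", "p3"],
    )
    series = {s.label: s for s in prevalence_by_stratum(daily, patients)}
    assert set(series) == {"A", "unknown"}
    a = series["A"]
    assert a.mean[0] == 3.0 and a.min[0] == 2 and a.max[0] == 4
    u = series["unknown"]
    assert u.mean == u.min == u.max  # single-patient stratum


@pytest.mark.parametrize("seed", range(25))
def test_oracle_equivalence_random_cohorts(seed):
    """Interval-based exposure equals a day-grid membership scan, exactly."""
    rng = random.Random(seed)
    pids, episodes = random_cohort(rng, max_patients=20, max_eps_per_patient=6)
    horizon = 60
    oracle = brute_force_active(episodes, pids, horizon)
    daily = daily_exposure(episodes, horizon, pids)
    for pid in pids:
        for d in range(1, horizon + 1):
            assert daily[pid].active_on(d) == oracle[pid][d]
    # windowed unique counts against the same oracle
    for w in (7, 14, 30, 60):
        counts = unique_meds_in_window(episodes, w, pids)
        for pid in pids:
            expected = set().union(*(oracle[pid][d] for d in range(1, w + 1)))
            assert counts[pid] == len(expected)
    # frequency against the oracle
    freq = dict(medication_frequency(episodes, horizon))
    meds = {e.generic_name for e in episodes}
    for med in meds:
        n = sum(
            1
            for pid in pids
            if any(med in oracle[pid][d] for d in range(1, horizon + 1))
        )
        assert freq.get(med, 0) == n


_episode_st = st.tuples(
    st.sampled_from(["p1", "p2", "p3"]),
    st.sampled_from(["A", "B", "C", "D"]),
    st.integers(1, 70),
    st.one_of(st.none(), st.integers(0, 30)),
)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(_episode_st, max_size=40))
def test_window_monotonicity_property(raw):
    """Unique-in-window counts never decrease as the window widens."""
    episodes = [ep(p, m, s, None if d is None else s + d) for p, m, s, d in raw]
    pids = ["p1", "p2", "p3"]
    per_window = {w: unique_meds_in_window(episodes, w, pids) for w in (7, 14, 30, 60)}
    for pid in pids:
        assert (
            per_window[7][pid] <= per_window[14][pid]
            <= per_window[30][pid] <= per_window[60][pid]
        )


@pytest.mark.parametrize("seed", range(10))
def test_window_monotonicity_and_consistency(seed):
    rng = random.Random(1000 + seed)
    pids, episodes = random_cohort(rng, max_patients=15)
    per_window = {w: unique_meds_in_window(episodes, w, pids) for w in (7, 14, 30, 60)}
    daily = daily_exposure(episodes, 60, pids)
    for pid in pids:
        assert (
            per_window[7][pid] <= per_window[14][pid]
            <= per_window[30][pid] <= per_window[60][pid]
        )
        prev = point_prevalence(daily[pid])
        for w in (7, 14, 30, 60):
            assert per_window[w][pid] >= max(prev[d] for d in range(1, w + 1))
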