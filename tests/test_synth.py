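"""Synthetic cohort generator: determinism, censoring, analytic recovery."""

import dataclasses

import numpy as np
import pytest

from polypharm import (
    ColumnMap,
    SyntheticConfig,
    daily_exposure,
    default_catalog,
    expected_mean_daily_prevalence,
    point_prevalence,
    read_medication_log,
    read_patient_table,
    recover_parameters,
    simulate_cohort,
    unique_meds_in_window,
    write_episode_table,
    write_patient_table,
)
from polypharm.synth import ConfigError, prob_active, start_day_pmf


def test_determinism_identical_seed(tmp_path):
    config = SyntheticConfig(n_patients=40, seed=42)
    out1 = simulate_cohort(config)
    out2 = simulate_cohort(SyntheticConfig(n_patients=40, seed=42))
    assert out1[0] == out2[0]
    assert out1[1] == out2[1]
    # byte-identical files
    for run, suffix in ((out1, "a"), (out2, "b")):
        write_patient_table(run[0], tmp_path / f"p_{suffix}.csv")
        write_episode_table(run[1], tmp_path / f"e_{suffix}.csv")
    assert (tmp_path / "p_a.csv").read_bytes() == (tmp_path / "p_b.csv").read_bytes()
    assert (tmp_path / "e_a.csv").read_bytes() == (tmp_path / "e_b.csv").read_bytes()


def test_different_seed_differs():
    a = simulate_cohort(SyntheticConfig(n_patients=40, seed=1))
    b = simulate_cohort(SyntheticConfig(n_patients=40, seed=2))
    assert a[1] != b[1]


def test_invalid_config_rejected_before_sampling():
    config = SyntheticConfig(n_patients=10)
    config.sex_probs = {"male": 0.8, "female": 0.1}  # sums to 0.9
    with pytest.raises(ConfigError):
        simulate_cohort(config)
    with pytest.raises(ConfigError):
        simulate_cohort(SyntheticConfig(n_patients=0))


def test_degenerate_single_medication_config():
    catalog = default_catalog(1)
    config = SyntheticConfig(n_patients=1, seed=5, catalog=catalog)
    config.episode_rate_by_ais = {k: 1.0 for k in config.episode_rate_by_ais}
    _, episodes, truth = simulate_cohort(config)
    assert all(e.generic_name == catalog[0].name for e in truth.latent_episodes)


def test_output_passes_ingest_validation_with_zero_rejections(tmp_path, small_cohort):
    patients, episodes, _ = small_cohort
    write_patient_table(patients, tmp_path / "p.csv")
    write_episode_table(episodes, tmp_path / "e.csv")
    back_patients = read_patient_table(tmp_path / "p.csv")
    back_eps, report = read_medication_log(tmp_path / "e.csv", ColumnMap(), back_patients)
    assert report.records_rejected == 0
    assert back_eps == episodes


def test_start_pmf_and_activity_are_proper():
    config = SyntheticConfig()
    pmf = start_day_pmf(config)
    assert pmf.shape == (60,)
    assert pmf.sum() == pytest.approx(1.0)
    p = prob_active(config)
    assert np.all((0 <= p) & (p <= 1))


def test_censoring_observed_subset_of_latent():
    config = SyntheticConfig(n_patients=60, seed=11, flavor="observational")
    patients, observed, truth = simulate_cohort(config)
    latent_days = {}
    for e in truth.latent_episodes:
        end = e.end_day if e.end_day is not None else e.start_day
        latent_days.setdefault(e.patient_id, set()).update(
            (e.generic_name, d) for d in range(e.start_day, end + 1)
        )
    for e in observed:
        end = e.end_day if e.end_day is not None else e.start_day
        for d in range(e.start_day, end + 1):
            assert (e.generic_name, d) in latent_days[e.patient_id]
    # capture begins at enrollment: nothing observed before it
    enroll = truth.enrollment_day
    assert all(e.start_day >= enroll[e.patient_id] for e in observed)


def test_observational_flavor_near_zero_week1_capture():
    config = SyntheticConfig(n_patients=150, seed=3, flavor="observational")
    patients, observed, _ = simulate_cohort(config)
    pids = [p.patient_id for p in patients]
    week1 = unique_meds_in_window(observed, 7, pids)
    zero_share = sum(1 for v in week1.values() if v == 0) / len(pids)
    # most patients enroll after day 7, so their week-1 exposure is unobserved
    assert zero_share > 0.6


def test_window_counts_monotone_and_reach_tens(small_cohort):
    patients, episodes, _ = small_cohort
    pids = [p.patient_id for p in patients]
    per_window = {w: unique_meds_in_window(episodes, w, pids) for w in (7, 14, 30, 60)}
    for pid in pids:
        assert (
            per_window[7][pid] <= per_window[14][pid]
            <= per_window[30][pid] <= per_window[60][pid]
        )
    daily = daily_exposure(episodes, 60, pids)
    max_daily = max(max(point_prevalence(d).values()) for d in daily.values())
    assert max_daily >= 10  # daily concurrent counts reach the tens


def test_severity_gradient_detectable():
    """AIS A/B patients accumulate more week-1 medications than AIS D."""
    config = SyntheticConfig(n_patients=500, seed=17)
    patients, episodes, _ = simulate_cohort(config)
    counts = unique_meds_in_window(episodes, 7, [p.patient_id for p in patients])
    by_grade = {}
    for p in patients:
        group = "AB" if p.ais_grade in ("A", "B") else p.ais_grade
        by_grade.setdefault(group, []).append(counts[p.patient_id])
    ab, d = np.array(by_grade["AB"], float), np.array(by_grade["D"], float)
    diff = ab.mean() - d.mean()
    se = np.sqrt(ab.var(ddof=1) / len(ab) + d.var(ddof=1) / len(d))
    assert diff > 3 * se


def test_recovery_uncensored_identity():
    config = SyntheticConfig(n_patients=100, seed=23, censor_before_enrollment=False)
    patients, episodes, truth = simulate_cohort(config)
    report = recover_parameters(patients, episodes, truth)
    assert all(err == 0.0 for err in report.window_mean_abs_error.values())
    assert report.prevalence_abs_error_vs_latent == 0.0


def test_recovery_matches_analytic_expectation():
    """Simulated mean daily prevalence within 3 SE of the closed form."""
    config = SyntheticConfig(n_patients=200, seed=29, censor_before_enrollment=False)
    patients, episodes, truth = simulate_cohort(config)
    report = recover_parameters(patients, episodes, truth)
    assert report.prevalence_abs_error_vs_expected <= 3 * report.prevalence_se


def test_recovery_rejects_mismatched_cohort():
    config = SyntheticConfig(n_patients=20, seed=1)
    patients, episodes, truth = simulate_cohort(config)
    other_patients, _, _ = simulate_cohort(SyntheticConfig(n_patients=25, seed=1))
    with pytest.raises(ConfigError):
        recover_parameters(other_patients, episodes, truth)


def test_expected_prevalence_positive_and_finite():
    val = expected_mean_daily_prevalence(SyntheticConfig())
    assert 0 < val < 50
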