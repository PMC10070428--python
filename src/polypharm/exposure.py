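"""Day-level drug exposure, windowed unique-medication counts and point prevalence.

The counting unit throughout is the distinct normalized medication name: a
patient on two overlapping prescriptions of the same generic contributes one
active medication on the overlap days, and episodes of the same generic in a
window count once. Exposure intervals are closed on both endpoints and the
analysis horizon defaults to the first 60 days post-injury.

Episodes with a missing end day are treated as single-day administrations by
default (``missing_end="single_day"``); set ``missing_end="censor"`` to
instead carry them to the analysis horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._utils import fmt_mean_sd_range, round1
from .records import MedicationEpisode, PatientRecord

DEFAULT_HORIZON = 60
DEFAULT_WINDOWS = (7, 14, 30, 60)


def _effective_interval(
    episode: MedicationEpisode, horizon: int, missing_end: str
) -> tuple[int, int] | None:
    """Closed day interval of an episode clipped to [1, horizon], or None."""
    start = episode.start_day
    if start > horizon:
        return None
    if episode.end_day is not None:
        end = episode.end_day
    elif missing_end == "single_day":
        end = start
    elif missing_end == "censor":
        end = horizon
    else:
        raise ValueError(f"unknown missing_end policy {missing_end!r}")
    return start, min(end, horizon)


@dataclass
class DailyExposure:
    """Per-patient mapping of post-injury day to the set of active medications."""

    patient_id: str
    horizon_days: int = DEFAULT_HORIZON
    active: dict[int, set[str]] = field(default_factory=dict)

    def active_on(self, day: int) -> set[str]:
        if not 1 <= day <= self.horizon_days:
            raise ValueError(f"day {day} outside horizon [1, {self.horizon_days}]")
        return self.active.get(day, set())


def daily_exposure(
    episodes: Iterable[MedicationEpisode],
    horizon: int = DEFAULT_HORIZON,
    patient_ids: Iterable[str] | None = None,
    missing_end: str = "single_day",
) -> dict[str, DailyExposure]:
    """Build per-patient day-level exposure from episode intervals.

    Patients listed in ``patient_ids`` but holding no episode get an empty
    exposure record, so zero-medication patients stay in every downstream
    summary.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    out: dict[str, DailyExposure] = {}
    if patient_ids is not None:
        for pid in patient_ids:
            out[pid] = DailyExposure(pid, horizon)
    for ep in episodes:
        interval = _effective_interval(ep, horizon, missing_end)
        if interval is None:
            continue
        exp = out.setdefault(ep.patient_id, DailyExposure(ep.patient_id, horizon))
        start, end = interval
        for day in range(start, end + 1):
            exp.active.setdefault(day, set()).add(ep.generic_name)
    return out


def unique_meds_in_window(
    episodes: Iterable[MedicationEpisode],
    window_days: int,
    patient_ids: Iterable[str] | None = None,
    missing_end: str = "single_day",
    partial_overlap_counts: bool = True,
) -> dict[str, int]:
    """Distinct medications per patient with exposure in days [1, window].

    An episode overlapping the window on any day counts by default;
    ``partial_overlap_counts=False`` requires the episode to lie wholly
    inside the window. Patients without any overlap are retained at 0.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    meds: dict[str, set[str]] = {}
    if patient_ids is not None:
        for pid in patient_ids:
            meds[pid] = set()
    for ep in episodes:
        interval = _effective_interval(ep, window_days, missing_end)
        if interval is None:
            continue
        start, end = interval
        if not partial_overlap_counts and (ep.end_day or ep.start_day) > window_days:
            continue
        if start <= window_days and end >= 1:
            meds.setdefault(ep.patient_id, set()).add(ep.generic_name)
    return {pid: len(s) for pid, s in meds.items()}


@dataclass
class WindowCountSummary:
    """Cohort summary of per-patient unique-medication counts in one window."""

    window_days: int
    per_patient_counts: dict[str, int]
    mean: float
    sd: float | None
    min: int
    max: int

    @property
    def n(self) -> int:
        return len(self.per_patient_counts)

    def format(self) -> str:
        """Render as ``'9.9 ± 4.9 (range 0–34)'``."""
        return fmt_mean_sd_range(self.mean, self.sd, self.min, self.max)

    def to_dict(self) -> dict:
        return {
            "window_days": self.window_days,
            "n_patients": self.n,
            "mean": round1(self.mean),
            "sd": None if self.sd is None else round1(self.sd),
            "min": self.min,
            "max": self.max,
            "formatted": self.format(),
        }


def window_summary(
    per_patient_counts: Mapping[str, int], window_days: int = 0
) -> WindowCountSummary:
    """Mean, sample (n−1) SD, min and max of per-patient window counts.

    With a single patient the SD is reported as not available.
    """
    counts = list(per_patient_counts.values())
    if not counts:
        raise ValueError("window_summary of an empty cohort")
    n = len(counts)
    mean = sum(counts) / n
    if n > 1:
        sd = math.sqrt(sum((c - mean) ** 2 for c in counts) / (n - 1))
    else:
        sd = None
    return WindowCountSummary(
        window_days=window_days,
        per_patient_counts=dict(per_patient_counts),
        mean=mean,
        sd=sd,
        min=min(counts),
        max=max(counts),
    )


def point_prevalence(daily: DailyExposure) -> dict[int, int]:
    """Number of distinct medications active on each day 1..horizon."""
    return {day: len(daily.active.get(day, ())) for day in range(1, daily.horizon_days + 1)}


@dataclass
class PrevalenceSeries:
    """Per-day mean/min/max medication count across one patient stratum."""

    label: str
    n_patients: int
    days: list[int]
    mean: list[float]
    min: list[int]
    max: list[int]


def prevalence_by_stratum(
    daily_by_patient: Mapping[str, DailyExposure],
    patients: Sequence[PatientRecord],
    stratifier: str = "ais_grade",
) -> list[PrevalenceSeries]:
    """Stratified daily point-prevalence curves (e.g. by AIS grade).

    Patients whose stratum value is missing form their own ``"unknown"``
    stratum rather than being dropped. Patients without an exposure record
    contribute zero counts.
    """
    strata: dict[str, list[str]] = {}
    for p in patients:
        label = getattr(p, stratifier, None) or "unknown"
        strata.setdefault(str(label), []).append(p.patient_id)
    horizon = max((d.horizon_days for d in daily_by_patient.values()), default=DEFAULT_HORIZON)
    series: list[PrevalenceSeries] = []
    for label in sorted(strata):
        pids = strata[label]
        days = list(range(1, horizon + 1))
        means, mins, maxs = [], [], []
        for day in days:
            counts = [
                len(daily_by_patient[pid].active.get(day, ()))
                if pid in daily_by_patient
                else 0
                for pid in pids
            ]
            means.append(sum(counts) / len(counts))
            mins.append(min(counts))
            maxs.append(max(counts))
        series.append(PrevalenceSeries(label, len(pids), days, means, mins, maxs))
    return series


def medication_frequency(
    episodes: Iterable[MedicationEpisode],
    window_days: int = DEFAULT_HORIZON,
    missing_end: str = "single_day",
) -> list[tuple[str, int]]:
    """Ranked (medication, n distinct patients) within days [1, window].

    Deterministic order: patient count descending, then name ascending. A
    patient with several episodes of the same medication counts once.
    """
    patients_by_med: dict[str, set[str]] = {}
    for ep in episodes:
        interval = _effective_interval(ep, window_days, missing_end)
        if interval is None:
            continue
        patients_by_med.setdefault(ep.generic_name, set()).add(ep.patient_id)
    ranked = [(med, len(pids)) for med, pids in patients_by_med.items()]
    ranked.sort(key=lambda kv: (-kv[1], kv[0]))
    return ranked
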