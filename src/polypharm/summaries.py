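"""Cohort demographics, inclusion filters, cross-source overlap and reporting.

Conventions shared by every table: percentages use the full cohort
(including missing) as denominator and are rounded half away from zero to
one decimal; missing values appear as their own category so per-variable
counts always sum to the cohort size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._utils import pct, round1
from .records import MedicationEpisode, PatientRecord

REPORT_SCHEMA_VERSION = "1.0"

#: stages a consolidated report must contain
REQUIRED_STAGES = (
    "demographics",
    "window_summaries",
    "medication_frequency",
    "soc_summary",
    "prophylaxis",
    "bbb",
    "networks",
)

_CATEGORICAL_VARIABLES = ("sex", "age_group", "ais_grade", "neuro_level", "plegia", "cause")
_MISSING_LABELS = {"sex": "missing", "ais_grade": "unknown", "neuro_level": "unknown",
                   "plegia": "unknown", "cause": "unknown", "age_group": "missing"}


@dataclass
class DemographicsTable:
    """Table-1-style cohort description."""

    n: int
    variables: dict[str, dict[str, tuple[int, float]]]
    age_mean: float | None = None
    age_sd: float | None = None
    age_median: float | None = None
    age_min: float | None = None
    age_max: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, cats in self.variables.items():
            for cat, (count, share) in cats.items():
                rows.append({"variable": var, "category": cat, "n": count, "pct": share})
        return pd.DataFrame(rows, columns=["variable", "category", "n", "pct"])

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "variables": {
                var: {cat: {"n": c, "pct": p} for cat, (c, p) in cats.items()}
                for var, cats in self.variables.items()
            },
            "age": {
                "mean": self.age_mean,
                "sd": self.age_sd,
                "median": self.age_median,
                "min": self.age_min,
                "max": self.age_max,
            },
        }


def demographics_table(patients: Sequence[PatientRecord]) -> DemographicsTable:
    """Counts and full-cohort percentages per demographic variable.

    Missing values form their own category; per-variable counts sum to the
    cohort size. Continuous age is summarized as mean (SD) and
    median [min, max] over non-missing values.
    """
    if not patients:
        raise ValueError("demographics_table of an empty cohort")
    n = len(patients)
    variables: dict[str, dict[str, tuple[int, float]]] = {}
    for var in _CATEGORICAL_VARIABLES:
        counts: dict[str, int] = {}
        for p in patients:
            value = getattr(p, var)
            label = str(value) if value not in (None, "") else _MISSING_LABELS[var]
            counts[label] = counts.get(label, 0) + 1
        variables[var] = {cat: (c, pct(c, n)) for cat, c in sorted(counts.items())}

    ages = [p.age_years for p in patients if p.age_years is not None]
    age_stats: dict[str, float | None] = dict(mean=None, sd=None, median=None, lo=None, hi=None)
    if ages:
        s = pd.Series(ages, dtype=float)
        age_stats = dict(
            mean=round1(s.mean()),
            sd=round1(s.std(ddof=1)) if len(ages) > 1 else None,
            median=round1(s.median()),
            lo=float(s.min()),
            hi=float(s.max()),
        )
    return DemographicsTable(
        n=n,
        variables=variables,
        age_mean=age_stats["mean"],
        age_sd=age_stats["sd"],
        age_median=age_stats["median"],
        age_min=age_stats["lo"],
        age_max=age_stats["hi"],
    )


@dataclass
class ExclusionTally:
    """Per-reason exclusion counts; reasons sum to total."""

    no_meds: int = 0
    ais_e: int = 0

    @property
    def total(self) -> int:
        return self.no_meds + self.ais_e

    def to_dict(self) -> dict:
        return {"no_meds": self.no_meds, "ais_e": self.ais_e, "total": self.total}


def apply_inclusion_filters(
    patients: Sequence[PatientRecord],
    episodes: Sequence[MedicationEpisode],
    abstraction_cohorts: Iterable[str] = (),
) -> tuple[list[PatientRecord], ExclusionTally]:
    """Exclude AIS-E patients and, in record-abstraction cohorts, patients
    with no medication records.

    ``abstraction_cohorts`` names the cohort labels whose medication data
    were abstracted from medical records, where an empty log means missing
    data rather than genuinely zero exposure. In those cohorts only,
    zero-episode patients are excluded; AIS grade E (no residual
    sensorimotor deficit) is excluded everywhere. The tally reports each
    reason separately; a patient matching both reasons counts under the
    first (missing medications).
    """
    abstraction = set(abstraction_cohorts)
    with_eps = {e.patient_id for e in episodes}
    included: list[PatientRecord] = []
    tally = ExclusionTally()
    for p in patients:
        if p.cohort in abstraction and p.patient_id not in with_eps:
            tally.no_meds += 1
        elif p.ais_grade == "E":
            tally.ais_e += 1
        else:
            included.append(p)
    return included, tally


@dataclass
class OverlapSummary:
    """Cross-source unique-medication overlap via inclusion–exclusion."""

    n_source_a: int
    n_source_b: int
    n_shared: int
    n_union: int
    pct_shared_of_union: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def medication_overlap(
    unique_names_a: Iterable[str], unique_names_b: Iterable[str]
) -> OverlapSummary:
    """Overlap of two sources' unique-medication sets.

    ``n_union = |A| + |B| − |A∩B|`` exactly; the shared percentage is
    relative to the union, one decimal.
    """
    a, b = set(unique_names_a), set(unique_names_b)
    if not a and not b:
        raise ValueError("both medication sets are empty")
    shared = len(a & b)
    union = len(a) + len(b) - shared
    return OverlapSummary(
        n_source_a=len(a),
        n_source_b=len(b),
        n_shared=shared,
        n_union=union,
        pct_shared_of_union=pct(shared, union),
    )


def build_report(stages: dict, extra_stages_ok: bool = True) -> dict:
    """Consolidate stage outputs into a versioned, JSON-serializable report.

    ``stages`` maps stage name → JSON-serializable payload and must contain
    every stage in :data:`REQUIRED_STAGES`; a missing mandatory stage raises
    an error naming it.
    """
    for stage in REQUIRED_STAGES:
        if stage not in stages:
            raise ValueError(f"report is missing mandatory stage output: {stage!r}")
    report = {"schema_version": REPORT_SCHEMA_VERSION}
    report.update({k: stages[k] for k in sorted(stages)})
    json.dumps(report)  # fail fast if any payload is not serializable
    return report


def write_report(report: dict, path: str | Path) -> None:
    """Write a report deterministically (sorted keys, stable formatting)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
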