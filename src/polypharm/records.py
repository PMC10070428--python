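"""Reading, validation and normalization of patient tables and medication logs.

Input files are delimited text (comma or tab) with a header row. A
:class:`ColumnMap` names the columns that hold each logical field and says
whether dosing intervals are recorded as calendar dates (converted against
the patient's injury date) or directly as post-injury day offsets.

Day convention: the day of injury is day 1, and exposure intervals are
closed on both ends. For calendar-date inputs,
``day = (date - injury_date).days + 1``.

Malformed rows never abort a run: they are rejected with a machine-readable
reason code and tallied in a :class:`ValidationReport`, mirroring how
medication reconciliation treats record-abstraction noise as a reported
outcome rather than a fatal error.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

SEX_LEVELS = {"female", "male", "missing"}
AIS_LEVELS = {"A", "B", "C", "D", "E", "unknown"}
NEURO_LEVELS = {"cervical", "thoracic", "lumbar", "unknown"}
PLEGIA_LEVELS = {"paraplegia", "tetraplegia", "unknown"}

#: tokens stripped from raw medication names (dose units, forms, routes)
DEFAULT_STRIP_LEXICON = frozenset(
    {
        "mg", "mcg", "g", "kg", "ml", "l", "meq", "iu", "units", "unit", "%",
        "tablet", "tablets", "tab", "tabs", "capsule", "capsules", "cap",
        "caps", "solution", "soln", "suspension", "syrup", "cream",
        "ointment", "patch", "injection", "inj", "suppository", "spray",
        "drops", "gtt", "po", "iv", "im", "sc", "sq", "pr", "oral",
        "topical", "er", "sr", "xr", "hcl", "sodium",
    }
)

_COMBINATION_SPLIT = re.compile(r"\s*/\s*|\s*\+\s*|\s+and\s+|\s*;\s*")
_NUMERIC_TOKEN = re.compile(r"^\d+([.,/-]\d+)*(mg|mcg|g|ml|meq|iu|%)?$")

COMBINATION_SEPARATOR = "+"


class MedRecError(ValueError):
    """Structural error in an input table (missing column, duplicate id)."""


def normalize_generic_name(raw: str, strip_lexicon: frozenset[str] | None = None) -> str:
    """Normalize a raw medication name to its canonical generic form.

    Case-folds, collapses whitespace and drops dose/form/route suffix tokens
    from the stripping lexicon. Combination products (components joined by
    ``/``, ``+``, ``and`` or ``;`` in the source) are kept as a *single*
    distinct medication: components are sorted lexicographically and joined
    with ``+`` — ``"Oxycodone/Acetaminophen"`` becomes
    ``"acetaminophen+oxycodone"`` and is counted separately from plain
    acetaminophen, never split into its components.

    Raises :class:`MedRecError` if nothing is left after stripping.
    """
    if strip_lexicon is None:
        strip_lexicon = DEFAULT_STRIP_LEXICON
    text = raw.strip().casefold()
    parts = [p for p in _COMBINATION_SPLIT.split(text) if p]

    def clean(part: str) -> str:
        tokens = part.split()
        kept = [t for t in tokens if t not in strip_lexicon and not _NUMERIC_TOKEN.match(t)]
        return " ".join(kept)

    components = sorted({c for c in (clean(p) for p in parts) if c})
    if not components:
        raise MedRecError(f"medication name empty after normalization: {raw!r}")
    return COMBINATION_SEPARATOR.join(components)


@dataclass
class PatientRecord:
    """One study participant with demographics and injury characteristics."""

    patient_id: str
    cohort: str
    sex: str = "missing"
    age_years: float | None = None
    age_group: str | None = None
    ais_grade: str = "unknown"
    neuro_level: str = "unknown"
    plegia: str = "unknown"
    cause: str = "unknown"
    injury_date: date | None = None
    enrollment_day: int = 1

    def __post_init__(self) -> None:
        if self.sex not in SEX_LEVELS:
            raise MedRecError(f"invalid sex {self.sex!r}")
        if self.ais_grade not in AIS_LEVELS:
            raise MedRecError(f"invalid AIS grade {self.ais_grade!r}")
        if self.neuro_level not in NEURO_LEVELS:
            raise MedRecError(f"invalid neurological level {self.neuro_level!r}")
        if self.plegia not in PLEGIA_LEVELS:
            raise MedRecError(f"invalid plegia {self.plegia!r}")
        if self.enrollment_day < 1:
            raise MedRecError("enrollment_day must be >= 1")
        if self.age_years is not None and self.age_years < 0:
            raise MedRecError("age_years must be nonnegative")


@dataclass
class MedicationEpisode:
    """One administered medication with a closed exposure interval in days."""

    patient_id: str
    generic_name: str
    start_day: int
    end_day: int | None = None
    dose: float | None = None
    dose_unit: str | None = None
    frequency: str | None = None
    route: str | None = None
    indication_text: str | None = None
    prophylactic_marker: bool | None = None

    def __post_init__(self) -> None:
        if not self.generic_name:
            raise MedRecError("generic_name must be non-empty")
        if self.start_day < 1:
            raise MedRecError("start_day must be >= 1 (day of injury = day 1)")
        if self.end_day is not None and self.end_day < self.start_day:
            raise MedRecError("end_day must be >= start_day")


@dataclass
class ValidationReport:
    """Tally of the medication-reconciliation outcome of one ingest run."""

    records_read: int = 0
    records_accepted: int = 0
    rejected_by_reason: dict[str, int] = field(default_factory=dict)
    duplicates_collapsed: int = 0
    dosage_change_merges: int = 0
    patients_without_episodes: int = 0
    unknown_category_values: int = 0

    @property
    def records_rejected(self) -> int:
        return sum(self.rejected_by_reason.values())

    def reject(self, reason: str) -> None:
        self.rejected_by_reason[reason] = self.rejected_by_reason.get(reason, 0) + 1

    def check(self) -> None:
        if self.records_read != self.records_accepted + self.records_rejected:
            raise MedRecError("validation report does not conserve records")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["records_rejected"] = self.records_rejected
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


@dataclass
class ColumnMap:
    """Mapping from logical fields to the columns of a concrete file pair.

    ``date_mode`` selects how dosing intervals are recorded: ``"days"``
    (integer post-injury day offsets) or ``"dates"`` (ISO 8601 calendar
    dates, converted using each patient's injury date).
    """

    # patient table
    patient_id: str = "patient_id"
    cohort: str = "cohort"
    sex: str = "sex"
    age_years: str = "age_years"
    age_group: str = "age_group"
    ais_grade: str = "ais_grade"
    neuro_level: str = "neuro_level"
    plegia: str = "plegia"
    cause: str = "cause"
    injury_date: str = "injury_date"
    enrollment_day: str = "enrollment_day"
    # medication log
    med_patient_id: str = "patient_id"
    generic_name: str = "medication"
    start: str = "start_day"
    end: str = "end_day"
    dose: str = "dose"
    dose_unit: str = "dose_unit"
    frequency: str = "frequency"
    route: str = "route"
    indication: str = "indication"
    prophylactic: str = "prophylactic"
    date_mode: str = "days"
    delimiter: str = ","

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise MedRecError(f"unknown column-map keys: {sorted(unknown)}")
        return cls(**data)


def _canon_category(value, levels: set[str], missing: str, report: ValidationReport | None) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        return missing
    text = str(value).strip()
    if text in levels:
        return text
    lowered = text.lower()
    for lvl in levels:
        if lvl.lower() == lowered:
            return lvl
    if text.upper() in levels:  # AIS grades
        return text.upper()
    if report is not None:
        report.unknown_category_values += 1
    return missing


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, na_values=[""])


def read_patient_table(
    path: str | Path,
    dialect: ColumnMap | None = None,
    report: ValidationReport | None = None,
) -> list[PatientRecord]:
    """Read one cohort's patient table into :class:`PatientRecord` objects.

    Unknown strings in closed-vocabulary columns map to the missing/unknown
    level (tallied in ``report`` when given). A missing mandatory column or
    a duplicate ``patient_id`` is a hard error.
    """
    dialect = dialect or ColumnMap()
    df = _read_table(path, dialect.delimiter)
    for col in (dialect.patient_id, dialect.cohort):
        if col not in df.columns:
            raise MedRecError(f"patient table is missing mandatory column {col!r}")
    patients: list[PatientRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = str(row[dialect.patient_id]).strip()
        if pid in seen:
            raise MedRecError(f"duplicate patient_id {pid!r}")
        seen.add(pid)

        def cell(col):
            return row[col] if col in df.columns else None

        injury = _opt_str(cell(dialect.injury_date))
        enroll = _opt_float(cell(dialect.enrollment_day))
        patients.append(
            PatientRecord(
                patient_id=pid,
                cohort=str(row[dialect.cohort]).strip(),
                sex=_canon_category(cell(dialect.sex), SEX_LEVELS, "missing", report),
                age_years=_opt_float(cell(dialect.age_years)),
                age_group=_opt_str(cell(dialect.age_group)),
                ais_grade=_canon_category(cell(dialect.ais_grade), AIS_LEVELS, "unknown", report),
                neuro_level=_canon_category(cell(dialect.neuro_level), NEURO_LEVELS, "unknown", report),
                plegia=_canon_category(cell(dialect.plegia), PLEGIA_LEVELS, "unknown", report),
                cause=_opt_str(cell(dialect.cause)) or "unknown",
                injury_date=date.fromisoformat(injury) if injury else None,
                enrollment_day=int(enroll) if enroll is not None else 1,
            )
        )
    return patients


def day_offset(when: date, injury: date) -> int:
    """Calendar date to post-injury day, day of injury = day 1."""
    return (when - injury).days + 1


def _parse_day(
    value,
    mode: str,
    injury: date | None,
):
    """Return (day:int|None, error_reason:str|None)."""
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        return None, None
    text = str(value).strip()
    if mode == "days":
        try:
            return int(float(text)), None
        except ValueError:
            return None, "unparseable_day"
    try:
        when = datetime.strptime(text, "%Y-%m-%d").date()
    except ValueError:
        return None, "unparseable_date"
    if injury is None:
        return None, "missing_injury_date"
    return day_offset(when, injury), None


def read_medication_log(
    path: str | Path,
    dialect: ColumnMap | None = None,
    patients: Sequence[PatientRecord] | None = None,
) -> tuple[list[MedicationEpisode], ValidationReport]:
    """Read a medication log, validating against an already-loaded cohort.

    Rows are rejected (never fatal) with a reason code when the patient id
    is unknown, a date cannot be parsed, the interval ends before it starts,
    or the start precedes the injury. Exact duplicate rows collapse to one
    episode; rows identical except for dose/frequency/route collapse as
    dosage-change merges. An empty file yields an empty list plus a report.
    """
    dialect = dialect or ColumnMap()
    report = ValidationReport()
    df = _read_table(path, dialect.delimiter)
    for col in (dialect.med_patient_id, dialect.generic_name, dialect.start):
        if col not in df.columns:
            raise MedRecError(f"medication log is missing mandatory column {col!r}")

    index: dict[str, PatientRecord] = {}
    if patients is not None:
        index = {p.patient_id: p for p in patients}

    episodes: list[MedicationEpisode] = []
    seen_exact: set[tuple] = set()
    seen_interval: set[tuple] = set()
    for _, row in df.iterrows():
        report.records_read += 1

        def cell(col):
            return row[col] if col in df.columns else None

        pid = str(row[dialect.med_patient_id]).strip()
        if patients is not None and pid not in index:
            report.reject("unknown_patient")
            continue
        injury = index[pid].injury_date if pid in index else None
        raw_name = cell(dialect.generic_name)
        try:
            name = normalize_generic_name(str(raw_name)) if _opt_str(raw_name) else ""
        except MedRecError:
            name = ""
        if not name:
            report.reject("empty_name")
            continue
        start, err = _parse_day(cell(dialect.start), dialect.date_mode, injury)
        if err:
            report.reject(err)
            continue
        if start is None:
            report.reject("missing_start")
            continue
        end, err = _parse_day(cell(dialect.end), dialect.date_mode, injury)
        if err:
            report.reject(err)
            continue
        if start < 1:
            report.reject("start_before_injury")
            continue
        if end is not None and end < start:
            report.reject("end_before_start")
            continue

        dose = _opt_float(cell(dialect.dose))
        dose_unit = _opt_str(cell(dialect.dose_unit))
        frequency = _opt_str(cell(dialect.frequency))
        route = _opt_str(cell(dialect.route))
        indication = _opt_str(cell(dialect.indication))
        proph_raw = _opt_str(cell(dialect.prophylactic))
        proph = None
        if proph_raw is not None:
            proph = proph_raw.lower() in {"1", "true", "yes", "y"}

        exact_key = (pid, name, start, end, dose, dose_unit, frequency, route, indication, proph)
        interval_key = (pid, name, start, end)
        if exact_key in seen_exact:
            report.duplicates_collapsed += 1
            report.records_accepted += 1
            continue
        if interval_key in seen_interval:
            report.dosage_change_merges += 1
            report.records_accepted += 1
            continue
        seen_exact.add(exact_key)
        seen_interval.add(interval_key)
        episodes.append(
            MedicationEpisode(
                patient_id=pid,
                generic_name=name,
                start_day=start,
                end_day=end,
                dose=dose,
                dose_unit=dose_unit,
                frequency=frequency,
                route=route,
                indication_text=indication,
                prophylactic_marker=proph,
            )
        )
        report.records_accepted += 1

    if patients is not None:
        with_eps = {e.patient_id for e in episodes}
        report.patients_without_episodes = sum(1 for p in patients if p.patient_id not in with_eps)
    report.check()
    return episodes, report


_EPISODE_COLUMNS = [
    "patient_id", "medication", "start_day", "end_day", "dose", "dose_unit",
    "frequency", "route", "indication", "prophylactic",
]


def write_episode_table(episodes: Iterable[MedicationEpisode], path: str | Path) -> None:
    """Write normalized episodes as CSV (day-offset dialect); round-trip stable."""
    rows = []
    for e in episodes:
        rows.append(
            {
                "patient_id": e.patient_id,
                "medication": e.generic_name,
                "start_day": e.start_day,
                "end_day": "" if e.end_day is None else e.end_day,
                "dose": "" if e.dose is None else e.dose,
                "dose_unit": e.dose_unit or "",
                "frequency": e.frequency or "",
                "route": e.route or "",
                "indication": e.indication_text or "",
                "prophylactic": "" if e.prophylactic_marker is None else str(e.prophylactic_marker).lower(),
            }
        )
    pd.DataFrame(rows, columns=_EPISODE_COLUMNS).to_csv(path, index=False)


def write_patient_table(patients: Iterable[PatientRecord], path: str | Path) -> None:
    """Write patients in the default :class:`ColumnMap` dialect."""
    rows = []
    for p in patients:
        rows.append(
            {
                "patient_id": p.patient_id,
                "cohort": p.cohort,
                "sex": p.sex,
                "age_years": "" if p.age_years is None else p.age_years,
                "age_group": p.age_group or "",
                "ais_grade": p.ais_grade,
                "neuro_level": p.neuro_level,
                "plegia": p.plegia,
                "cause": p.cause,
                "injury_date": p.injury_date.isoformat() if p.injury_date else "",
                "enrollment_day": p.enrollment_day,
            }
        )
    cols = [
        "patient_id", "cohort", "sex", "age_years", "age_group", "ais_grade",
        "neuro_level", "plegia", "cause", "injury_date", "enrollment_day",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
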