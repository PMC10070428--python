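"""Free-text indication classification into 27 organ-system categories.

Each medication indication is assigned to one of the 26 System Organ
Classes — the highest level of the MedDRA hierarchy, as used by the CTCAE —
plus a dedicated "Trauma-related pain" category (nociceptive and
neuropathic), which the standard classes cover poorly in a trauma
population. Classification is lexicon-based: an exact-string override table
is consulted first, then a case-insensitive keyword scan where the longest
matching keyword wins and ties fall to the category listed first in the
vocabulary. Unmatched indications are surfaced as ``"unclassified"`` rather
than forced into a category or dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from ._utils import pct, round1
from .records import MedicationEpisode

UNCLASSIFIED = "unclassified"
TRAUMA_PAIN = "Trauma-related pain"

_PROPHYLAXIS_STEMS = ("prophyla", "prevent")


class VocabularyError(ValueError):
    """Malformed classification vocabulary."""


@dataclass
class SOCVocabulary:
    """Ordered category list with per-category keywords and exact overrides."""

    categories: list[str]
    keywords: dict[str, list[str]]
    overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise VocabularyError("category labels must be unique")
        for cat in self.keywords:
            if cat not in self.categories:
                raise VocabularyError(f"keywords for unknown category {cat!r}")
        for text, cat in self.overrides.items():
            if cat not in self.categories:
                raise VocabularyError(f"override {text!r} targets unknown category {cat!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SOCVocabulary":
        data = yaml.safe_load(Path(path).read_text())
        cats = [entry["name"] for entry in data["categories"]]
        keywords = {entry["name"]: list(entry.get("keywords", [])) for entry in data["categories"]}
        overrides = {str(k).casefold(): v for k, v in (data.get("overrides") or {}).items()}
        return cls(categories=cats, keywords=keywords, overrides=overrides)

    @classmethod
    def default(cls) -> "SOCVocabulary":
        ref = resources.files("polypharm.data") / "soc_vocabulary.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


@dataclass
class SOCAssignment:
    """Result of classifying one indication text."""

    indication_text: str | None
    category: str
    method: str  # override | keyword | unmatched
    prophylactic: bool = False

    def __post_init__(self) -> None:
        if (self.method == "unmatched") != (self.category == UNCLASSIFIED):
            raise VocabularyError("method 'unmatched' iff category 'unclassified'")


def flag_prophylactic(indication_text: str | None, explicit_marker: bool | None = None) -> bool:
    """Whether an administration was prophylactic/preventative.

    An explicit marker (True or False) always wins; otherwise the indication
    text is scanned for the stems "prophyla" and "prevent".
    """
    if explicit_marker is not None:
        return explicit_marker
    if not indication_text:
        return False
    lowered = indication_text.casefold()
    return any(stem in lowered for stem in _PROPHYLAXIS_STEMS)


def classify_indication(
    indication_text: str | None,
    vocabulary: SOCVocabulary,
    explicit_marker: bool | None = None,
) -> SOCAssignment:
    """Assign an indication to an organ-system category.

    Exact override first; else longest-matching keyword (case-insensitive
    substring), ties resolved by vocabulary category order; else
    unclassified. Empty text is unclassified, never an error.
    """
    prophylactic = flag_prophylactic(indication_text, explicit_marker)
    if not indication_text or not indication_text.strip():
        return SOCAssignment(indication_text, UNCLASSIFIED, "unmatched", prophylactic)
    lowered = indication_text.strip().casefold()

    if lowered in vocabulary.overrides:
        return SOCAssignment(indication_text, vocabulary.overrides[lowered], "override", prophylactic)

    best: tuple[int, int, str] | None = None  # (-len(keyword), category_rank, category)
    for rank, cat in enumerate(vocabulary.categories):
        for kw in vocabulary.keywords.get(cat, ()):
            if kw.casefold() in lowered:
                key = (-len(kw), rank, cat)
                if best is None or key < best:
                    best = key
    if best is None:
        return SOCAssignment(indication_text, UNCLASSIFIED, "unmatched", prophylactic)
    return SOCAssignment(indication_text, best[2], "keyword", prophylactic)


def classify_episodes(
    episodes: Sequence[MedicationEpisode], vocabulary: SOCVocabulary
) -> list[SOCAssignment]:
    """Classify every episode's indication, honouring explicit prophylaxis markers."""
    return [
        classify_indication(e.indication_text, vocabulary, e.prophylactic_marker)
        for e in episodes
    ]


def soc_summary(
    episodes: Sequence[MedicationEpisode],
    assignments: Sequence[SOCAssignment],
    vocabulary: SOCVocabulary,
    cohort_size: int | None = None,
) -> pd.DataFrame:
    """Per-category medication and patient burden.

    Returns a frame indexed by category (all 27 plus ``unclassified``,
    zero-filled so empty organ systems are still reported) with columns
    ``n_unique_medications``, ``n_patients`` and ``pct_patients`` (full
    cohort denominator, one decimal). A patient counts once per category
    however many qualifying medications they received; a medication may
    appear under several categories.
    """
    if len(episodes) != len(assignments):
        raise ValueError("episodes and assignments must align one-to-one")
    meds: dict[str, set[str]] = {}
    patients: dict[str, set[str]] = {}
    all_patients: set[str] = set()
    for ep, asg in zip(episodes, assignments):
        all_patients.add(ep.patient_id)
        meds.setdefault(asg.category, set()).add(ep.generic_name)
        patients.setdefault(asg.category, set()).add(ep.patient_id)
    denom = cohort_size if cohort_size is not None else len(all_patients)
    rows = []
    for cat in list(vocabulary.categories) + [UNCLASSIFIED]:
        n_pat = len(patients.get(cat, ()))
        rows.append(
            {
                "category": cat,
                "n_unique_medications": len(meds.get(cat, ())),
                "n_patients": n_pat,
                "pct_patients": pct(n_pat, denom) if denom else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("category")


@dataclass
class ProphylaxisSummary:
    """Cohort-level summary of prophylactically administered medications."""

    n_unique_medications: int
    n_patients: int
    pct_patients: float
    mean_medications_per_patient: float
    range_medications: tuple[int, int] | None
    mean_indications_per_patient: float
    range_indications: tuple[int, int] | None
    per_category_indications: dict[str, int]

    def format(self) -> str:
        if self.range_medications is None:
            return "no prophylactic administrations"
        mlo, mhi = self.range_medications
        ilo, ihi = self.range_indications
        return (
            f"mean medications/patient = {self.mean_medications_per_patient:.1f} "
            f"[range {mlo}–{mhi}]; mean indications/patient = "
            f"{self.mean_indications_per_patient:.1f} [range {ilo}–{ihi}]"
        )

    def to_dict(self) -> dict:
        return {
            "n_unique_medications": self.n_unique_medications,
            "n_patients": self.n_patients,
            "pct_patients": self.pct_patients,
            "mean_medications_per_patient": self.mean_medications_per_patient,
            "range_medications": list(self.range_medications) if self.range_medications else None,
            "mean_indications_per_patient": self.mean_indications_per_patient,
            "range_indications": list(self.range_indications) if self.range_indications else None,
            "per_category_indications": dict(self.per_category_indications),
        }


def prophylaxis_summary(
    episodes: Sequence[MedicationEpisode],
    assignments: Sequence[SOCAssignment],
    cohort_size: int | None = None,
) -> ProphylaxisSummary:
    """Type and frequency of prophylactically administered medications.

    "Indications" counts prophylactic administration records, "medications"
    distinct generic names; per-patient means and ranges are over patients
    with at least one prophylactic medication, while the patient percentage
    uses the full cohort as denominator.
    """
    if len(episodes) != len(assignments):
        raise ValueError("episodes and assignments must align one-to-one")
    meds_by_patient: dict[str, set[str]] = {}
    inds_by_patient: dict[str, int] = {}
    per_category: dict[str, int] = {}
    unique_meds: set[str] = set()
    all_patients: set[str] = set()
    for ep, asg in zip(episodes, assignments):
        all_patients.add(ep.patient_id)
        if not asg.prophylactic:
            continue
        unique_meds.add(ep.generic_name)
        meds_by_patient.setdefault(ep.patient_id, set()).add(ep.generic_name)
        inds_by_patient[ep.patient_id] = inds_by_patient.get(ep.patient_id, 0) + 1
        per_category[asg.category] = per_category.get(asg.category, 0) + 1
    denom = cohort_size if cohort_size is not None else len(all_patients)
    n_pat = len(meds_by_patient)
    if n_pat == 0:
        return ProphylaxisSummary(0, 0, 0.0, 0.0, None, 0.0, None, {})
    med_counts = [len(s) for s in meds_by_patient.values()]
    ind_counts = list(inds_by_patient.values())
    return ProphylaxisSummary(
        n_unique_medications=len(unique_meds),
        n_patients=n_pat,
        pct_patients=pct(n_pat, denom) if denom else 0.0,
        mean_medications_per_patient=round1(sum(med_counts) / n_pat),
        range_medications=(min(med_counts), max(med_counts)),
        mean_indications_per_patient=round1(sum(ind_counts) / n_pat),
        range_indications=(min(ind_counts), max(ind_counts)),
        per_category_indications=dict(sorted(per_category.items())),
    )
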