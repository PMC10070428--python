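"""Blood-brain-barrier permeability annotation of unique medications.

Each unique medication is annotated with one of three states — permeable,
not_permeable, unknown — from a lookup table keyed on the normalized generic
name. Medications absent from the table default to unknown; the package
never attempts physicochemical permeability prediction. A starter table
covering common acute-care medications ships with the package; users can
(and for serious use should) supply their own curated table, e.g. compiled
from DrugBank and the primary literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._utils import pct

BBB_STATES = ("permeable", "not_permeable", "unknown")


@dataclass
class BBBTable:
    """Lookup of normalized medication name → permeability state."""

    states: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = {k.casefold(): v for k, v in self.states.items()}
        bad = {v for v in self.states.values()} - set(BBB_STATES)
        if bad:
            raise ValueError(f"invalid BBB states: {sorted(bad)}")

    def lookup(self, name: str) -> str:
        return self.states.get(name.casefold(), "unknown")

    @classmethod
    def from_file(cls, path: str | Path, sep: str | None = None) -> "BBBTable":
        """Read a 2–3 column delimited file (name, state[, provenance])."""
        if sep is None:
            sep = "\t" if str(path).endswith(".tsv") else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
        for col in ("name", "state"):
            if col not in df.columns:
                raise ValueError(f"BBB table is missing column {col!r}")
        states = dict(zip(df["name"], df["state"]))
        provenance = (
            dict(zip(df["name"], df["provenance"].fillna("unreviewed")))
            if "provenance" in df.columns
            else {}
        )
        return cls(states=states, provenance=provenance)

    @classmethod
    def default(cls) -> "BBBTable":
        ref = resources.files("polypharm.data") / "bbb_starter.tsv"
        with resources.as_file(ref) as path:
            return cls.from_file(path, sep="\t")


def annotate_bbb(medications: Iterable[str], table: BBBTable) -> dict[str, str]:
    """Annotate every input medication; absent names get state ``unknown``.

    Idempotent and independent of input order.
    """
    return {name: table.lookup(name) for name in medications}


@dataclass
class BBBProportions:
    """Three-state split of the unique-medication set."""

    n_total: int
    n_permeable: int
    n_not_permeable: int
    n_unknown: int
    pct_permeable: float
    pct_not_permeable: float
    pct_unknown: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def proportions_from_counts(
    n_permeable: int, n_not_permeable: int, n_unknown: int
) -> BBBProportions:
    """Three-state percentages (one decimal) from raw counts."""
    total = n_permeable + n_not_permeable + n_unknown
    if total == 0:
        raise ValueError("no annotated medications")
    return BBBProportions(
        n_total=total,
        n_permeable=n_permeable,
        n_not_permeable=n_not_permeable,
        n_unknown=n_unknown,
        pct_permeable=pct(n_permeable, total),
        pct_not_permeable=pct(n_not_permeable, total),
        pct_unknown=pct(n_unknown, total),
    )


def bbb_proportions(annotations: Mapping[str, str]) -> BBBProportions:
    """Percentages of permeable / not permeable / unknown medications.

    The denominator is the number of unique annotated medications; counts
    partition it exactly.
    """
    if not annotations:
        raise ValueError("no annotated medications")
    counts = {state: 0 for state in BBB_STATES}
    for state in annotations.values():
        if state not in counts:
            raise ValueError(f"invalid BBB state {state!r}")
        counts[state] += 1
    return proportions_from_counts(
        counts["permeable"], counts["not_permeable"], counts["unknown"]
    )
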