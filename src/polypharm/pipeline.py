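"""End-to-end pipeline: ingest/simulate → filters → exposure → classification
→ BBB → networks → consolidated report.

Everything is a thin orchestration over the library modules. Outputs are
written atomically (temp file + rename) into a fixed layout inside the
output directory, alongside a run manifest recording the configuration,
seed, package version and input checksums, so a run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .bbb import BBBTable, annotate_bbb, bbb_proportions
from .exposure import (
    DEFAULT_HORIZON,
    DEFAULT_WINDOWS,
    daily_exposure,
    medication_frequency,
    point_prevalence,
    prevalence_by_stratum,
    unique_meds_in_window,
    window_summary,
)
from .indications import SOCVocabulary, classify_episodes, prophylaxis_summary, soc_summary
from .network import build_coadmin_network, export_network, rank_combinations
from .records import (
    ColumnMap,
    MedicationEpisode,
    PatientRecord,
    ValidationReport,
    read_medication_log,
    read_patient_table,
    write_episode_table,
    write_patient_table,
)
from .summaries import (
    apply_inclusion_filters,
    build_report,
    demographics_table,
    write_report,
)
from .synth import SyntheticConfig, simulate_cohort

log = logging.getLogger("polypharm")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    output_dir: str
    # either simulate ...
    simulate: bool = False
    synthetic: SyntheticConfig | None = None
    # ... or ingest from files
    patient_table: str | None = None
    medication_log: str | None = None
    column_map: str | None = None

    horizon: int = DEFAULT_HORIZON
    windows: tuple[int, ...] = DEFAULT_WINDOWS
    network_days: tuple[int, ...] = (7, 14)
    min_edge_weight: int = 1
    top_k_combinations: int = 10
    vocabulary_path: str | None = None
    bbb_table_path: str | None = None
    abstraction_cohorts: tuple[str, ...] = ("observational",)
    missing_end: str = "single_day"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if list(self.windows) != sorted(self.windows):
            raise ValueError("windows must be sorted ascending")
        if any(w > self.horizon for w in self.windows):
            raise ValueError("windows must not exceed the horizon")
        if any(d > self.horizon or d < 1 for d in self.network_days):
            raise ValueError("network days must lie within the horizon")
        if not self.simulate and not (self.patient_table and self.medication_log):
            raise ValueError("either simulate=True or both input paths are required")


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_json(path: Path, payload) -> None:
    _atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and populate the output directory.

    Returns the consolidated report dict. Stage outputs are written as they
    complete; on a stage hard-error the manifest records the failure point
    and the exception propagates.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "input_checksums": {},
        "status": "running",
        "failed_stage": None,
    }
    stage = "ingest"
    try:
        # --- ingest or simulate -------------------------------------------
        if config.simulate:
            stage = "simulate"
            syn = config.synthetic or SyntheticConfig()
            syn = dataclasses.replace(syn, seed=config.seed)
            patients, episodes, _truth = simulate_cohort(syn)
            write_patient_table(patients, outdir / "patients.csv")
            write_episode_table(episodes, outdir / "episodes.csv")
            validation = ValidationReport(
                records_read=len(episodes), records_accepted=len(episodes)
            )
            with_eps = {e.patient_id for e in episodes}
            validation.patients_without_episodes = sum(
                1 for p in patients if p.patient_id not in with_eps
            )
        else:
            dialect = ColumnMap.from_yaml(config.column_map) if config.column_map else ColumnMap()
            patients = read_patient_table(config.patient_table, dialect)
            episodes, validation = read_medication_log(
                config.medication_log, dialect, patients
            )
            for p in (config.patient_table, config.medication_log):
                manifest["input_checksums"][p] = _sha256(Path(p))
        _atomic_write_json(outdir / "validation_report.json", validation.to_dict())

        # --- inclusion filters --------------------------------------------
        stage = "filters"
        included, tally = apply_inclusion_filters(
            patients, episodes, config.abstraction_cohorts
        )
        included_ids = {p.patient_id for p in included}
        episodes = [e for e in episodes if e.patient_id in included_ids]
        _atomic_write_json(outdir / "exclusions.json", tally.to_dict())
        if not included:
            raise ValueError("no patients remain after inclusion filters")

        # --- exposure ------------------------------------------------------
        stage = "exposure"
        daily = daily_exposure(
            episodes, config.horizon, included_ids, config.missing_end
        )
        long_rows = [
            {"patient_id": pid, "day": day, "medication": med}
            for pid, exp in sorted(daily.items())
            for day in sorted(exp.active)
            for med in sorted(exp.active[day])
        ]
        pd.DataFrame(long_rows, columns=["patient_id", "day", "medication"]).to_csv(
            outdir / "exposure_long.csv", index=False
        )
        windows_out = {}
        for w in config.windows:
            counts = unique_meds_in_window(episodes, w, included_ids, config.missing_end)
            windows_out[str(w)] = window_summary(counts, w).to_dict()
        _atomic_write_json(outdir / "window_summaries.json", windows_out)

        prevalence = {
            pid: point_prevalence(exp) for pid, exp in sorted(daily.items())
        }
        wide = pd.DataFrame.from_dict(
            {pid: [c[d] for d in range(1, config.horizon + 1)] for pid, c in prevalence.items()},
            orient="index",
            columns=[f"day{d}" for d in range(1, config.horizon + 1)],
        )
        wide.index.name = "patient_id"
        wide.to_csv(outdir / "daily_counts_wide.csv")

        strata = prevalence_by_stratum(daily, included, "ais_grade")
        strata_rows = [
            {"stratum": s.label, "day": d, "mean": m, "min": lo, "max": hi}
            for s in strata
            for d, m, lo, hi in zip(s.days, s.mean, s.min, s.max)
        ]
        pd.DataFrame(strata_rows).to_csv(outdir / "prevalence_by_ais.csv", index=False)

        frequency = medication_frequency(episodes, config.horizon, config.missing_end)
        pd.DataFrame(frequency, columns=["medication", "n_patients"]).to_csv(
            outdir / "medication_frequency.csv", index=False
        )

        # --- indication classification ------------------------------------
        stage = "soc"
        vocabulary = (
            SOCVocabulary.from_yaml(config.vocabulary_path)
            if config.vocabulary_path
            else SOCVocabulary.default()
        )
        assignments = classify_episodes(episodes, vocabulary)
        soc = soc_summary(episodes, assignments, vocabulary, len(included))
        soc.to_csv(outdir / "soc_summary.csv")
        proph = prophylaxis_summary(episodes, assignments, len(included))
        _atomic_write_json(outdir / "prophylaxis.json", proph.to_dict())

        # --- BBB annotation ------------------------------------------------
        stage = "bbb"
        bbb_table = (
            BBBTable.from_file(config.bbb_table_path)
            if config.bbb_table_path
            else BBBTable.default()
        )
        unique_meds = sorted({e.generic_name for e in episodes})
        annotations = annotate_bbb(unique_meds, bbb_table)
        bbb_out = (
            bbb_proportions(annotations).to_dict()
            if annotations
            else {"n_total": 0}
        )
        _atomic_write_json(outdir / "bbb.json", bbb_out)

        # --- networks -------------------------------------------------------
        stage = "network"
        network_summaries = {}
        for day in config.network_days:
            net = build_coadmin_network(daily, day, config.min_edge_weight)
            export_network(net, outdir / f"network_day{day}.tsv", "edgelist")
            export_network(net, outdir / f"network_day{day}.graphml", "graphml")
            network_summaries[str(day)] = net.summary()
        combos = rank_combinations(daily, config.top_k_combinations, window=config.horizon)
        pd.DataFrame(
            [{"med_a": a, "med_b": b, "n_patients": n} for (a, b), n in combos]
        ).to_csv(outdir / "top_combinations.csv", index=False)

        # --- report ---------------------------------------------------------
        stage = "report"
        demo = demographics_table(included)
        demo.to_frame().to_csv(outdir / "demographics.csv", index=False)
        report = build_report(
            {
                "demographics": demo.to_dict(),
                "window_summaries": windows_out,
                "medication_frequency": [list(kv) for kv in frequency[:50]],
                "soc_summary": json.loads(soc.reset_index().to_json(orient="records")),
                "prophylaxis": proph.to_dict(),
                "bbb": bbb_out,
                "networks": network_summaries,
                "top_combinations": [
                    {"pair": [a, b], "n_patients": n} for (a, b), n in combos
                ],
                "exclusions": tally.to_dict(),
                "validation": validation.to_dict(),
                "n_patients_included": len(included),
                "n_unique_medications": len(unique_meds),
            }
        )
        write_report(report, outdir / "report.json")
    except BaseException:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        _atomic_write_json(outdir / "manifest.json", manifest)
        raise
    manifest["status"] = "ok"
    _atomic_write_json(outdir / "manifest.json", manifest)
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("synthetic") and d["synthetic"].get("catalog"):
        # catalog entries are verbose; record only their names
        d["synthetic"]["catalog"] = [e["name"] for e in d["synthetic"]["catalog"]]
    for key in ("windows", "network_days", "abstraction_cohorts"):
        d[key] = list(d[key])
    return d
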