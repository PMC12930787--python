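"""Unit analysis and benchmark reports.

``run_unit_analysis`` chains the whole engine for one unit: eligibility and
windows, exposure denominators, infection classification, stratified
metrics, and the per-cell aggregate a unit shares for benchmarking.  Every
report echoes the definitions-config hash and the day-of-life band edges so
that pooled benchmarks are machine-checkably comparable.

``run_benchmark`` pools unit aggregates into reference rates and returns an
SIR per unit.  Benchmark artifacts contain aggregated data only — no
patient-level rows ever leave the unit report.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .cohort import Cohort, Device, HaiType, SSI_TYPES
from .classify import ClassifiedHAI, classify_cohort
from .config import DefinitionsConfig, catalog_hash, default_organism_catalog
from .eligibility import SurveillanceWindow, build_windows
from .exposure import ExposureSummary, summarize_exposures
from .metrics import (
    StratumAggregate,
    aggregate_by_stratum,
    assign_stratum,
    ssi_rates,
    stratified_metrics,
)
from .sir import (
    ALL_TYPES,
    DEFAULT_BAND_EDGES,
    ReferenceRates,
    SirResult,
    UnitSirAggregate,
    aggregate_reference,
    band_label,
    build_unit_sir_aggregate,
    compute_sir,
)

#: fields that must never appear in any report artifact
FORBIDDEN_IDENTIFIERS = {"name", "patient_name", "hospital_id", "birth_date"}


@dataclass
class UnitAnalysis:
    """Everything the engine derives for one unit from one cohort."""

    windows: Dict[str, SurveillanceWindow]
    summaries: Dict[str, ExposureSummary]
    infections: List[ClassifiedHAI]
    aggregates: Dict[str, StratumAggregate]
    metric_rows: List[dict]
    ssi_rate_table: Dict[str, Optional[float]]
    sir_aggregate: UnitSirAggregate
    sir_results: Dict[str, SirResult] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    metadata: Dict = field(default_factory=dict)


def run_unit_analysis(
    cohort: Cohort,
    definitions: Optional[DefinitionsConfig] = None,
    organism_catalog=None,
    band_edges: Sequence[int] = DEFAULT_BAND_EDGES,
    reference: Optional[ReferenceRates] = None,
    as_of: Optional[dt.date] = None,
) -> UnitAnalysis:
    """Run the full surveillance pipeline for one unit."""
    definitions = definitions or DefinitionsConfig()
    definitions.validate()
    organism_catalog = organism_catalog or default_organism_catalog()
    cohort.validate(organism_catalog=organism_catalog,
                    criterion_codes=definitions.criterion_codes)

    windows = build_windows(cohort, as_of=as_of)
    warnings: List[str] = []
    for w in windows.values():
        warnings.extend(f"{w.patient_id}: {msg}" for msg in w.warnings)

    summaries = {}
    for pid, window in windows.items():
        if not window.included:
            continue
        summaries[pid] = summarize_exposures(
            cohort.exposures, window, definitions)
        warnings.extend(f"{pid}: {msg}" for msg in summaries[pid].warnings)

    infections, class_warnings = classify_cohort(
        cohort, windows, definitions, organism_catalog)
    warnings.extend(class_warnings)

    included_patients = [p for p in cohort.patients
                         if windows[p.patient_id].included]
    aggregates = aggregate_by_stratum(included_patients, summaries,
                                      infections)
    metric_rows = stratified_metrics(aggregates)

    ssi_cases = [h for h in infections if h.hai_type in SSI_TYPES]
    included_ids = {p.patient_id for p in included_patients}
    unit_surgeries = [s for s in cohort.surgeries
                      if s.patient_id in included_ids]
    ssi_table = ssi_rates(ssi_cases, unit_surgeries)

    sir_aggregate = build_unit_sir_aggregate(
        included_patients, windows, infections, band_edges)

    analysis = UnitAnalysis(
        windows=windows,
        summaries=summaries,
        infections=infections,
        aggregates=aggregates,
        metric_rows=metric_rows,
        ssi_rate_table=ssi_table,
        sir_aggregate=sir_aggregate,
        warnings=warnings,
        metadata={
            "engine_version": __version__,
            "definitions_hash": definitions.config_hash(),
            "catalog_hash": catalog_hash(organism_catalog),
            "band_edges": list(band_edges),
            "n_patients_total": len(cohort.patients),
            "n_patients_included": len(included_patients),
            "secondary_bsi_enabled": definitions.secondary_bsi_enabled,
        },
    )
    if reference is not None:
        keys = sorted(set(reference.rates) | {ALL_TYPES})
        analysis.sir_results = {
            key: compute_sir(sir_aggregate, reference, key) for key in keys
        }
    return analysis


# ---------------------------------------------------------------------------
# serialisation

def _round2(value):
    return None if value is None else round(value, 2)


def hai_line_rows(infections: Sequence[ClassifiedHAI]) -> List[dict]:
    return [{
        "patient_id": h.patient_id,
        "hai_type": h.hai_type.value,
        "infection_date": h.infection_date.isoformat(),
        "day_of_life": h.day_of_life,
        "late_onset": h.late_onset,
        "device_association": h.device_association.value
        if h.device_association else "",
        "linked_surgery_id": h.linked_surgery_id or "",
        "organisms": ";".join(o for o, _ in h.organisms),
        "is_mdro": h.is_mdro,
        "mdro_markers": ";".join(sorted(m.value for m in h.mdro_markers)),
        "secondary_to": h.secondary_to or "",
    } for h in infections]


def sir_aggregate_to_json(agg: UnitSirAggregate, metadata: dict) -> dict:
    return {
        "metadata": metadata,
        "band_edges": list(agg.band_edges),
        "cells": [
            {
                "stratum": cell[0],
                "band": cell[1],
                "band_label": band_label(cell[1], agg.band_edges),
                "patient_days": days,
                "observed": {
                    key: agg.observed.get(key, {}).get(cell, 0)
                    for key in sorted(agg.observed)
                },
            }
            for cell, days in sorted(agg.patient_days.items())
        ],
    }


def sir_aggregate_from_json(doc: dict) -> UnitSirAggregate:
    cells = doc["cells"]
    patient_days = {(c["stratum"], int(c["band"])): int(c["patient_days"])
                    for c in cells}
    observed: Dict[str, Dict] = {}
    for c in cells:
        cell = (c["stratum"], int(c["band"]))
        for key, n in c["observed"].items():
            if n:
                observed.setdefault(key, {})[cell] = int(n)
    observed.setdefault(ALL_TYPES, {})
    return UnitSirAggregate(tuple(doc["band_edges"]), patient_days, observed)


def check_no_identifiers(obj) -> None:
    """Recursively assert a report object carries no direct identifier."""
    if isinstance(obj, dict):
        for key, value in obj.items():
            if key in FORBIDDEN_IDENTIFIERS:
                raise ValueError(
                    f"report contains forbidden identifier field {key!r}"
                )
            check_no_identifiers(value)
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            check_no_identifiers(item)


def write_unit_report(analysis: UnitAnalysis, output_dir) -> Dict[str, Path]:
    """Write the unit report: line list, exposure summary, metrics (CSV with
    2-decimal rates, JSON at full precision), the shareable SIR aggregate,
    and report.json with metadata and warnings."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    rows = hai_line_rows(analysis.infections)
    paths["hai_line_list"] = out / "hai_line_list.csv"
    pd.DataFrame(rows, columns=[
        "patient_id", "hai_type", "infection_date", "day_of_life",
        "late_onset", "device_association", "linked_surgery_id",
        "organisms", "is_mdro", "mdro_markers", "secondary_to",
    ]).to_csv(paths["hai_line_list"], index=False)

    exp_rows = [{
        "patient_id": s.patient_id,
        "patient_days": s.patient_days,
        **{f"{d.value.lower()}_days": s.device_days[d] for d in Device},
        "antibiotic_days": s.antibiotic_days_total,
        "breast_milk_days": s.breast_milk_days,
        "probiotic_days": s.probiotic_days,
        "kangaroo_days": s.kangaroo_days,
    } for s in analysis.summaries.values()]
    paths["exposure_summary"] = out / "exposure_summary.csv"
    pd.DataFrame(exp_rows, columns=[
        "patient_id", "patient_days", "cvc_days", "pvc_days", "inv_days",
        "niv_days", "antibiotic_days", "breast_milk_days", "probiotic_days",
        "kangaroo_days",
    ]).to_csv(paths["exposure_summary"], index=False)

    csv_rows = [
        {**row, "value": _round2(row["value"])
         if isinstance(row["value"], float) else row["value"]}
        for row in analysis.metric_rows
    ]
    paths["metrics_csv"] = out / "metrics.csv"
    pd.DataFrame(csv_rows).to_csv(paths["metrics_csv"], index=False)
    paths["metrics_json"] = out / "metrics.json"
    with open(paths["metrics_json"], "w", encoding="utf-8") as fh:
        json.dump({
            "metadata": analysis.metadata,
            "metrics": analysis.metric_rows,
            "ssi_rates": analysis.ssi_rate_table,
        }, fh, indent=2, default=str)

    agg_doc = sir_aggregate_to_json(analysis.sir_aggregate,
                                    analysis.metadata)
    check_no_identifiers(agg_doc)
    paths["sir_aggregate"] = out / "sir_aggregate.json"
    with open(paths["sir_aggregate"], "w", encoding="utf-8") as fh:
        json.dump(agg_doc, fh, indent=2)

    if analysis.sir_results:
        sir_rows = [{
            "infection": key,
            "observed": res.observed,
            "expected": _round2(res.expected),
            "sir": _round2(res.sir),
        } for key, res in sorted(analysis.sir_results.items())]
        paths["sir_csv"] = out / "sir_report.csv"
        pd.DataFrame(sir_rows).to_csv(paths["sir_csv"], index=False)
        paths["sir_json"] = out / "sir_report.json"
        with open(paths["sir_json"], "w", encoding="utf-8") as fh:
            json.dump({
                "metadata": analysis.metadata,
                "results": {
                    key: {"observed": res.observed,
                          "expected": res.expected,
                          "sir": res.sir,
                          "warnings": res.warnings}
                    for key, res in analysis.sir_results.items()
                },
            }, fh, indent=2)

    report_doc = {
        "metadata": analysis.metadata,
        "n_infections": len(analysis.infections),
        "warnings": analysis.warnings,
    }
    paths["report"] = out / "report.json"
    with open(paths["report"], "w", encoding="utf-8") as fh:
        json.dump(report_doc, fh, indent=2)
    return paths


# ---------------------------------------------------------------------------
# benchmark level

def run_benchmark(
    unit_aggregates: Sequence[UnitSirAggregate],
    unit_metadata: Optional[Sequence[dict]] = None,
) -> Dict:
    """Pool unit aggregates into reference rates and benchmark each unit.

    Units must share the definitions-config hash and band edges; anything
    else makes strata/bands incomparable and is an error.
    """
    if unit_metadata:
        hashes = {m.get("definitions_hash") for m in unit_metadata}
        if len(hashes) > 1:
            raise ValueError(
                f"definitions config hashes differ between units: {hashes}; "
                "benchmark would not be comparable"
            )
    reference = aggregate_reference(list(unit_aggregates))
    per_unit = []
    for i, agg in enumerate(unit_aggregates):
        results = {
            key: compute_sir(agg, reference, key)
            for key in sorted(reference.rates)
        }
        per_unit.append({
            "unit": i,
            "sir": {
                key: {"observed": r.observed, "expected": r.expected,
                      "sir": r.sir}
                for key, r in results.items()
            },
        })
    return {"reference": reference, "units": per_unit}
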