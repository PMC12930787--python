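"""Standardized infection ratio (SIR) and reference-rate benchmarking.

Expected infection counts are an indirect standardization over two risk
variables: birth-weight stratum and day-of-life band.  Each surveillance day
of each patient falls into exactly one (stratum x band) cell; expected
infections are the sum over cells of the cell's reference rate (infections
per patient-day) times the unit's patient-days in that cell, and

    SIR = observed / expected.

1.0 means the unit matches the reference; above/below means more/fewer
infections than expected given its case mix.  Day-of-life band edges are a
configuration choice and are echoed into every report: benchmarks are only
comparable across identical bands.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .cohort import HaiType, PatientRecord, ValidationError
from .classify import ClassifiedHAI
from .eligibility import SurveillanceWindow
from .exposure import day_of_life
from .metrics import assign_stratum

#: default day-of-life band lower edges: bands 1-3, 4-7, 8-14, 15-28, >=29
DEFAULT_BAND_EDGES: Tuple[int, ...] = (1, 4, 8, 15, 29)

#: key used for the all-types SIR alongside per-type keys
ALL_TYPES = "all"

Cell = Tuple[str, int]  # (birth-weight stratum, band index)


def band_index(dol: int, band_edges: Sequence[int]) -> int:
    """Index of the day-of-life band containing day ``dol`` (1-based)."""
    if dol < band_edges[0]:
        raise ValidationError(f"day of life {dol} below first band edge")
    idx = 0
    for i, edge in enumerate(band_edges):
        if dol >= edge:
            idx = i
    return idx


def band_label(idx: int, band_edges: Sequence[int]) -> str:
    start = band_edges[idx]
    if idx + 1 < len(band_edges):
        return f"{start}-{band_edges[idx + 1] - 1}"
    return f">={start}"


def _check_edges(band_edges: Sequence[int]) -> None:
    if not band_edges or band_edges[0] != 1:
        raise ValidationError("band edges must start at day of life 1")
    if list(band_edges) != sorted(set(band_edges)):
        raise ValidationError("band edges must be strictly increasing")


# ---------------------------------------------------------------------------

def tabulate_risk_days(
    windows: Dict[str, SurveillanceWindow],
    patients: Sequence[PatientRecord],
    band_edges: Sequence[int] = DEFAULT_BAND_EDGES,
) -> Dict[Cell, int]:
    """Patient-days per (stratum x day-of-life band) cell.

    Every surveillance day lands in exactly one cell, so the cell sums equal
    total patient-days.
    """
    _check_edges(band_edges)
    table: Dict[Cell, int] = {}
    by_id = {p.patient_id: p for p in patients}
    for pid, window in windows.items():
        if not window.included:
            continue
        patient = by_id[pid]
        stratum = assign_stratum(patient.birth_weight)
        for day in window.surveillance_days:
            cell = (stratum,
                    band_index(day_of_life(day, patient.birth_date),
                               band_edges))
            table[cell] = table.get(cell, 0) + 1
    return table


def tabulate_observed(
    infections: Sequence[ClassifiedHAI],
    patients: Sequence[PatientRecord],
    band_edges: Sequence[int] = DEFAULT_BAND_EDGES,
) -> Dict[str, Dict[Cell, int]]:
    """Observed infections per cell, keyed by infection type plus 'all'."""
    _check_edges(band_edges)
    by_id = {p.patient_id: p for p in patients}
    out: Dict[str, Dict[Cell, int]] = {ALL_TYPES: {}}
    for hai in infections:
        patient = by_id[hai.patient_id]
        cell = (assign_stratum(patient.birth_weight),
                band_index(hai.day_of_life, band_edges))
        for key in (ALL_TYPES, hai.hai_type.value):
            cells = out.setdefault(key, {})
            cells[cell] = cells.get(cell, 0) + 1
    return out


@dataclass
class ReferenceRates:
    """Reference infections per patient-day for each (stratum x band) cell,
    per infection type plus pooled ('all')."""

    band_edges: Tuple[int, ...] = DEFAULT_BAND_EDGES
    rates: Dict[str, Dict[Cell, float]] = field(default_factory=dict)

    def validate(self) -> None:
        _check_edges(self.band_edges)
        for key, cells in self.rates.items():
            for cell, rate in cells.items():
                if rate < 0:
                    raise ValidationError(
                        f"reference rate for {key} cell {cell} is negative"
                    )

    def to_yaml(self, path) -> None:
        doc = {
            "band_edges": list(self.band_edges),
            "rates": {
                key: [
                    {"stratum": cell[0], "band": cell[1], "rate": rate}
                    for cell, rate in sorted(cells.items())
                ]
                for key, cells in self.rates.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ReferenceRates":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        rates = {
            key: {(row["stratum"], int(row["band"])): float(row["rate"])
                  for row in rows}
            for key, rows in doc["rates"].items()
        }
        ref = cls(tuple(doc["band_edges"]), rates)
        ref.validate()
        return ref


@dataclass
class SirResult:
    """Observed vs expected infection counts and their ratio; the ratio is
    absent (with the observed count still reported) when expected is 0."""

    observed: int
    expected: float
    sir: Optional[float]
    warnings: List[str] = field(default_factory=list)


def expected_infections(
    risk_day_table: Dict[Cell, int],
    cell_rates: Dict[Cell, float],
) -> float:
    """Sum over occupied cells of rate x patient-days; an occupied cell
    missing from the reference is an error naming the cell."""
    total = 0.0
    for cell, days in sorted(risk_day_table.items()):
        if days == 0:
            continue
        if cell not in cell_rates:
            raise ValidationError(
                f"reference has no rate for occupied cell "
                f"(stratum {cell[0]!r}, band {cell[1]})"
            )
        total += cell_rates[cell] * days
    return total


def standardized_infection_ratio(observed: int, expected: float) -> SirResult:
    """observed / expected; incalculable (None) when expected is 0."""
    if observed < 0 or expected < 0:
        raise ValidationError("observed and expected must be non-negative")
    if expected == 0:
        warnings = []
        if observed > 0:
            warnings.append(
                f"SIR incalculable: {observed} infections observed but 0 "
                "expected"
            )
        return SirResult(observed, expected, None, warnings)
    return SirResult(observed, expected, observed / expected)


# ---------------------------------------------------------------------------
# unit aggregates and reference pooling

@dataclass
class UnitSirAggregate:
    """Per-cell patient-days and observed infections for one unit; the only
    thing a unit shares for benchmarking (aggregates, never patient rows)."""

    band_edges: Tuple[int, ...]
    patient_days: Dict[Cell, int]
    observed: Dict[str, Dict[Cell, int]]

    def total_observed(self, key: str = ALL_TYPES) -> int:
        return sum(self.observed.get(key, {}).values())


def build_unit_sir_aggregate(
    patients: Sequence[PatientRecord],
    windows: Dict[str, SurveillanceWindow],
    infections: Sequence[ClassifiedHAI],
    band_edges: Sequence[int] = DEFAULT_BAND_EDGES,
) -> UnitSirAggregate:
    return UnitSirAggregate(
        band_edges=tuple(band_edges),
        patient_days=tabulate_risk_days(windows, patients, band_edges),
        observed=tabulate_observed(infections, patients, band_edges),
    )


def aggregate_reference(
    units: Sequence[UnitSirAggregate],
) -> ReferenceRates:
    """Pool unit aggregates into reference rates: per cell, pooled rate =
    total infections / total patient-days.  All units must share band
    edges."""
    if not units:
        raise ValidationError("at least one unit aggregate is required")
    edges = units[0].band_edges
    for u in units[1:]:
        if u.band_edges != edges:
            raise ValidationError(
                f"band edges differ between units: {edges} vs {u.band_edges}"
            )
    pooled_days: Dict[Cell, int] = {}
    pooled_obs: Dict[str, Dict[Cell, int]] = {}
    for u in units:
        for cell, days in u.patient_days.items():
            pooled_days[cell] = pooled_days.get(cell, 0) + days
        for key, cells in u.observed.items():
            dst = pooled_obs.setdefault(key, {})
            for cell, n in cells.items():
                dst[cell] = dst.get(cell, 0) + n
    rates: Dict[str, Dict[Cell, float]] = {}
    keys = set(pooled_obs) | {ALL_TYPES}
    for key in keys:
        cells = {}
        for cell, days in pooled_days.items():
            if days > 0:
                cells[cell] = pooled_obs.get(key, {}).get(cell, 0) / days
        rates[key] = cells
    ref = ReferenceRates(edges, rates)
    ref.validate()
    return ref


def compute_sir(
    unit: UnitSirAggregate,
    reference: ReferenceRates,
    key: str = ALL_TYPES,
) -> SirResult:
    """SIR of one unit against a reference, overall or per infection type."""
    if unit.band_edges != reference.band_edges:
        raise ValidationError(
            "unit and reference use different day-of-life bands; "
            "benchmarks are not comparable"
        )
    cell_rates = reference.rates.get(key)
    if cell_rates is None:
        # no reference signal at all for this infection type
        expected = 0.0
    else:
        expected = expected_infections(unit.patient_days, cell_rates)
    return standardized_infection_ratio(unit.total_observed(key), expected)
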