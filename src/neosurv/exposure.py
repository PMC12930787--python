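"""Denominators and risk/protective-factor day counts.

All factors are counted in whole surveillance days.  A device-day requires at
least 12 cumulative hours of the device on that day; a kangaroo-care day
requires at least 2 hours of skin-to-skin contact; antibiotic, exclusive
breast-milk and probiotic days are presence flags.  Antibiotic days are kept
both cumulatively (any substance) and per substance.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

from .cohort import DailyExposureRecord, Device, Feeding, ValidationError
from .config import DefinitionsConfig
from .eligibility import SurveillanceWindow


def day_of_life(date: dt.date, birth_date: dt.date) -> int:
    """1-based day of life: the day of birth is day 1."""
    if date < birth_date:
        raise ValidationError(
            f"date {date} precedes birth date {birth_date}"
        )
    return (date - birth_date).days + 1


@dataclass
class ExposureSummary:
    """Per-patient day counts feeding the unit-level denominators."""

    patient_id: str
    patient_days: int = 0
    device_days: Dict[Device, int] = field(
        default_factory=lambda: {d: 0 for d in Device})
    antibiotic_days_total: int = 0
    antibiotic_days_by_substance: Dict[str, int] = field(default_factory=dict)
    breast_milk_days: int = 0
    probiotic_days: int = 0
    kangaroo_days: int = 0
    warnings: List[str] = field(default_factory=list)


def compute_patient_days(window: SurveillanceWindow) -> int:
    """Count of surveillance days; any presence on a calendar day counts as
    one full patient-day (no minimum time)."""
    return len(window.surveillance_days)


def is_device_day(record: DailyExposureRecord, device: Device,
                  config: DefinitionsConfig) -> bool:
    return record.device_hours(device) >= config.device_day_min_hours


def compute_device_days(
    exposures: Sequence[DailyExposureRecord],
    window: SurveillanceWindow,
    device: Device,
    config: DefinitionsConfig | None = None,
) -> int:
    """Days within the window on which the device was in place for at least
    the qualifying 12 cumulative hours."""
    config = config or DefinitionsConfig()
    days = set(window.surveillance_days)
    return sum(
        1 for e in exposures
        if e.patient_id == window.patient_id and e.date in days
        and is_device_day(e, device, config)
    )


def summarize_exposures(
    exposures: Sequence[DailyExposureRecord],
    window: SurveillanceWindow,
    config: DefinitionsConfig | None = None,
) -> ExposureSummary:
    """All factor-day counts for one patient; rows outside the surveillance
    window are ignored with a warning."""
    config = config or DefinitionsConfig()
    summary = ExposureSummary(window.patient_id)
    summary.patient_days = compute_patient_days(window)
    days = set(window.surveillance_days)

    for e in exposures:
        if e.patient_id != window.patient_id:
            continue
        if e.date not in days:
            summary.warnings.append(
                f"exposure row on {e.date} is outside the surveillance "
                "window; ignored"
            )
            continue
        for device in Device:
            if is_device_day(e, device, config):
                summary.device_days[device] += 1
        if e.antibiotic_substances:
            summary.antibiotic_days_total += 1
            for substance in e.antibiotic_substances:
                summary.antibiotic_days_by_substance[substance] = (
                    summary.antibiotic_days_by_substance.get(substance, 0) + 1
                )
        if e.enteral_feeding is Feeding.exclusive_breast_milk:
            summary.breast_milk_days += 1
        if e.probiotic_given:
            summary.probiotic_days += 1
        if e.kangaroo_hours >= config.kangaroo_min_hours:
            summary.kangaroo_days += 1
    return summary


def device_day_dates(
    exposures: Iterable[DailyExposureRecord],
    window: SurveillanceWindow,
    device: Device,
    config: DefinitionsConfig,
) -> set:
    """The set of qualifying device-day dates, used by the device-association
    rule in the classifier."""
    days = set(window.surveillance_days)
    return {
        e.date for e in exposures
        if e.patient_id == window.patient_id and e.date in days
        and is_device_day(e, device, config)
    }
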