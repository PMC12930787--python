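"""Inclusion criteria and surveillance-window computation.

The surveillance population is very-low-birth-weight (< 1500 g) and/or very
preterm (< 32 completed weeks) live-born infants admitted to the unit within
120 days of birth.  Follow-up runs until death, discharge or transfer, except
that short absences of up to 48 hours are bridged: consecutive unit stays
separated by at most 48 hours belong to one surveillance episode, with the
absent days themselves not counted as surveillance days.

With date-granular data the gap between two stays is measured as 24 h per
full calendar day strictly between them, so a two-day absence (48 h) merges
and a three-day absence does not.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .cohort import (
    Cohort,
    EndReason,
    PatientRecord,
    StayInterval,
    ValidationError,
)

#: eligibility thresholds
BIRTH_WEIGHT_LIMIT_G = 1500
GESTATIONAL_AGE_LIMIT_WEEKS = 32
ADMISSION_WINDOW_DAYS = 120
ABSENCE_MERGE_HOURS = 48


@dataclass
class SurveillanceWindow:
    """The set of calendar days one patient is under surveillance."""

    patient_id: str
    included: bool
    exclusion_reason: Optional[str] = None
    surveillance_days: Tuple[dt.date, ...] = ()
    end_reason: Optional[EndReason] = None
    warnings: List[str] = field(default_factory=list)

    @property
    def patient_days(self) -> int:
        return len(self.surveillance_days)

    @property
    def first_day(self) -> Optional[dt.date]:
        return self.surveillance_days[0] if self.surveillance_days else None

    @property
    def last_day(self) -> Optional[dt.date]:
        return self.surveillance_days[-1] if self.surveillance_days else None


def assess_eligibility(patient: PatientRecord) -> Tuple[bool, Optional[str]]:
    """Decide inclusion; total function returning (included, reason).

    Inclusion requires: live birth, AND (birth weight < 1500 g OR gestational
    age < 32 completed weeks), AND admission within 120 days of birth.  Both
    weight and age comparisons are strict, so 1500 g with 32+0 weeks is
    excluded while 1499 g or 31+6 qualifies.
    """
    if not patient.live_born:
        return False, "not_live_born"
    vlbw = patient.birth_weight < BIRTH_WEIGHT_LIMIT_G
    vpt = (patient.gestational_age_days_total
           < 7 * GESTATIONAL_AGE_LIMIT_WEEKS)
    if not (vlbw or vpt):
        return False, "neither_vlbw_nor_vpt"
    if (patient.admission_date - patient.birth_date).days > ADMISSION_WINDOW_DAYS:
        return False, "admitted_after_120_days"
    return True, None


def gap_hours(earlier_end: dt.date, later_start: dt.date) -> int:
    """Absence length between two stays at date granularity: 24 h per full
    calendar day strictly between them."""
    full_days_between = (later_start - earlier_end).days - 1
    return 24 * max(full_days_between, 0)


def _effective_end(stay: StayInterval, patient: PatientRecord,
                   as_of: Optional[dt.date]) -> dt.date:
    if stay.end_date is not None:
        return stay.end_date
    if patient.end_date is not None:
        return patient.end_date
    if as_of is not None:
        return as_of
    return stay.start_date


def compute_surveillance_window(
    patient: PatientRecord,
    stays: Sequence[StayInterval],
    as_of: Optional[dt.date] = None,
) -> SurveillanceWindow:
    """Merge stays into one follow-up episode and enumerate its days.

    Stays whose between-gap is at most 48 h are merged; surveillance ends at
    the first longer gap (end reason discharge/transfer) or at the recorded
    end of surveillance.  Stays after a longer gap are reported as a warning
    and excluded (re-enrollment is not part of the core episode).  Days fully
    absent during a bridged gap are not surveillance days.

    ``as_of`` caps open-ended stays when the patient record itself is still
    open (interim analysis date).
    """
    included, reason = assess_eligibility(patient)
    window = SurveillanceWindow(patient.patient_id, included, reason)
    if not included:
        return window

    mine = sorted(
        (s for s in stays if s.patient_id == patient.patient_id),
        key=lambda s: s.start_date,
    )
    if not mine:
        window.warnings.append("no stay intervals recorded")
        window.included = False
        window.exclusion_reason = "no_stays"
        return window

    # overlap check on the sorted intervals
    for a, b in zip(mine, mine[1:]):
        a_end = _effective_end(a, patient, as_of)
        if b.start_date <= a_end:
            raise ValidationError(
                f"{patient.patient_id}: stay intervals overlap "
                f"({a.start_date}..{a_end} and {b.start_date}..)"
            )

    episode = [mine[0]]
    truncated = False
    for stay in mine[1:]:
        prev_end = _effective_end(episode[-1], patient, as_of)
        if gap_hours(prev_end, stay.start_date) <= ABSENCE_MERGE_HOURS:
            episode.append(stay)
        else:
            truncated = True
            window.warnings.append(
                f"stay starting {stay.start_date} follows an absence "
                "longer than 48 h; treated as a separate (unreported) "
                "surveillance episode"
            )

    days: List[dt.date] = []
    hard_end = patient.end_date
    for stay in episode:
        start = max(stay.start_date, patient.admission_date)
        end = _effective_end(stay, patient, as_of)
        if hard_end is not None:
            end = min(end, hard_end)
        d = start
        while d <= end:
            days.append(d)
            d += dt.timedelta(days=1)
    window.surveillance_days = tuple(sorted(set(days)))

    if truncated:
        window.end_reason = EndReason.discharge_or_transfer
    else:
        window.end_reason = patient.end_reason
    if not window.surveillance_days:
        window.included = False
        window.exclusion_reason = "no_surveillance_days"
    return window


def build_windows(cohort: Cohort, as_of: Optional[dt.date] = None) -> dict:
    """Surveillance window per patient (included or not) for a whole cohort."""
    return {
        p.patient_id: compute_surveillance_window(p, cohort.stays, as_of)
        for p in cohort.patients
    }
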