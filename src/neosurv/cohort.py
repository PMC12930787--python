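"""Domain types for neonatal infection-surveillance inputs.

The surveillance engine consumes six patient-level tables: demographics and
admission data, unit-stay intervals, one-row-per-patient-day exposure records,
surgeries, clinical/laboratory/imaging findings, and microbiology results.
Every type here is a plain dataclass with an explicit ``validate`` hook so the
CSV readers can report the exact row and rule that failed.

Conventions
-----------
* Dates are ISO-8601 calendar dates; birth may optionally carry a time of day
  so that hour-based rules (72 h onset cut-off) can use exact arithmetic.
* Patient identifiers are opaque pseudonyms.  The engine never sees names,
  hospital numbers or other direct identifiers.
* The exposure table is wide (one row per patient-day) because every factor is
  counted in whole days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import FrozenSet, Optional, Tuple


class Sex(str, Enum):
    male = "male"
    female = "female"
    undetermined = "undetermined"


class DeliveryMode(str, Enum):
    vaginal = "vaginal"
    elective_cesarean = "elective_cesarean"
    emergency_cesarean = "emergency_cesarean"


class AdmissionType(str, Enum):
    delivery_room = "delivery_room"
    transfer_day_of_birth = "transfer_day_of_birth"
    transfer_later = "transfer_later"


class EndReason(str, Enum):
    discharge_or_transfer = "discharge_or_transfer"
    death = "death"


class Feeding(str, Enum):
    none = "none"
    exclusive_breast_milk = "exclusive_breast_milk"
    mixed_or_formula = "mixed_or_formula"


class FindingCategory(str, Enum):
    clinical = "clinical"
    laboratory = "laboratory"
    imaging = "imaging"
    surgical_evidence = "surgical_evidence"


class BodySystem(str, Enum):
    bloodstream = "bloodstream"
    respiratory = "respiratory"
    gastrointestinal = "gastrointestinal"
    surgical_site = "surgical_site"
    other = "other"


class SpecimenType(str, Enum):
    blood = "blood"
    respiratory = "respiratory"
    wound = "wound"
    other = "other"


#: Body system a specimen type speaks for when an episode is assembled.
SPECIMEN_BODY_SYSTEM = {
    SpecimenType.blood: BodySystem.bloodstream,
    SpecimenType.respiratory: BodySystem.respiratory,
    SpecimenType.wound: BodySystem.surgical_site,
    SpecimenType.other: BodySystem.other,
}


class ResistanceMarker(str, Enum):
    MRSA = "MRSA"
    VRE = "VRE"
    THIRD_GEN_CEPH_R = "3GCR"
    carbapenem_resistant = "carbapenem_resistant"
    colistin_resistant = "colistin_resistant"


class OrganismClass(str, Enum):
    recognized_pathogen = "recognized_pathogen"
    common_commensal = "common_commensal"


class Device(str, Enum):
    CVC = "CVC"  # central venous catheter
    PVC = "PVC"  # peripheral venous catheter
    INV = "INV"  # invasive ventilation
    NIV = "NIV"  # noninvasive ventilation


class WoundClass(str, Enum):
    clean = "clean"
    clean_contaminated = "clean_contaminated"
    contaminated = "contaminated"
    dirty = "dirty"


class HaiType(str, Enum):
    clinical_sepsis = "clinical_sepsis"
    lcbsi_pathogen = "lcbsi_pathogen"
    lcbsi_commensal = "lcbsi_commensal"
    secondary_bsi = "secondary_bsi"
    pneumonia = "pneumonia"
    nec = "nec"
    ssi_superficial = "ssi_superficial"
    ssi_deep = "ssi_deep"
    ssi_organ_space = "ssi_organ_space"


#: Infection types eligible for venous-catheter association.
BSI_TYPES = frozenset(
    {HaiType.clinical_sepsis, HaiType.lcbsi_pathogen, HaiType.lcbsi_commensal}
)
SSI_TYPES = frozenset(
    {HaiType.ssi_superficial, HaiType.ssi_deep, HaiType.ssi_organ_space}
)


class ValidationError(ValueError):
    """A domain invariant was violated; message names the record and rule."""


@dataclass(frozen=True)
class PatientRecord:
    """One infant's demographics, admission and end-of-surveillance data.

    Gestational age is expressed in completed weeks plus days (25 weeks and
    4 days -> ``ga_weeks=25, ga_days=4``).  ``end_date``/``end_reason`` are
    absent while the stay is still open (censoring open).  ``live_born``
    defaults to True; stillbirths and delivery-room deaths are expected to be
    pre-filtered but are re-checked when the flag is supplied.
    """

    patient_id: str
    ga_weeks: int
    ga_days: int
    birth_weight: int
    sex: Sex
    delivery_mode: DeliveryMode
    multiple_birth: int
    birth_date: dt.date
    admission_type: AdmissionType
    admission_date: dt.date
    birth_time: Optional[dt.time] = None
    end_date: Optional[dt.date] = None
    end_reason: Optional[EndReason] = None
    live_born: bool = True

    def validate(self) -> None:
        pid = self.patient_id
        if not pid:
            raise ValidationError("patient_id must be non-empty")
        if self.birth_weight <= 0:
            raise ValidationError(f"{pid}: birth_weight must be > 0 g")
        if not 0 <= self.ga_days <= 6:
            raise ValidationError(f"{pid}: gestational-age days must be 0..6")
        if self.ga_weeks < 0:
            raise ValidationError(f"{pid}: gestational-age weeks must be >= 0")
        if self.multiple_birth < 1:
            raise ValidationError(f"{pid}: multiple_birth must be >= 1")
        if self.admission_date < self.birth_date:
            raise ValidationError(f"{pid}: admission_date precedes birth_date")
        if self.end_date is not None and self.end_date < self.admission_date:
            raise ValidationError(f"{pid}: end_date precedes admission_date")
        if (self.end_date is None) != (self.end_reason is None):
            raise ValidationError(
                f"{pid}: end_reason must be present exactly when end_date is"
            )

    @property
    def gestational_age_days_total(self) -> int:
        return 7 * self.ga_weeks + self.ga_days

    def birth_datetime(self) -> Optional[dt.datetime]:
        if self.birth_time is None:
            return None
        return dt.datetime.combine(self.birth_date, self.birth_time)


@dataclass(frozen=True)
class StayInterval:
    """One contiguous presence of a patient on the unit; ``end_date`` may be
    open (None) for an ongoing stay."""

    patient_id: str
    start_date: dt.date
    end_date: Optional[dt.date] = None

    def validate(self) -> None:
        if self.end_date is not None and self.end_date < self.start_date:
            raise ValidationError(
                f"{self.patient_id}: stay end {self.end_date} precedes "
                f"start {self.start_date}"
            )


@dataclass(frozen=True)
class DailyExposureRecord:
    """One patient x calendar-day row of device hours, antibiotics, feeding,
    probiotic and kangaroo-care exposure."""

    patient_id: str
    date: dt.date
    cvc_hours: float = 0.0
    pvc_hours: float = 0.0
    inv_hours: float = 0.0
    niv_hours: float = 0.0
    antibiotic_substances: FrozenSet[str] = frozenset()
    enteral_feeding: Feeding = Feeding.none
    probiotic_given: bool = False
    kangaroo_hours: float = 0.0

    def device_hours(self, device: Device) -> float:
        return {
            Device.CVC: self.cvc_hours,
            Device.PVC: self.pvc_hours,
            Device.INV: self.inv_hours,
            Device.NIV: self.niv_hours,
        }[device]

    def validate(self) -> None:
        for name in ("cvc_hours", "pvc_hours", "inv_hours", "niv_hours",
                     "kangaroo_hours"):
            value = getattr(self, name)
            if not 0.0 <= value <= 24.0:
                raise ValidationError(
                    f"{self.patient_id} {self.date}: {name}={value} "
                    "outside [0, 24]"
                )


@dataclass(frozen=True)
class SurgeryRecord:
    surgery_id: str
    patient_id: str
    description: str
    date: dt.date
    duration_minutes: int
    main_procedure_code: str
    asa_score: int
    wound_class: WoundClass
    side_procedure_codes: Tuple[str, ...] = ()
    endoscopic: bool = False
    emergency: bool = False
    revision: bool = False
    primary_wound_closure: bool = True
    implant: bool = False
    infection_signs_at_surgery: bool = False

    def validate(self) -> None:
        if self.duration_minutes <= 0:
            raise ValidationError(
                f"surgery {self.surgery_id}: duration_minutes must be > 0"
            )
        if not 1 <= self.asa_score <= 5:
            raise ValidationError(
                f"surgery {self.surgery_id}: asa_score must be 1..5"
            )
        if not self.main_procedure_code:
            raise ValidationError(
                f"surgery {self.surgery_id}: main_procedure_code required"
            )


@dataclass(frozen=True)
class Finding:
    """A dated clinical, laboratory, imaging or surgical-evidence criterion
    hit, keyed into the active definitions configuration."""

    patient_id: str
    date: dt.date
    category: FindingCategory
    criterion_code: str
    body_system_hint: BodySystem

    def validate(self) -> None:
        if not self.criterion_code:
            raise ValidationError(
                f"{self.patient_id} {self.date}: empty criterion_code"
            )


@dataclass(frozen=True)
class MicrobiologyResult:
    patient_id: str
    specimen_date: dt.date
    specimen_type: SpecimenType
    organism: str
    resistance_markers: FrozenSet[ResistanceMarker] = frozenset()

    def validate(self) -> None:
        if not self.organism:
            raise ValidationError(
                f"{self.patient_id} {self.specimen_date}: empty organism key"
            )

    @property
    def body_system(self) -> BodySystem:
        return SPECIMEN_BODY_SYSTEM[self.specimen_type]


@dataclass(frozen=True)
class OrganismCatalogEntry:
    key: str
    display_name: str
    organism_class: OrganismClass


@dataclass
class Cohort:
    """The six validated surveillance input tables for one unit."""

    patients: list = field(default_factory=list)
    stays: list = field(default_factory=list)
    exposures: list = field(default_factory=list)
    surgeries: list = field(default_factory=list)
    findings: list = field(default_factory=list)
    microbiology: list = field(default_factory=list)

    def patient_ids(self) -> set:
        return {p.patient_id for p in self.patients}

    def validate(self, organism_catalog=None, criterion_codes=None) -> None:
        """Check all per-record invariants, foreign keys, uniqueness, and
        (when supplied) that organism and criterion codes are known."""
        for p in self.patients:
            p.validate()
        ids = self.patient_ids()
        if len(ids) != len(self.patients):
            raise ValidationError("duplicate patient_id in patients table")

        seen_days = set()
        for table_name, rows in (
            ("stays", self.stays),
            ("exposures", self.exposures),
            ("surgeries", self.surgeries),
            ("findings", self.findings),
            ("microbiology", self.microbiology),
        ):
            for i, row in enumerate(rows):
                row.validate()
                if row.patient_id not in ids:
                    raise ValidationError(
                        f"{table_name} row {i}: unknown patient_id "
                        f"{row.patient_id!r}"
                    )
        for i, row in enumerate(self.exposures):
            key = (row.patient_id, row.date)
            if key in seen_days:
                raise ValidationError(
                    f"exposures row {i}: duplicate record for "
                    f"{row.patient_id} on {row.date}"
                )
            seen_days.add(key)

        if organism_catalog is not None:
            for i, m in enumerate(self.microbiology):
                if m.organism not in organism_catalog:
                    raise ValidationError(
                        f"microbiology row {i}: unknown organism "
                        f"{m.organism!r}"
                    )
        if criterion_codes is not None:
            for i, f in enumerate(self.findings):
                if f.criterion_code not in criterion_codes:
                    raise ValidationError(
                        f"findings row {i}: unknown criterion_code "
                        f"{f.criterion_code!r}"
                    )

    def for_patient(self, patient_id: str) -> "Cohort":
        return Cohort(
            patients=[p for p in self.patients if p.patient_id == patient_id],
            stays=[s for s in self.stays if s.patient_id == patient_id],
            exposures=[e for e in self.exposures if e.patient_id == patient_id],
            surgeries=[s for s in self.surgeries if s.patient_id == patient_id],
            findings=[f for f in self.findings if f.patient_id == patient_id],
            microbiology=[m for m in self.microbiology
                          if m.patient_id == patient_id],
        )
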