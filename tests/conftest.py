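import datetime as dt

import pytest

from neosurv.cohort import (
    AdmissionType,
    BodySystem,
    DeliveryMode,
    EndReason,
    Finding,
    FindingCategory,
    MicrobiologyResult,
    PatientRecord,
    ResistanceMarker,
    Sex,
    SpecimenType,
    StayInterval,
)
from neosurv.config import DefinitionsConfig, default_organism_catalog

BIRTH = dt.date(2025, 1, 1)


def day(n: int) -> dt.date:
    """Day of life n (day of birth = day 1) for the standard test birth."""
    return BIRTH + dt.timedelta(days=n - 1)


def make_patient(pid="P1", birth_weight=900, ga_weeks=27, ga_days=0,
                 birth_date=BIRTH, admission_offset=0, los=60,
                 end_reason=EndReason.discharge_or_transfer,
                 live_born=True, birth_time=None):
    admission = birth_date + dt.timedelta(days=admission_offset)
    return PatientRecord(
        patient_id=pid,
        ga_weeks=ga_weeks,
        ga_days=ga_days,
        birth_weight=birth_weight,
        sex=Sex.female,
        delivery_mode=DeliveryMode.vaginal,
        multiple_birth=1,
        birth_date=birth_date,
        birth_time=birth_time,
        admission_type=AdmissionType.delivery_room,
        admission_date=admission,
        end_date=admission + dt.timedelta(days=los - 1),
        end_reason=end_reason,
        live_born=live_born,
    )


def make_stay(pid="P1", start=1, end=60):
    return StayInterval(pid, day(start), day(end))


def finding(code, on, category=FindingCategory.clinical,
            system=BodySystem.bloodstream, pid="P1"):
    return Finding(pid, day(on), category, code, system)


def culture(organism, on, specimen=SpecimenType.blood, markers=(), pid="P1"):
    return MicrobiologyResult(
        pid, day(on), specimen, organism,
        frozenset(ResistanceMarker(m) for m in markers))


@pytest.fixture
def defs():
    return DefinitionsConfig()


@pytest.fixture
def catalog():
    return default_organism_catalog()
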