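"""Delimited-file readers and writers for the six surveillance tables.

Files are UTF-8 comma-delimited with a header row; dates are ISO-8601.  The
round trip ``read_cohort(write_cohort(c)) == c`` is exact for every valid
cohort.  Every malformed row produces a located error (file, row number,
rule) rather than a crash.
"""

from __future__ import annotations

import datetime as dt
import unicodedata
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from .cohort import (
    AdmissionType,
    BodySystem,
    Cohort,
    DailyExposureRecord,
    DeliveryMode,
    EndReason,
    Feeding,
    Finding,
    FindingCategory,
    MicrobiologyResult,
    PatientRecord,
    ResistanceMarker,
    Sex,
    SpecimenType,
    StayInterval,
    SurgeryRecord,
    ValidationError,
    WoundClass,
)
from .config import OUT_OF_SCOPE_CODES

FILES = {
    "patients": "patients.csv",
    "stays": "stays.csv",
    "exposures": "exposures.csv",
    "surgeries": "surgeries.csv",
    "findings": "findings.csv",
    "microbiology": "microbiology.csv",
}

_LIST_SEP = ";"


def _norm(s: str) -> str:
    return unicodedata.normalize("NFC", s)


def _parse_date(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def _parse_opt_date(s: str) -> Optional[dt.date]:
    return dt.date.fromisoformat(s) if s else None


def _parse_opt_time(s: str) -> Optional[dt.time]:
    return dt.time.fromisoformat(s) if s else None


def _parse_bool(s: str) -> bool:
    if s.lower() in {"true", "1", "yes"}:
        return True
    if s.lower() in {"false", "0", "no"}:
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _split_list(s: str) -> tuple:
    return tuple(part for part in s.split(_LIST_SEP) if part) if s else ()


def _read_table(directory: Path, name: str) -> pd.DataFrame:
    path = directory / FILES[name]
    if not path.exists():
        raise FileNotFoundError(f"missing required input file: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=False,
                       encoding="utf-8")


def _row_error(name: str, index: int, exc: Exception) -> ValidationError:
    return ValidationError(f"{FILES[name]} row {index + 2}: {exc}")


def read_cohort(input_directory, organism_catalog=None,
                criterion_codes=None) -> Cohort:
    """Read and validate the six tables from ``input_directory``.

    Parameters
    ----------
    organism_catalog, criterion_codes
        When given, organism keys and finding criterion codes are checked
        against them; unknown codes are errors naming the code and row.
    """
    directory = Path(input_directory)
    cohort = Cohort()

    df = _read_table(directory, "patients")
    for i, row in df.iterrows():
        try:
            cohort.patients.append(PatientRecord(
                patient_id=_norm(row["patient_id"]),
                ga_weeks=int(row["ga_weeks"]),
                ga_days=int(row["ga_days"]),
                birth_weight=int(row["birth_weight"]),
                sex=Sex(row["sex"]),
                delivery_mode=DeliveryMode(row["delivery_mode"]),
                multiple_birth=int(row["multiple_birth"]),
                birth_date=_parse_date(row["birth_date"]),
                birth_time=_parse_opt_time(row["birth_time"]),
                admission_type=AdmissionType(row["admission_type"]),
                admission_date=_parse_date(row["admission_date"]),
                end_date=_parse_opt_date(row["end_date"]),
                end_reason=EndReason(row["end_reason"])
                if row["end_reason"] else None,
                live_born=_parse_bool(row["live_born"]),
            ))
        except (ValueError, KeyError) as exc:
            raise _row_error("patients", i, exc) from exc

    df = _read_table(directory, "stays")
    for i, row in df.iterrows():
        try:
            cohort.stays.append(StayInterval(
                patient_id=_norm(row["patient_id"]),
                start_date=_parse_date(row["start_date"]),
                end_date=_parse_opt_date(row["end_date"]),
            ))
        except (ValueError, KeyError) as exc:
            raise _row_error("stays", i, exc) from exc

    df = _read_table(directory, "exposures")
    for i, row in df.iterrows():
        try:
            cohort.exposures.append(DailyExposureRecord(
                patient_id=_norm(row["patient_id"]),
                date=_parse_date(row["date"]),
                cvc_hours=float(row["cvc_hours"]),
                pvc_hours=float(row["pvc_hours"]),
                inv_hours=float(row["inv_hours"]),
                niv_hours=float(row["niv_hours"]),
                antibiotic_substances=frozenset(
                    _norm(s) for s in _split_list(row["antibiotic_substances"])
                ),
                enteral_feeding=Feeding(row["enteral_feeding"]),
                probiotic_given=_parse_bool(row["probiotic_given"]),
                kangaroo_hours=float(row["kangaroo_hours"]),
            ))
        except (ValueError, KeyError) as exc:
            raise _row_error("exposures", i, exc) from exc

    df = _read_table(directory, "surgeries")
    for i, row in df.iterrows():
        try:
            cohort.surgeries.append(SurgeryRecord(
                surgery_id=_norm(row["surgery_id"]),
                patient_id=_norm(row["patient_id"]),
                description=_norm(row["description"]),
                date=_parse_date(row["date"]),
                duration_minutes=int(row["duration_minutes"]),
                main_procedure_code=_norm(row["main_procedure_code"]),
                side_procedure_codes=tuple(
                    _norm(c) for c in _split_list(row["side_procedure_codes"])
                ),
                asa_score=int(row["asa_score"]),
                wound_class=WoundClass(row["wound_class"]),
                endoscopic=_parse_bool(row["endoscopic"]),
                emergency=_parse_bool(row["emergency"]),
                revision=_parse_bool(row["revision"]),
                primary_wound_closure=_parse_bool(
                    row["primary_wound_closure"]),
                implant=_parse_bool(row["implant"]),
                infection_signs_at_surgery=_parse_bool(
                    row["infection_signs_at_surgery"]),
            ))
        except (ValueError, KeyError) as exc:
            raise _row_error("surgeries", i, exc) from exc

    df = _read_table(directory, "findings")
    for i, row in df.iterrows():
        code = row.get("criterion_code", "")
        if code in OUT_OF_SCOPE_CODES:
            raise ValidationError(
                f"findings.csv row {i + 2}: {OUT_OF_SCOPE_CODES[code]} are "
                "outside the surveillance scope and cannot be recorded "
                f"(criterion_code {code!r})"
            )
        try:
            cohort.findings.append(Finding(
                patient_id=_norm(row["patient_id"]),
                date=_parse_date(row["date"]),
                category=FindingCategory(row["category"]),
                criterion_code=_norm(code),
                body_system_hint=BodySystem(row["body_system_hint"]),
            ))
        except (ValueError, KeyError) as exc:
            raise _row_error("findings", i, exc) from exc

    df = _read_table(directory, "microbiology")
    for i, row in df.iterrows():
        try:
            cohort.microbiology.append(MicrobiologyResult(
                patient_id=_norm(row["patient_id"]),
                specimen_date=_parse_date(row["specimen_date"]),
                specimen_type=SpecimenType(row["specimen_type"]),
                organism=_norm(row["organism"]),
                resistance_markers=frozenset(
                    ResistanceMarker(m)
                    for m in _split_list(row["resistance_markers"])
                ),
            ))
        except (ValueError, KeyError) as exc:
            raise _row_error("microbiology", i, exc) from exc

    cohort.validate(organism_catalog=organism_catalog,
                    criterion_codes=criterion_codes)
    return cohort


def _fmt_opt(value) -> str:
    return "" if value is None else value.isoformat()


def write_cohort(cohort: Cohort, output_directory) -> Dict[str, Path]:
    """Write the cohort as six CSV files; lossless inverse of read_cohort."""
    directory = Path(output_directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = [{
        "patient_id": p.patient_id,
        "ga_weeks": p.ga_weeks,
        "ga_days": p.ga_days,
        "birth_weight": p.birth_weight,
        "sex": p.sex.value,
        "delivery_mode": p.delivery_mode.value,
        "multiple_birth": p.multiple_birth,
        "birth_date": p.birth_date.isoformat(),
        "birth_time": _fmt_opt(p.birth_time),
        "admission_type": p.admission_type.value,
        "admission_date": p.admission_date.isoformat(),
        "end_date": _fmt_opt(p.end_date),
        "end_reason": p.end_reason.value if p.end_reason else "",
        "live_born": _fmt_bool(p.live_born),
    } for p in cohort.patients]
    paths["patients"] = _write(directory, "patients", rows, [
        "patient_id", "ga_weeks", "ga_days", "birth_weight", "sex",
        "delivery_mode", "multiple_birth", "birth_date", "birth_time",
        "admission_type", "admission_date", "end_date", "end_reason",
        "live_born"])

    rows = [{
        "patient_id": s.patient_id,
        "start_date": s.start_date.isoformat(),
        "end_date": _fmt_opt(s.end_date),
    } for s in cohort.stays]
    paths["stays"] = _write(directory, "stays", rows,
                            ["patient_id", "start_date", "end_date"])

    rows = [{
        "patient_id": e.patient_id,
        "date": e.date.isoformat(),
        "cvc_hours": e.cvc_hours,
        "pvc_hours": e.pvc_hours,
        "inv_hours": e.inv_hours,
        "niv_hours": e.niv_hours,
        "antibiotic_substances": _LIST_SEP.join(
            sorted(e.antibiotic_substances)),
        "enteral_feeding": e.enteral_feeding.value,
        "probiotic_given": _fmt_bool(e.probiotic_given),
        "kangaroo_hours": e.kangaroo_hours,
    } for e in cohort.exposures]
    paths["exposures"] = _write(directory, "exposures", rows, [
        "patient_id", "date", "cvc_hours", "pvc_hours", "inv_hours",
        "niv_hours", "antibiotic_substances", "enteral_feeding",
        "probiotic_given", "kangaroo_hours"])

    rows = [{
        "surgery_id": s.surgery_id,
        "patient_id": s.patient_id,
        "description": s.description,
        "date": s.date.isoformat(),
        "duration_minutes": s.duration_minutes,
        "main_procedure_code": s.main_procedure_code,
        "side_procedure_codes": _LIST_SEP.join(s.side_procedure_codes),
        "asa_score": s.asa_score,
        "wound_class": s.wound_class.value,
        "endoscopic": _fmt_bool(s.endoscopic),
        "emergency": _fmt_bool(s.emergency),
        "revision": _fmt_bool(s.revision),
        "primary_wound_closure": _fmt_bool(s.primary_wound_closure),
        "implant": _fmt_bool(s.implant),
        "infection_signs_at_surgery": _fmt_bool(s.infection_signs_at_surgery),
    } for s in cohort.surgeries]
    paths["surgeries"] = _write(directory, "surgeries", rows, [
        "surgery_id", "patient_id", "description", "date",
        "duration_minutes", "main_procedure_code", "side_procedure_codes",
        "asa_score", "wound_class", "endoscopic", "emergency", "revision",
        "primary_wound_closure", "implant", "infection_signs_at_surgery"])

    rows = [{
        "patient_id": f.patient_id,
        "date": f.date.isoformat(),
        "category": f.category.value,
        "criterion_code": f.criterion_code,
        "body_system_hint": f.body_system_hint.value,
    } for f in cohort.findings]
    paths["findings"] = _write(directory, "findings", rows, [
        "patient_id", "date", "category", "criterion_code",
        "body_system_hint"])

    rows = [{
        "patient_id": m.patient_id,
        "specimen_date": m.specimen_date.isoformat(),
        "specimen_type": m.specimen_type.value,
        "organism": m.organism,
        "resistance_markers": _LIST_SEP.join(
            sorted(v.value for v in m.resistance_markers)),
    } for m in cohort.microbiology]
    paths["microbiology"] = _write(directory, "microbiology", rows, [
        "patient_id", "specimen_date", "specimen_type", "organism",
        "resistance_markers"])

    return paths


def _write(directory: Path, name: str, rows, columns) -> Path:
    path = directory / FILES[name]
    pd.DataFrame(rows, columns=columns).to_csv(
        path, index=False, encoding="utf-8")
    return path
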