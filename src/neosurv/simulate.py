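"""Synthetic neonatal-unit cohorts with planted, recoverable infections.

The generator emulates the surveillance inputs a unit would collect: very
preterm / very-low-birth-weight admissions (plus a few ineligible infants to
exercise the inclusion rules), unit stays with occasional short absences,
daily device/antibiotic/feeding/probiotic/kangaroo exposure, surgeries, and
infection events emitted as criterion-code findings plus microbiology rows
that the classifier can rediscover.

Planted events are the ground truth.  Within one patient and body system
the generator leaves at least ``episode_max_gap_days + 1`` days between the
elements of consecutive events, so each planted event corresponds to exactly
one assembled episode; the recovery oracle (:func:`rule_aware_truth`)
re-applies the eligibility, onset, association and suppression rules to the
planted truth with its own inline logic and yields the line list a correct
classifier must produce.

A single seeded generator stream is consumed in a fixed per-patient order,
so one seed fixes every table byte-identically.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cohort import (
    AdmissionType,
    BodySystem,
    Cohort,
    DailyExposureRecord,
    DeliveryMode,
    Device,
    EndReason,
    Feeding,
    Finding,
    FindingCategory,
    HaiType,
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
from .config import DefinitionsConfig, default_organism_catalog
from .eligibility import build_windows, compute_surveillance_window

_PATHOGENS = (
    "escherichia_coli", "klebsiella_pneumoniae", "staphylococcus_aureus",
    "enterococcus_faecium", "pseudomonas_aeruginosa",
    "streptococcus_agalactiae", "candida_albicans", "serratia_marcescens",
)
_COMMENSALS = (
    "staphylococcus_epidermidis", "corynebacterium_spp",
    "micrococcus_spp", "bacillus_spp",
)
_ANTIBIOTICS = ("ampicillin", "gentamicin", "vancomycin", "meropenem",
                "cefotaxime")

#: plausible resistance phenotypes per species
_MARKERS = {
    "staphylococcus_aureus": (ResistanceMarker.MRSA,),
    "enterococcus_faecium": (ResistanceMarker.VRE,),
    "escherichia_coli": (ResistanceMarker.THIRD_GEN_CEPH_R,
                         ResistanceMarker.carbapenem_resistant),
    "klebsiella_pneumoniae": (ResistanceMarker.THIRD_GEN_CEPH_R,
                              ResistanceMarker.carbapenem_resistant),
    "serratia_marcescens": (ResistanceMarker.THIRD_GEN_CEPH_R,),
    "pseudomonas_aeruginosa": (ResistanceMarker.carbapenem_resistant,
                               ResistanceMarker.colistin_resistant),
}

_BW_RANGES = ((400, 499), (500, 999), (1000, 1499), (1500, 2200))
_GA_RANGES = ((23, 25), (24, 28), (27, 31), (29, 31))  # completed weeks

_PROCEDURE_CODES = ("KDQ.AA", "KDJ.BB", "JAB.CC", "KCA.DD")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic unit.

    The defaults describe a mid-size neonatal unit over a quarter year:
    mostly eligible VLBW/VPT admissions, a geometric length of stay around
    five weeks, device exposure typical of intensive care, and late-onset
    infection hazards of a few events per 1000 patient-days.
    """

    n_patients: int = 50
    seed: int = 0
    start_date: dt.date = dt.date(2025, 1, 1)
    admission_period_days: int = 90
    #: birth-weight mix over the four strata (<500, 500-999, 1000-1499, >=1500)
    birth_weight_probs: Tuple[float, ...] = (0.05, 0.30, 0.50, 0.15)
    prob_ineligible: float = 0.05      # neither VLBW nor VPT
    prob_not_live_born: float = 0.01
    prob_late_admission: float = 0.02  # admitted > 120 days after birth
    los_distribution: str = "geometric"  # or "fixed"
    mean_los_days: float = 35.0
    max_los_days: int = 120
    prob_death: float = 0.05
    prob_split_stay: float = 0.08      # a short absence mid-stay
    #: daily probability that a device episode starts / its mean duration
    device_start_prob: Dict[str, float] = field(default_factory=lambda: {
        "CVC": 0.05, "PVC": 0.08, "INV": 0.04, "NIV": 0.07})
    device_mean_duration: Dict[str, float] = field(default_factory=lambda: {
        "CVC": 7.0, "PVC": 4.0, "INV": 4.0, "NIV": 6.0})
    prob_exclusive_breast_milk_day: float = 0.45
    prob_probiotic_day: float = 0.40
    prob_kangaroo_day: float = 0.35
    antibiotic_start_prob: float = 0.04
    antibiotic_mean_duration: float = 5.0
    #: per-day infection hazards by body-system family
    hazards: Dict[str, float] = field(default_factory=lambda: {
        "bsi": 0.004, "pneumonia": 0.0020, "nec": 0.0010})
    #: mix of bloodstream subtypes (clinical sepsis, pathogen, commensal)
    bsi_subtype_probs: Tuple[float, ...] = (0.30, 0.45, 0.25)
    prob_device_plant: float = 0.5     # plant a qualifying device run
    prob_culture_before_symptoms: float = 0.3
    contaminant_hazard: float = 0.0010  # lone commensal blood culture
    noise_hazard: float = 0.0015       # isolated non-diagnostic finding
    mdro_prob: float = 0.25
    surgery_prob: float = 0.15
    implant_prob: float = 0.4
    ssi_prob: float = 0.30             # SSI after a surgery
    early_onset_from_day: int = 1      # hazards apply from this day of life

    def validate(self) -> None:
        probs = [self.prob_ineligible, self.prob_not_live_born,
                 self.prob_late_admission, self.prob_death,
                 self.prob_split_stay, self.prob_exclusive_breast_milk_day,
                 self.prob_probiotic_day, self.prob_kangaroo_day,
                 self.antibiotic_start_prob, self.prob_device_plant,
                 self.prob_culture_before_symptoms, self.mdro_prob,
                 self.surgery_prob, self.implant_prob, self.ssi_prob,
                 self.contaminant_hazard, self.noise_hazard,
                 *self.birth_weight_probs, *self.bsi_subtype_probs,
                 *self.device_start_prob.values(), *self.hazards.values()]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if abs(sum(self.birth_weight_probs) - 1.0) > 1e-9:
            raise ValidationError("birth_weight_probs must sum to 1")
        if abs(sum(self.bsi_subtype_probs) - 1.0) > 1e-9:
            raise ValidationError("bsi_subtype_probs must sum to 1")
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")


@dataclass(frozen=True)
class PlantedEvent:
    """One planted infection (or non-infection control event)."""

    patient_id: str
    hai_type: str                      # HaiType value
    onset_date: dt.date
    body_system: str
    element_dates: Tuple[dt.date, ...]
    symptom_dates: Tuple[dt.date, ...]
    organisms: Tuple[Tuple[str, Tuple[str, ...]], ...] = ()

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["onset_date"] = self.onset_date.isoformat()
        d["element_dates"] = [x.isoformat() for x in self.element_dates]
        d["symptom_dates"] = [x.isoformat() for x in self.symptom_dates]
        d["organisms"] = [[o, sorted(m)] for o, m in self.organisms]
        return d


# ---------------------------------------------------------------------------

def _geometric_days(rng, mean: float) -> int:
    return max(int(rng.geometric(1.0 / max(mean, 1.0))), 1)


class _PatientBuilder:
    """Consumes the shared RNG in a fixed order for one patient."""

    def __init__(self, rng, config: SimulationConfig,
                 defs: DefinitionsConfig, pid: str):
        self.rng = rng
        self.cfg = config
        self.defs = defs
        self.pid = pid
        self.truth: List[PlantedEvent] = []
        # last element date per body system, for episode separation
        self._last_element: Dict[str, dt.date] = {}

    # -- demographics and stays -------------------------------------------

    def make_patient(self) -> Tuple[PatientRecord, List[StayInterval]]:
        rng, cfg = self.rng, self.cfg
        ineligible = rng.random() < cfg.prob_ineligible
        not_live = rng.random() < cfg.prob_not_live_born
        late_adm = rng.random() < cfg.prob_late_admission

        if ineligible:
            bw = int(rng.integers(1500, 2600))
            ga_weeks = int(rng.integers(32, 37))
        else:
            stratum = int(rng.choice(4, p=cfg.birth_weight_probs))
            lo, hi = _BW_RANGES[stratum]
            bw = int(rng.integers(lo, hi + 1))
            glo, ghi = _GA_RANGES[stratum]
            ga_weeks = int(rng.integers(glo, ghi + 1))
        ga_days = int(rng.integers(0, 7))

        birth_date = cfg.start_date + dt.timedelta(
            days=int(rng.integers(0, cfg.admission_period_days)))
        birth_time = (dt.time(int(rng.integers(0, 24)),
                              int(rng.integers(0, 60)))
                      if rng.random() < 0.3 else None)

        if late_adm:
            offset = int(rng.integers(121, 150))
            admission_type = AdmissionType.transfer_later
        else:
            offset = int(rng.choice([0, 0, 0, 1, 2]))
            admission_type = (
                AdmissionType.delivery_room if offset == 0
                else AdmissionType.transfer_later)
        admission_date = birth_date + dt.timedelta(days=offset)

        if cfg.los_distribution == "fixed":
            los = int(round(cfg.mean_los_days))
        else:
            los = min(_geometric_days(rng, cfg.mean_los_days),
                      cfg.max_los_days)
        los = max(los, 1)
        end_date = admission_date + dt.timedelta(days=los - 1)
        died = rng.random() < cfg.prob_death
        end_reason = EndReason.death if died else \
            EndReason.discharge_or_transfer

        stays = [StayInterval(self.pid, admission_date, end_date)]
        if los >= 10 and rng.random() < cfg.prob_split_stay:
            cut = int(rng.integers(3, los - 4))
            gap = int(rng.integers(1, 5))  # 1-2 merge, 3-4 split the episode
            first_end = admission_date + dt.timedelta(days=cut)
            second_start = first_end + dt.timedelta(days=gap + 1)
            if second_start <= end_date:
                stays = [
                    StayInterval(self.pid, admission_date, first_end),
                    StayInterval(self.pid, second_start, end_date),
                ]

        patient = PatientRecord(
            patient_id=self.pid,
            ga_weeks=ga_weeks,
            ga_days=ga_days,
            birth_weight=bw,
            sex=Sex(["male", "female", "undetermined"][
                int(rng.choice(3, p=[0.49, 0.49, 0.02]))]),
            delivery_mode=DeliveryMode(
                ["vaginal", "elective_cesarean", "emergency_cesarean"][
                    int(rng.choice(3, p=[0.4, 0.3, 0.3]))]),
            multiple_birth=int(rng.choice([1, 1, 1, 2, 3],
                                          p=[0.6, 0.1, 0.1, 0.15, 0.05])),
            birth_date=birth_date,
            birth_time=birth_time,
            admission_type=admission_type,
            admission_date=admission_date,
            end_date=end_date,
            end_reason=end_reason,
            live_born=not not_live,
        )
        return patient, stays

    # -- daily exposure ----------------------------------------------------

    def make_exposures(self, days: Sequence[dt.date]
                       ) -> Dict[dt.date, DailyExposureRecord]:
        rng, cfg = self.rng, self.cfg
        n = len(days)
        hours = {d: np.zeros(n) for d in Device}
        for device in Device:
            start_p = cfg.device_start_prob[device.value]
            mean_dur = cfg.device_mean_duration[device.value]
            remaining = 0
            for i in range(n):
                if remaining == 0 and rng.random() < start_p:
                    remaining = _geometric_days(rng, mean_dur)
                if remaining > 0:
                    # partial hours on the last day exercise the 12 h rule
                    hours[device][i] = (
                        float(np.round(rng.uniform(4.0, 24.0), 1))
                        if remaining == 1 else 24.0)
                    remaining -= 1

        abx_remaining = 0
        abx_set: frozenset = frozenset()
        records: Dict[dt.date, DailyExposureRecord] = {}
        for i, day in enumerate(days):
            if abx_remaining == 0 and rng.random() < cfg.antibiotic_start_prob:
                abx_remaining = _geometric_days(
                    rng, cfg.antibiotic_mean_duration)
                k = int(rng.integers(1, 3))
                abx_set = frozenset(
                    rng.choice(_ANTIBIOTICS, size=k, replace=False).tolist())
            substances = abx_set if abx_remaining > 0 else frozenset()
            if abx_remaining > 0:
                abx_remaining -= 1
            feeding = (Feeding.exclusive_breast_milk
                       if rng.random() < cfg.prob_exclusive_breast_milk_day
                       else Feeding(["none", "mixed_or_formula"][
                           int(rng.integers(0, 2))]))
            kangaroo = (float(np.round(rng.uniform(0.5, 6.0), 1))
                        if rng.random() < cfg.prob_kangaroo_day else 0.0)
            records[day] = DailyExposureRecord(
                patient_id=self.pid,
                date=day,
                cvc_hours=float(hours[Device.CVC][i]),
                pvc_hours=float(hours[Device.PVC][i]),
                inv_hours=float(hours[Device.INV][i]),
                niv_hours=float(hours[Device.NIV][i]),
                antibiotic_substances=substances,
                enteral_feeding=feeding,
                probiotic_given=bool(rng.random() < cfg.prob_probiotic_day),
                kangaroo_hours=kangaroo,
            )
        return records

    # -- event planting ----------------------------------------------------

    def _separated(self, system: str, first_day: dt.date) -> bool:
        last = self._last_element.get(system)
        return last is None or (first_day - last).days > \
            self.defs.episode_max_gap_days

    def _reserve(self, system: str, last_day: dt.date) -> None:
        prev = self._last_element.get(system)
        if prev is None or last_day > prev:
            self._last_element[system] = last_day

    def _organism(self, pool: Sequence[str]) -> Tuple[str, Tuple[str, ...]]:
        key = str(self.rng.choice(pool))
        markers: Tuple[str, ...] = ()
        if key in _MARKERS and self.rng.random() < self.cfg.mdro_prob:
            markers = (str(self.rng.choice(
                [m.value for m in _MARKERS[key]])),)
        return key, markers

    def plant_events(
        self,
        days: Sequence[dt.date],
        exposures: Dict[dt.date, DailyExposureRecord],
    ) -> Tuple[List[Finding], List[MicrobiologyResult]]:
        rng, cfg = self.rng, self.cfg
        findings: List[Finding] = []
        micro: List[MicrobiologyResult] = []
        day_set = set(days)

        def in_window(day: dt.date) -> bool:
            return day in day_set

        def add_finding(day, category, code, system):
            findings.append(Finding(self.pid, day,
                                    FindingCategory(category), code,
                                    BodySystem(system)))

        def add_culture(day, specimen, organism, markers):
            micro.append(MicrobiologyResult(
                self.pid, day, SpecimenType(specimen), organism,
                frozenset(ResistanceMarker(m) for m in markers)))

        for day in days:
            # bloodstream events
            if rng.random() < cfg.hazards.get("bsi", 0.0) and \
                    self._separated("bloodstream", day):
                subtype = int(rng.choice(3, p=cfg.bsi_subtype_probs))
                element_days = [day]
                symptom_days = [day]
                organisms: Tuple = ()
                if subtype == 0:  # clinical sepsis: no organism detected
                    add_finding(day, "clinical", "CLIN_SEPSIS_SIGN",
                                "bloodstream")
                    add_finding(day, "laboratory", "LAB_SEPSIS_MARKER",
                                "bloodstream")
                    hai_type = HaiType.clinical_sepsis
                elif subtype == 1:  # recognized pathogen
                    org, markers = self._organism(_PATHOGENS)
                    organisms = ((org, markers),)
                    if rng.random() < cfg.prob_culture_before_symptoms and \
                            in_window(day + dt.timedelta(days=1)):
                        culture_day, symptom_day = day, \
                            day + dt.timedelta(days=1)
                    else:
                        culture_day = symptom_day = day
                    add_culture(culture_day, "blood", org, markers)
                    add_finding(symptom_day, "clinical", "CLIN_SEPSIS_SIGN",
                                "bloodstream")
                    element_days = sorted({culture_day, symptom_day})
                    symptom_days = [symptom_day]
                    hai_type = HaiType.lcbsi_pathogen
                else:  # common commensal with clinical + laboratory support
                    org, markers = self._organism(_COMMENSALS)
                    organisms = ((org, markers),)
                    add_culture(day, "blood", org, markers)
                    add_finding(day, "clinical", "CLIN_SEPSIS_SIGN",
                                "bloodstream")
                    add_finding(day, "laboratory", "LAB_SEPSIS_MARKER",
                                "bloodstream")
                    hai_type = HaiType.lcbsi_commensal
                # optional trailing symptom day
                tail = element_days[-1] + dt.timedelta(days=1)
                if rng.random() < 0.4 and in_window(tail):
                    add_finding(tail, "clinical", "CLIN_SEPSIS_SIGN",
                                "bloodstream")
                    element_days.append(tail)
                    symptom_days.append(tail)
                onset = min(element_days)
                self._maybe_plant_device(
                    onset, (Device.CVC, Device.PVC), (0.7, 0.3),
                    exposures, day_set)
                self.truth.append(PlantedEvent(
                    self.pid, hai_type.value, onset, "bloodstream",
                    tuple(sorted(element_days)),
                    tuple(sorted(symptom_days)), organisms))
                self._reserve("bloodstream", max(element_days))

            elif rng.random() < cfg.contaminant_hazard and \
                    self._separated("bloodstream", day):
                org, markers = self._organism(_COMMENSALS)
                add_culture(day, "blood", org, markers)
                self._reserve("bloodstream", day)

            elif rng.random() < cfg.noise_hazard and \
                    self._separated("bloodstream", day):
                add_finding(day, "clinical", "CLIN_SEPSIS_SIGN",
                            "bloodstream")
                self._reserve("bloodstream", day)

            # pneumonia
            if rng.random() < cfg.hazards.get("pneumonia", 0.0) and \
                    self._separated("respiratory", day):
                add_finding(day, "clinical", "PNEU_CLINICAL", "respiratory")
                add_finding(day, "imaging", "PNEU_IMAGING", "respiratory")
                add_finding(day, "laboratory", "PNEU_LAB", "respiratory")
                element_days = [day]
                symptom_days = [day]
                organisms = ()
                if rng.random() < 0.4:
                    org, markers = self._organism(_PATHOGENS)
                    organisms = ((org, markers),)
                    add_culture(day, "respiratory", org, markers)
                self._maybe_plant_device(
                    day, (Device.INV, Device.NIV), (0.6, 0.4),
                    exposures, day_set)
                self.truth.append(PlantedEvent(
                    self.pid, HaiType.pneumonia.value, day, "respiratory",
                    tuple(element_days), tuple(symptom_days), organisms))
                self._reserve("respiratory", max(element_days))
            elif rng.random() < cfg.noise_hazard and \
                    self._separated("respiratory", day):
                add_finding(day, "clinical", "PNEU_CLINICAL", "respiratory")
                self._reserve("respiratory", day)

            # necrotizing enterocolitis
            if rng.random() < cfg.hazards.get("nec", 0.0) and \
                    self._separated("gastrointestinal", day):
                if rng.random() < 0.5:
                    add_finding(day, "clinical", "NEC_CLINICAL",
                                "gastrointestinal")
                    add_finding(day, "imaging", "NEC_RADIOLOGY",
                                "gastrointestinal")
                else:
                    add_finding(day, "surgical_evidence", "NEC_SURGICAL",
                                "gastrointestinal")
                self.truth.append(PlantedEvent(
                    self.pid, HaiType.nec.value, day, "gastrointestinal",
                    (day,), (day,), ()))
                self._reserve("gastrointestinal", day)

        return findings, micro

    def _maybe_plant_device(self, onset, devices, probs, exposures, day_set):
        rng, cfg = self.rng, self.cfg
        if rng.random() >= cfg.prob_device_plant:
            return
        device = devices[int(rng.choice(len(devices), p=list(probs)))]
        run = int(rng.integers(self.defs.device_assoc_min_days,
                               self.defs.device_assoc_min_days + 3))
        anchor = onset - dt.timedelta(days=int(rng.integers(0, 2)))
        for k in range(run):
            day = anchor - dt.timedelta(days=k)
            if day not in day_set:
                break
            old = exposures[day]
            kwargs = {f"{device.value.lower()}_hours": 24.0}
            exposures[day] = dataclasses.replace(old, **kwargs)

    # -- surgery and SSI ---------------------------------------------------

    def plant_surgery(self, days: Sequence[dt.date]
                      ) -> Tuple[List[SurgeryRecord], List[Finding],
                                 List[MicrobiologyResult]]:
        rng, cfg = self.rng, self.cfg
        if not days or rng.random() >= cfg.surgery_prob:
            return [], [], []
        day_set = set(days)
        sdate = days[int(rng.integers(0, len(days)))]
        implant = bool(rng.random() < cfg.implant_prob)
        surgery = SurgeryRecord(
            surgery_id=f"{self.pid}-S1",
            patient_id=self.pid,
            description="neonatal procedure",
            date=sdate,
            duration_minutes=int(rng.integers(30, 180)),
            main_procedure_code=str(rng.choice(_PROCEDURE_CODES)),
            asa_score=int(rng.integers(2, 5)),
            wound_class=WoundClass(list(WoundClass)[
                int(rng.integers(0, 4))]),
            endoscopic=bool(rng.random() < 0.2),
            emergency=bool(rng.random() < 0.3),
            revision=bool(rng.random() < 0.1),
            primary_wound_closure=bool(rng.random() < 0.9),
            implant=implant,
            infection_signs_at_surgery=False,
        )
        findings: List[Finding] = []
        micro: List[MicrobiologyResult] = []
        if rng.random() < cfg.ssi_prob:
            depth = [HaiType.ssi_superficial, HaiType.ssi_deep,
                     HaiType.ssi_organ_space][int(rng.choice(
                         3, p=[0.4, 0.3, 0.3]))]
            max_delta = 80 if implant else 40
            onset = sdate + dt.timedelta(days=int(rng.integers(1, max_delta)))
            if onset in day_set and self._separated("surgical_site", onset):
                depth_code = {
                    HaiType.ssi_superficial: "SSI_SUPERFICIAL",
                    HaiType.ssi_deep: "SSI_DEEP",
                    HaiType.ssi_organ_space: "SSI_ORGAN_SPACE",
                }[depth]
                findings.append(Finding(
                    self.pid, onset, FindingCategory.clinical,
                    "SSI_LOCAL_SIGN", BodySystem.surgical_site))
                findings.append(Finding(
                    self.pid, onset, FindingCategory.clinical,
                    depth_code, BodySystem.surgical_site))
                organisms: Tuple = ()
                if rng.random() < 0.4:
                    org, markers = self._organism(_PATHOGENS)
                    organisms = ((org, markers),)
                    micro.append(MicrobiologyResult(
                        self.pid, onset, SpecimenType.wound, org,
                        frozenset(ResistanceMarker(m) for m in markers)))
                self.truth.append(PlantedEvent(
                    self.pid, depth.value, onset, "surgical_site",
                    (onset,), (onset,), organisms))
                self._reserve("surgical_site", onset)
        return [surgery], findings, micro


# ---------------------------------------------------------------------------

def generate_with_truth(
    config: SimulationConfig,
    definitions: Optional[DefinitionsConfig] = None,
) -> Tuple[Cohort, List[PlantedEvent]]:
    """Generate a cohort plus the list of planted events (ground truth)."""
    config.validate()
    defs = definitions or DefinitionsConfig()
    rng = np.random.default_rng(config.seed)
    cohort = Cohort()
    truth: List[PlantedEvent] = []

    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        builder = _PatientBuilder(rng, config, defs, pid)
        patient, stays = builder.make_patient()
        cohort.patients.append(patient)
        cohort.stays.extend(stays)

        window = compute_surveillance_window(patient, stays)
        days = list(window.surveillance_days) if window.included else [
            d for s in stays for d in _stay_days(s, patient)
        ]
        exposures = builder.make_exposures(days)
        findings, micro = builder.plant_events(days, exposures)
        surgeries, sfindings, smicro = builder.plant_surgery(days)

        cohort.exposures.extend(exposures[d] for d in days)
        cohort.findings.extend(findings + sfindings)
        cohort.surgeries.extend(surgeries)
        cohort.microbiology.extend(micro + smicro)
        truth.extend(builder.truth)

    cohort.validate(organism_catalog=default_organism_catalog(),
                    criterion_codes=defs.criterion_codes)
    return cohort, truth


def _stay_days(stay: StayInterval, patient: PatientRecord) -> List[dt.date]:
    end = stay.end_date or patient.end_date or stay.start_date
    out, d = [], stay.start_date
    while d <= end:
        out.append(d)
        d += dt.timedelta(days=1)
    return out


def generate_cohort(config: SimulationConfig,
                    definitions: Optional[DefinitionsConfig] = None) -> Cohort:
    return generate_with_truth(config, definitions)[0]


def ground_truth(config: SimulationConfig,
                 definitions: Optional[DefinitionsConfig] = None
                 ) -> List[PlantedEvent]:
    """Regenerate (deterministically) and return the planted events."""
    return generate_with_truth(config, definitions)[1]


# ---------------------------------------------------------------------------
# rule-aware recovery oracle

LineRecord = Tuple  # canonical line-list record for comparisons


def canonical_line_list(infections) -> List[LineRecord]:
    """Classifier output reduced to comparable tuples."""
    return sorted(
        (
            h.patient_id,
            h.hai_type.value,
            h.infection_date.isoformat(),
            h.device_association.value if h.device_association else None,
            h.linked_surgery_id,
            tuple(sorted((o, tuple(sorted(m.value for m in mk)))
                         for o, mk in h.organisms)),
            h.is_mdro,
        )
        for h in infections
    )


def rule_aware_truth(
    cohort: Cohort,
    truth: Sequence[PlantedEvent],
    definitions: Optional[DefinitionsConfig] = None,
) -> List[LineRecord]:
    """Apply the surveillance rules to the planted truth with inline logic.

    Eligibility windows come from the engine's window computation (the
    planted events live inside them by construction); onset gating, device
    association, surgical attribution and repeat suppression are re-derived
    here directly from the planted elements and the exposure/surgery tables,
    independently of the episode-assembly path under test.
    """
    defs = definitions or DefinitionsConfig()
    windows = build_windows(cohort)
    patients = {p.patient_id: p for p in cohort.patients}

    # qualifying device-days per patient/device, straight from the table
    device_days: Dict[Tuple[str, Device], set] = {}
    for e in cohort.exposures:
        w = windows.get(e.patient_id)
        if w is None or not w.included or \
                e.date not in set(w.surveillance_days):
            continue
        for device in Device:
            if e.device_hours(device) >= defs.device_day_min_hours:
                device_days.setdefault(
                    (e.patient_id, device), set()).add(e.date)

    # symptom dates per patient/system from the findings table
    symptoms: Dict[Tuple[str, str], set] = {}
    for f in cohort.findings:
        w = windows.get(f.patient_id)
        if w is None or not w.included or \
                f.date not in set(w.surveillance_days):
            continue
        if f.category in (FindingCategory.clinical,
                          FindingCategory.surgical_evidence):
            symptoms.setdefault(
                (f.patient_id, f.body_system_hint.value), set()).add(f.date)

    def run_ok(pid: str, devices, onset: dt.date) -> Optional[Device]:
        for device in devices:
            days = device_days.get((pid, device), set())
            for anchor_off in (0, 1):
                day = onset - dt.timedelta(days=anchor_off)
                n = 0
                while day in days:
                    n += 1
                    day -= dt.timedelta(days=1)
                if n >= defs.device_assoc_min_days:
                    return device
        return None

    surgeries_by_pid: Dict[str, List[SurgeryRecord]] = {}
    for s in cohort.surgeries:
        surgeries_by_pid.setdefault(s.patient_id, []).append(s)

    stage: List[dict] = []
    for ev in sorted(truth, key=lambda e: (e.patient_id, e.onset_date,
                                           e.hai_type)):
        w = windows.get(ev.patient_id)
        if w is None or not w.included:
            continue
        patient = patients[ev.patient_id]
        dol = (ev.onset_date - patient.birth_date).days + 1
        if dol < defs.late_onset_hours // 24 + 1:
            continue
        rec = {
            "pid": ev.patient_id,
            "type": ev.hai_type,
            "onset": ev.onset_date,
            "system": ev.body_system,
            "start": min(ev.element_dates),
            "end": max(ev.element_dates),
            "device": None,
            "surgery": None,
            "organisms": {o: set(m) for o, m in ev.organisms},
        }
        if ev.body_system == "bloodstream":
            rec["device"] = run_ok(ev.patient_id, (Device.CVC, Device.PVC),
                                   ev.onset_date)
        elif ev.body_system == "respiratory":
            rec["device"] = run_ok(ev.patient_id, (Device.INV, Device.NIV),
                                   ev.onset_date)
        elif ev.body_system == "surgical_site":
            best = None
            for s in surgeries_by_pid.get(ev.patient_id, []):
                delta = (ev.onset_date - s.date).days
                if delta < 0:
                    continue
                ok = delta <= defs.ssi_window_days or (
                    delta <= defs.ssi_implant_window_days and s.implant
                    and ev.hai_type in ("ssi_deep", "ssi_organ_space"))
                if ok and (best is None or s.date > best.date):
                    best = s
            if best is None:
                continue  # SSI outside every attribution window
            rec["surgery"] = best.surgery_id
        stage.append(rec)

    # greedy repeat suppression per patient and organ system
    kept: List[dict] = []
    last: Dict[Tuple[str, str], dict] = {}
    for rec in stage:
        key = (rec["pid"], rec["system"])
        prev = last.get(key)
        if prev is not None:
            waited = (rec["onset"] - prev["onset"]).days >= \
                defs.repeat_min_days
            sdays = symptoms.get(key, set())
            free = 0
            day = prev["end"] + dt.timedelta(days=1)
            while day < rec["start"]:
                if day not in sdays:
                    free += 1
                day += dt.timedelta(days=1)
            if not (waited and free >= defs.symptom_free_min_days):
                for o, m in rec["organisms"].items():
                    prev["organisms"].setdefault(o, set()).update(m)
                prev["end"] = max(prev["end"], rec["end"])
                continue
        last[key] = rec
        kept.append(rec)

    return sorted(
        (
            rec["pid"],
            rec["type"],
            rec["onset"].isoformat(),
            rec["device"].value if rec["device"] else None,
            rec["surgery"],
            tuple(sorted((o, tuple(sorted(m)))
                         for o, m in rec["organisms"].items())),
            any(rec["organisms"].values()),
        )
        for rec in kept
    )
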