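"""Episode assembly and rule-based infection classification.

The classifier turns dated findings and microbiology results into a line
list of healthcare-associated infections:

1.  *Episode assembly* — within one patient and body system, elements are
    chained into an episode while consecutive elements are no more than
    ``episode_max_gap_days`` apart and the whole episode spans no more than
    ``episode_max_span_days``.
2.  *Infection date* — the first symptom day, or the earlier primary-site
    positive specimen date if one precedes symptoms.
3.  *Late-onset gate* — only infections with onset at least 72 h after
    birth are healthcare-associated; earlier episodes are dropped.
4.  *Taxonomy* — bloodstream episodes become laboratory-confirmed BSI
    (recognized pathogen, or common commensal with clinical and laboratory
    support) or clinical sepsis; respiratory episodes pneumonia;
    gastrointestinal episodes necrotizing enterocolitis; surgical-site
    episodes an SSI of the depth its criterion codes indicate.
5.  *Attribution* — device association via the continuous three-day rule,
    SSI attribution via the 30/90-day post-surgical windows.
6.  *Repeat suppression* — within one organ system, a new episode within
    14 days of a registered infection (or without an intervening
    symptom-free day) is merged into it rather than counted.
7.  Optional secondary-BSI linking.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .cohort import (
    BSI_TYPES,
    BodySystem,
    Cohort,
    Device,
    Finding,
    FindingCategory,
    HaiType,
    MicrobiologyResult,
    OrganismClass,
    PatientRecord,
    SSI_TYPES,
    SurgeryRecord,
    ValidationError,
)
from .config import DefinitionsConfig
from .eligibility import SurveillanceWindow
from .exposure import day_of_life, device_day_dates

#: body system each infection type belongs to
HAI_BODY_SYSTEM = {
    HaiType.clinical_sepsis: BodySystem.bloodstream,
    HaiType.lcbsi_pathogen: BodySystem.bloodstream,
    HaiType.lcbsi_commensal: BodySystem.bloodstream,
    HaiType.secondary_bsi: BodySystem.bloodstream,
    HaiType.pneumonia: BodySystem.respiratory,
    HaiType.nec: BodySystem.gastrointestinal,
    HaiType.ssi_superficial: BodySystem.surgical_site,
    HaiType.ssi_deep: BodySystem.surgical_site,
    HaiType.ssi_organ_space: BodySystem.surgical_site,
}

#: candidate devices per infection family, in attribution precedence order
DEVICE_PRECEDENCE = {
    BodySystem.bloodstream: (Device.CVC, Device.PVC),
    BodySystem.respiratory: (Device.INV, Device.NIV),
}

_SSI_DEPTH_CODES = (
    ("SSI_ORGAN_SPACE", HaiType.ssi_organ_space),
    ("SSI_DEEP", HaiType.ssi_deep),
    ("SSI_SUPERFICIAL", HaiType.ssi_superficial),
)


@dataclass
class CandidateEpisode:
    """A temporally clustered set of findings and cultures proposed as one
    infection event."""

    patient_id: str
    body_system: BodySystem
    findings: List[Finding] = field(default_factory=list)
    micro: List[MicrobiologyResult] = field(default_factory=list)

    def element_dates(self) -> List[dt.date]:
        return sorted(
            [f.date for f in self.findings]
            + [m.specimen_date for m in self.micro]
        )

    @property
    def start(self) -> dt.date:
        return self.element_dates()[0]

    @property
    def end(self) -> dt.date:
        return self.element_dates()[-1]


@dataclass
class ClassifiedHAI:
    """A finalized infection with type, date, attribution and organisms."""

    patient_id: str
    hai_type: HaiType
    infection_date: dt.date
    day_of_life: int
    late_onset: bool
    device_association: Optional[Device] = None
    linked_surgery_id: Optional[str] = None
    organisms: Tuple[Tuple[str, FrozenSet], ...] = ()
    is_mdro: bool = False
    mdro_markers: FrozenSet = frozenset()
    secondary_to: Optional[str] = None  # "<hai_type>@<infection_date>"
    episode: Optional[CandidateEpisode] = None

    @property
    def body_system(self) -> BodySystem:
        return HAI_BODY_SYSTEM[self.hai_type]


# ---------------------------------------------------------------------------
# 1. episode assembly

def assemble_episodes(
    findings: Sequence[Finding],
    micro: Sequence[MicrobiologyResult],
    config: DefinitionsConfig,
) -> List[CandidateEpisode]:
    """Chain dated elements into maximal episodes per patient and body
    system.

    Elements are processed in date order; an element joins the current
    episode if its gap to the previous element is at most
    ``episode_max_gap_days`` and the episode's span stays within
    ``episode_max_span_days``; otherwise it starts a new episode.  Every
    element belongs to exactly one episode.
    """
    groups: Dict[Tuple[str, BodySystem], List] = {}
    for f in findings:
        groups.setdefault((f.patient_id, f.body_system_hint), []).append(
            (f.date, 0, f))
    for m in micro:
        groups.setdefault((m.patient_id, m.body_system), []).append(
            (m.specimen_date, 1, m))

    episodes: List[CandidateEpisode] = []
    for (pid, system), elements in sorted(
            groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        elements.sort(key=lambda t: (t[0], t[1]))
        current: Optional[CandidateEpisode] = None
        episode_start: Optional[dt.date] = None
        prev_date: Optional[dt.date] = None
        for date, kind, element in elements:
            new_episode = (
                current is None
                or (date - prev_date).days > config.episode_max_gap_days
                or (date - episode_start).days > config.episode_max_span_days
            )
            if new_episode:
                current = CandidateEpisode(pid, system)
                episodes.append(current)
                episode_start = date
            if kind == 0:
                current.findings.append(element)
            else:
                current.micro.append(element)
            prev_date = date
        # elements already date-sorted within each episode
    episodes.sort(key=lambda e: (e.patient_id, e.body_system.value, e.start))
    return episodes


# ---------------------------------------------------------------------------
# 2. infection date

def _symptom_dates(episode: CandidateEpisode) -> List[dt.date]:
    return sorted(
        f.date for f in episode.findings
        if f.category in (FindingCategory.clinical,
                          FindingCategory.surgical_evidence)
    )


def _primary_site_dates(episode: CandidateEpisode) -> List[dt.date]:
    return sorted(
        m.specimen_date for m in episode.micro
        if m.body_system == episode.body_system
    )


def determine_infection_date(episode: CandidateEpisode) -> dt.date:
    """First symptom day, or the earlier primary-site positive specimen date
    when the laboratory result precedes symptom onset."""
    symptoms = _symptom_dates(episode)
    cultures = _primary_site_dates(episode)
    if not symptoms and not cultures:
        raise ValidationError(
            f"{episode.patient_id}: episode starting {episode.start} has "
            "neither symptoms nor a primary-site positive result"
        )
    candidates = symptoms[:1] + cultures[:1]
    return min(candidates)


# ---------------------------------------------------------------------------
# 3. late onset

def is_late_onset(
    infection_date: dt.date,
    birth_date: dt.date,
    birth_time: Optional[dt.time] = None,
    onset_time: Optional[dt.time] = None,
    config: Optional[DefinitionsConfig] = None,
) -> bool:
    """Onset at least 72 h after birth.

    With both birth and onset times the comparison is exact in hours; with
    date-only data it falls back to day of life >= 4, which is equivalent to
    >= 72 full hours at day granularity.
    """
    config = config or DefinitionsConfig()
    if birth_time is not None and onset_time is not None:
        birth_dt = dt.datetime.combine(birth_date, birth_time)
        onset_dt = dt.datetime.combine(infection_date, onset_time)
        return onset_dt - birth_dt >= dt.timedelta(
            hours=config.late_onset_hours)
    return day_of_life(infection_date, birth_date) >= (
        config.late_onset_hours // 24 + 1)


# ---------------------------------------------------------------------------
# 4. taxonomy

def _count_matching(episode: CandidateEpisode, requirement: dict) -> int:
    codes = set(requirement["codes"])
    category = FindingCategory(requirement["category"])
    return sum(
        1 for f in episode.findings
        if f.category is category and f.criterion_code in codes
    )


def _satisfies(episode: CandidateEpisode, alternatives: List[List[dict]]) -> bool:
    return any(
        all(_count_matching(episode, req) >= req["min_count"] for req in reqs)
        for reqs in alternatives
    )


def _organism_classes(episode, organism_catalog):
    pathogens, commensals = [], []
    for m in episode.micro:
        if m.body_system != episode.body_system:
            continue
        entry = organism_catalog.get(m.organism)
        if entry is None:
            raise ValidationError(
                f"{episode.patient_id}: unknown organism key {m.organism!r}"
            )
        if entry.organism_class is OrganismClass.recognized_pathogen:
            pathogens.append(m)
        else:
            commensals.append(m)
    return pathogens, commensals


def classify_episode(
    episode: CandidateEpisode,
    organism_catalog,
    config: DefinitionsConfig,
) -> Optional[HaiType]:
    """Assign the matching infection type, or None when no criterion set is
    satisfied.

    Within bloodstream episodes laboratory evidence dominates: recognized
    pathogen > common commensal (with clinical and laboratory support) >
    clinical sepsis (no organism detected).
    """
    system = episode.body_system
    if system is BodySystem.bloodstream:
        pathogens, commensals = _organism_classes(episode, organism_catalog)
        if pathogens and _satisfies(episode, config.criteria["lcbsi_pathogen"]):
            return HaiType.lcbsi_pathogen
        if commensals and _satisfies(episode,
                                     config.criteria["lcbsi_commensal"]):
            return HaiType.lcbsi_commensal
        if not pathogens and not commensals and _satisfies(
                episode, config.criteria["clinical_sepsis"]):
            return HaiType.clinical_sepsis
        return None
    if system is BodySystem.respiratory:
        if _satisfies(episode, config.criteria["pneumonia"]):
            return HaiType.pneumonia
        return None
    if system is BodySystem.gastrointestinal:
        if _satisfies(episode, config.criteria["nec"]):
            return HaiType.nec
        return None
    if system is BodySystem.surgical_site:
        if not _satisfies(episode, config.criteria["ssi"]):
            return None
        present = {f.criterion_code for f in episode.findings}
        for code, depth_type in _SSI_DEPTH_CODES:  # deepest first
            if code in present:
                return depth_type
        return None
    return None


def episode_organisms(episode: CandidateEpisode) -> Tuple:
    """Primary-site organisms of an episode as sorted (key, markers) pairs."""
    pairs = {}
    for m in episode.micro:
        if m.body_system != episode.body_system:
            continue
        pairs[m.organism] = pairs.get(m.organism, frozenset()) | \
            m.resistance_markers
    return tuple(sorted(pairs.items()))


def flag_mdro(organisms: Sequence[Tuple[str, FrozenSet]]):
    """An infection is MDRO-involved iff any organism carries at least one
    resistance marker; all markers are aggregated."""
    markers = frozenset().union(*(m for _, m in organisms)) if organisms \
        else frozenset()
    return bool(markers), markers


# ---------------------------------------------------------------------------
# 5. attribution

def _run_length_ending(day: dt.date, qualifying: set) -> int:
    n = 0
    while day in qualifying:
        n += 1
        day -= dt.timedelta(days=1)
    return n


def assess_device_association(
    hai_type: HaiType,
    infection_date: dt.date,
    device_days: Dict[Device, set],
    config: DefinitionsConfig,
) -> Optional[Device]:
    """Device label for a device-assessable infection.

    Association requires a run of at least ``device_assoc_min_days``
    consecutive qualifying device-days ending on the onset day or the day
    immediately preceding it.  Venous catheters are checked CVC before PVC,
    ventilation INV before NIV; the first qualifying device wins.
    """
    system = HAI_BODY_SYSTEM[hai_type]
    candidates = DEVICE_PRECEDENCE.get(system, ())
    for device in candidates:
        days = device_days.get(device, set())
        for anchor in (infection_date,
                       infection_date - dt.timedelta(days=1)):
            if _run_length_ending(anchor, days) >= config.device_assoc_min_days:
                return device
    return None


def attribute_ssi(
    depth_type: HaiType,
    infection_date: dt.date,
    surgeries: Sequence[SurgeryRecord],
    config: DefinitionsConfig,
) -> Optional[str]:
    """Link an SSI to the most recent prior surgery whose post-operative
    window covers the onset: 30 days for every depth, 90 days for deep and
    organ/space infections after an implant."""
    best: Optional[SurgeryRecord] = None
    for s in surgeries:
        delta = (infection_date - s.date).days
        if delta < 0:
            continue
        if delta <= config.ssi_window_days:
            qualifies = True
        elif (delta <= config.ssi_implant_window_days and s.implant
              and depth_type in (HaiType.ssi_deep, HaiType.ssi_organ_space)):
            qualifies = True
        else:
            qualifies = False
        if qualifies and (best is None or s.date > best.date
                          or (s.date == best.date
                              and s.surgery_id < best.surgery_id)):
            best = s
    return best.surgery_id if best else None


# ---------------------------------------------------------------------------
# 6. repeat suppression

def suppress_repeats(
    infections: Sequence[ClassifiedHAI],
    config: DefinitionsConfig,
    symptom_dates_by_system: Optional[Dict[Tuple[str, BodySystem], set]] = None,
) -> List[ClassifiedHAI]:
    """Greedy left-to-right suppression per patient and organ system.

    A later episode in the same organ system is merged into the previous
    registered infection (its organisms appended, not counted) unless at
    least ``repeat_min_days`` have passed since that infection's date AND at
    least ``symptom_free_min_days`` symptom-free calendar days lie strictly
    between the two episodes.  A new pathogen alone never opens a new
    infection inside the window.
    """
    symptom_dates_by_system = symptom_dates_by_system or {}
    kept: List[ClassifiedHAI] = []
    last_kept_idx: Dict[Tuple[str, BodySystem], int] = {}
    ordered = sorted(
        infections,
        key=lambda h: (h.patient_id, h.infection_date, h.hai_type.value),
    )
    for hai in ordered:
        key = (hai.patient_id, hai.body_system)
        idx = last_kept_idx.get(key)
        if idx is None:
            last_kept_idx[key] = len(kept)
            kept.append(hai)
            continue
        prev = kept[idx]
        waited = (hai.infection_date - prev.infection_date).days \
            >= config.repeat_min_days
        free = _symptom_free_days_between(
            prev, hai, symptom_dates_by_system.get(key, set())
        ) >= config.symptom_free_min_days
        if waited and free:
            last_kept_idx[key] = len(kept)
            kept.append(hai)
        else:
            kept[idx] = _merge_organisms(prev, hai)
    return kept


def _symptom_free_days_between(prev: ClassifiedHAI, nxt: ClassifiedHAI,
                               symptom_dates: set) -> int:
    prev_end = prev.episode.end if prev.episode else prev.infection_date
    nxt_start = nxt.episode.start if nxt.episode else nxt.infection_date
    free = 0
    day = prev_end + dt.timedelta(days=1)
    while day < nxt_start:
        if day not in symptom_dates:
            free += 1
        day += dt.timedelta(days=1)
    return free


def _merge_organisms(prev: ClassifiedHAI, other: ClassifiedHAI) -> ClassifiedHAI:
    pairs = dict(prev.organisms)
    for organism, markers in other.organisms:
        pairs[organism] = pairs.get(organism, frozenset()) | markers
    organisms = tuple(sorted(pairs.items()))
    is_mdro, markers = flag_mdro(organisms)
    episode = prev.episode
    if episode is not None and other.episode is not None:
        episode = CandidateEpisode(
            prev.patient_id, prev.body_system,
            findings=sorted(episode.findings + other.episode.findings,
                            key=lambda f: f.date),
            micro=sorted(episode.micro + other.episode.micro,
                         key=lambda m: m.specimen_date),
        )
    return replace(prev, organisms=organisms, is_mdro=is_mdro,
                   mdro_markers=markers, episode=episode)


# ---------------------------------------------------------------------------
# 7. secondary BSI

def link_secondary_bsi(
    infections: Sequence[ClassifiedHAI],
    config: DefinitionsConfig,
) -> List[ClassifiedHAI]:
    """Flag laboratory-confirmed BSIs secondary to an active pneumonia, NEC
    or SSI of the same patient.

    A primary is *active* from its infection date through
    ``secondary_bsi_active_days`` days after it.  When the primary has
    documented organisms, organism concordance is additionally required
    (configurable).
    """
    out: List[ClassifiedHAI] = []
    primaries = [
        h for h in infections
        if h.hai_type in frozenset({HaiType.pneumonia, HaiType.nec})
        | SSI_TYPES
    ]
    for hai in infections:
        if hai.hai_type not in (HaiType.lcbsi_pathogen,
                                HaiType.lcbsi_commensal):
            out.append(hai)
            continue
        window_start = hai.episode.start if hai.episode else hai.infection_date
        window_end = hai.episode.end if hai.episode else hai.infection_date
        link = None
        for p in primaries:
            if p.patient_id != hai.patient_id:
                continue
            active_end = p.infection_date + dt.timedelta(
                days=config.secondary_bsi_active_days)
            if window_end < p.infection_date or window_start > active_end:
                continue
            if p.organisms and config.secondary_bsi_requires_organism_match:
                shared = {o for o, _ in p.organisms} & \
                    {o for o, _ in hai.organisms}
                if not shared:
                    continue
            link = p
            break
        if link is None:
            out.append(hai)
        else:
            out.append(replace(
                hai, hai_type=HaiType.secondary_bsi,
                secondary_to=f"{link.hai_type.value}@{link.infection_date}",
            ))
    return out


# ---------------------------------------------------------------------------
# full pipeline

def classify_cohort(
    cohort: Cohort,
    windows: Dict[str, SurveillanceWindow],
    config: DefinitionsConfig,
    organism_catalog,
) -> Tuple[List[ClassifiedHAI], List[str]]:
    """Run the whole classification pipeline for a cohort.

    Returns the final infection line list (after the late-onset gate, SSI
    attribution, repeat suppression and optional secondary-BSI linking) and
    a list of warnings for skipped elements.
    """
    warnings: List[str] = []
    patients = {p.patient_id: p for p in cohort.patients}

    findings, micro = [], []
    for f in cohort.findings:
        w = windows.get(f.patient_id)
        if w is None or not w.included:
            continue
        if f.date not in set(w.surveillance_days):
            warnings.append(
                f"{f.patient_id}: finding on {f.date} outside the "
                "surveillance window; ignored"
            )
            continue
        findings.append(f)
    for m in cohort.microbiology:
        w = windows.get(m.patient_id)
        if w is None or not w.included:
            continue
        if m.specimen_date not in set(w.surveillance_days):
            warnings.append(
                f"{m.patient_id}: specimen on {m.specimen_date} outside "
                "the surveillance window; ignored"
            )
            continue
        micro.append(m)

    episodes = assemble_episodes(findings, micro, config)

    classified: List[ClassifiedHAI] = []
    for episode in episodes:
        hai_type = classify_episode(episode, organism_catalog, config)
        if hai_type is None:
            continue
        onset = determine_infection_date(episode)
        patient = patients[episode.patient_id]
        late = is_late_onset(onset, patient.birth_date, config=config)
        if not late:
            continue  # early onset: outside the healthcare-associated scope

        organisms = episode_organisms(episode)
        is_mdro, markers = flag_mdro(organisms)
        hai = ClassifiedHAI(
            patient_id=episode.patient_id,
            hai_type=hai_type,
            infection_date=onset,
            day_of_life=day_of_life(onset, patient.birth_date),
            late_onset=True,
            organisms=organisms,
            is_mdro=is_mdro,
            mdro_markers=markers,
            episode=episode,
        )

        if hai_type in SSI_TYPES:
            surgeries = [s for s in cohort.surgeries
                         if s.patient_id == episode.patient_id]
            surgery_id = attribute_ssi(hai_type, onset, surgeries, config)
            if surgery_id is None:
                warnings.append(
                    f"{episode.patient_id}: surgical-site episode on {onset} "
                    "has no surgery within the attribution window; not "
                    "counted as SSI"
                )
                continue
            hai = replace(hai, linked_surgery_id=surgery_id)
        elif HAI_BODY_SYSTEM[hai_type] in DEVICE_PRECEDENCE:
            w = windows[episode.patient_id]
            dd = {
                device: device_day_dates(cohort.exposures, w, device, config)
                for device in DEVICE_PRECEDENCE[HAI_BODY_SYSTEM[hai_type]]
            }
            hai = replace(hai, device_association=assess_device_association(
                hai_type, onset, dd, config))
        classified.append(hai)

    symptom_dates: Dict[Tuple[str, BodySystem], set] = {}
    for f in findings:
        if f.category in (FindingCategory.clinical,
                          FindingCategory.surgical_evidence):
            symptom_dates.setdefault(
                (f.patient_id, f.body_system_hint), set()).add(f.date)

    kept = suppress_repeats(classified, config, symptom_dates)
    if config.secondary_bsi_enabled:
        kept = link_secondary_bsi(kept, config)
    return kept, warnings
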