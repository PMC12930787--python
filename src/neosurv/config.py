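"""Surveillance definitions configuration and the organism catalog.

The case definitions are parameterised: temporal windows (episode assembly,
repeat suppression, onset cut-off, device association, post-surgical windows)
and the criterion sets each infection type requires.  Defaults implement the
core-module rules; every parameter can be overridden from YAML/JSON so a unit
can tighten or localise definitions without touching code.

Criterion codes are a closed vocabulary: a finding row whose code is not in
the active configuration is a validation error, which keeps the case
definitions auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import yaml

from .cohort import (
    BodySystem,
    FindingCategory,
    OrganismCatalogEntry,
    OrganismClass,
    ValidationError,
)

# Infection sites outside the surveillance scope (too rare in this population
# for meaningful rates); encountering one of these codes is a hard error with
# an explanatory message rather than silent omission.
OUT_OF_SCOPE_CODES = {
    "UTI_SIGN": "urinary tract infections",
    "BONE_JOINT_SIGN": "bone and joint infections",
    "CARDIOVASCULAR_SIGN": "cardiovascular infections",
}

#: code -> (finding category, body system) for the shipped vocabulary.
DEFAULT_CRITERION_CODES: Dict[str, Tuple[str, str]] = {
    "CLIN_SEPSIS_SIGN": ("clinical", "bloodstream"),
    "HEM_MENINGITIS": ("clinical", "bloodstream"),  # recorded as primary BSI
    "LAB_SEPSIS_MARKER": ("laboratory", "bloodstream"),
    "PNEU_CLINICAL": ("clinical", "respiratory"),
    "PNEU_IMAGING": ("imaging", "respiratory"),
    "PNEU_LAB": ("laboratory", "respiratory"),
    "NEC_CLINICAL": ("clinical", "gastrointestinal"),
    "NEC_RADIOLOGY": ("imaging", "gastrointestinal"),
    "NEC_SURGICAL": ("surgical_evidence", "gastrointestinal"),
    "SSI_LOCAL_SIGN": ("clinical", "surgical_site"),
    "SSI_SUPERFICIAL": ("clinical", "surgical_site"),
    "SSI_DEEP": ("clinical", "surgical_site"),
    "SSI_ORGAN_SPACE": ("clinical", "surgical_site"),
}

# Finding-based requirement sets per infection family.  Each family maps to a
# list of ALTERNATIVE requirement sets (any one satisfied suffices); a
# requirement is (category, allowed codes, minimum count).  Organism-based
# conditions (pathogen vs commensal blood culture) are intrinsic to the
# taxonomy and live in the classifier, not here.
DEFAULT_CRITERIA: Dict[str, List[List[dict]]] = {
    # sepsis signs + laboratory marker; no organism detected
    "clinical_sepsis": [[
        {"category": "clinical",
         "codes": ["CLIN_SEPSIS_SIGN", "HEM_MENINGITIS"], "min_count": 1},
        {"category": "laboratory", "codes": ["LAB_SEPSIS_MARKER"],
         "min_count": 1},
    ]],
    # commensal culture must be accompanied by the same clinical+laboratory set
    "lcbsi_commensal": [[
        {"category": "clinical",
         "codes": ["CLIN_SEPSIS_SIGN", "HEM_MENINGITIS"], "min_count": 1},
        {"category": "laboratory", "codes": ["LAB_SEPSIS_MARKER"],
         "min_count": 1},
    ]],
    # a recognized-pathogen blood culture suffices on its own
    "lcbsi_pathogen": [[]],
    "pneumonia": [[
        {"category": "clinical", "codes": ["PNEU_CLINICAL"], "min_count": 1},
        {"category": "imaging", "codes": ["PNEU_IMAGING"], "min_count": 1},
        {"category": "laboratory", "codes": ["PNEU_LAB"], "min_count": 1},
    ]],
    # clinical + radiological findings, or surgical evidence alone
    "nec": [
        [
            {"category": "clinical", "codes": ["NEC_CLINICAL"],
             "min_count": 1},
            {"category": "imaging", "codes": ["NEC_RADIOLOGY"],
             "min_count": 1},
        ],
        [
            {"category": "surgical_evidence", "codes": ["NEC_SURGICAL"],
             "min_count": 1},
        ],
    ],
    # local signs plus a depth marker; depth decides the SSI subtype
    "ssi": [[
        {"category": "clinical", "codes": ["SSI_LOCAL_SIGN"], "min_count": 1},
        {"category": "clinical",
         "codes": ["SSI_SUPERFICIAL", "SSI_DEEP", "SSI_ORGAN_SPACE"],
         "min_count": 1},
    ]],
}


@dataclass
class DefinitionsConfig:
    """Temporal parameters and criterion sets of the case definitions.

    Attributes
    ----------
    episode_max_span_days
        Maximum span (first to last element, in days) of one infection
        episode.  Default 10, the permissive end of the 7-10 day guideline.
    episode_max_gap_days
        Maximum gap between consecutive elements of one episode.  Default 3,
        the permissive end of the 2-3 day guideline.
    repeat_min_days
        Days that must pass after an infection date before the same type can
        be registered again (14).
    symptom_free_min_days
        Minimum number of symptom-free calendar days required between
        consecutive registered episodes of the same type (length of the
        required symptom-free period is otherwise unspecified; default 1).
    late_onset_hours
        Age (hours after birth) from which an infection counts as late-onset
        and therefore healthcare-associated (72).
    device_assoc_min_days
        Length of the continuous device-use run required for
        device-association (3), ending on the onset day or the day before.
    ssi_window_days / ssi_implant_window_days
        Post-surgical attribution windows: 30 days for every depth, extended
        to 90 days for deep-incisional and organ/space infections when an
        implant was placed.
    device_day_min_hours
        Cumulative device hours a day needs to count as a device-day (12).
    kangaroo_min_hours
        Skin-to-skin hours a day needs to count as a kangaroo-care day (2).
    """

    episode_max_span_days: int = 10
    episode_max_gap_days: int = 3
    repeat_min_days: int = 14
    symptom_free_min_days: int = 1
    late_onset_hours: int = 72
    device_assoc_min_days: int = 3
    ssi_window_days: int = 30
    ssi_implant_window_days: int = 90
    device_day_min_hours: float = 12.0
    kangaroo_min_hours: float = 2.0
    secondary_bsi_enabled: bool = False
    secondary_bsi_requires_organism_match: bool = True
    secondary_bsi_active_days: int = 14
    criteria: Dict[str, List[List[dict]]] = field(
        default_factory=lambda: json.loads(json.dumps(DEFAULT_CRITERIA))
    )
    criterion_codes: Dict[str, Tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_CRITERION_CODES)
    )

    def validate(self) -> None:
        for name in (
            "episode_max_span_days", "episode_max_gap_days",
            "repeat_min_days", "symptom_free_min_days", "late_onset_hours",
            "device_assoc_min_days", "ssi_window_days",
            "ssi_implant_window_days",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.episode_max_span_days < self.episode_max_gap_days:
            raise ValidationError(
                "episode_max_span_days must be >= episode_max_gap_days"
            )
        if not 0 < self.device_day_min_hours <= 24:
            raise ValidationError("device_day_min_hours must be in (0, 24]")
        if not 0 < self.kangaroo_min_hours <= 24:
            raise ValidationError("kangaroo_min_hours must be in (0, 24]")
        for code in self.criterion_codes:
            if code in OUT_OF_SCOPE_CODES:
                raise ValidationError(
                    f"criterion code {code}: {OUT_OF_SCOPE_CODES[code]} are "
                    "outside the surveillance scope (excluded for rarity in "
                    "this population) and cannot be configured"
                )
            cat, system = self.criterion_codes[code]
            FindingCategory(cat)
            BodySystem(system)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["criterion_codes"] = {k: list(v) for k, v in
                                self.criterion_codes.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DefinitionsConfig":
        d = dict(d)
        if "criterion_codes" in d:
            d["criterion_codes"] = {
                k: tuple(v) for k, v in d["criterion_codes"].items()
            }
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "DefinitionsConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable hash echoed into reports so benchmark comparability is
        machine-checkable."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Organism catalog

DEFAULT_ORGANISMS = [
    # recognized pathogens
    ("escherichia_coli", "Escherichia coli", "recognized_pathogen"),
    ("klebsiella_pneumoniae", "Klebsiella pneumoniae", "recognized_pathogen"),
    ("staphylococcus_aureus", "Staphylococcus aureus", "recognized_pathogen"),
    ("enterococcus_faecium", "Enterococcus faecium", "recognized_pathogen"),
    ("pseudomonas_aeruginosa", "Pseudomonas aeruginosa",
     "recognized_pathogen"),
    ("streptococcus_agalactiae", "Streptococcus agalactiae",
     "recognized_pathogen"),
    ("candida_albicans", "Candida albicans", "recognized_pathogen"),
    ("serratia_marcescens", "Serratia marcescens", "recognized_pathogen"),
    # common commensals
    ("staphylococcus_epidermidis", "Staphylococcus epidermidis",
     "common_commensal"),
    ("corynebacterium_spp", "Corynebacterium spp.", "common_commensal"),
    ("micrococcus_spp", "Micrococcus spp.", "common_commensal"),
    ("bacillus_spp", "Bacillus spp.", "common_commensal"),
]


def default_organism_catalog() -> Dict[str, OrganismCatalogEntry]:
    """Small bundled catalog; user-extensible via :func:`load_organism_catalog`."""
    return {
        key: OrganismCatalogEntry(key, name, OrganismClass(cls))
        for key, name, cls in DEFAULT_ORGANISMS
    }


def load_organism_catalog(path) -> Dict[str, OrganismCatalogEntry]:
    """Read a catalog from YAML/JSON: list of {key, display_name, class}."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    catalog: Dict[str, OrganismCatalogEntry] = {}
    for entry in raw:
        key = entry["key"]
        if key in catalog:
            raise ValidationError(f"duplicate organism key {key!r}")
        catalog[key] = OrganismCatalogEntry(
            key, entry.get("display_name", key),
            OrganismClass(entry["class"]),
        )
    return catalog


def save_organism_catalog(catalog, path) -> None:
    rows = [
        {"key": e.key, "display_name": e.display_name,
         "class": e.organism_class.value}
        for e in catalog.values()
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(rows, fh, sort_keys=False, allow_unicode=True)


def catalog_hash(catalog) -> str:
    rows = sorted(
        (e.key, e.display_name, e.organism_class.value)
        for e in catalog.values()
    )
    return hashlib.sha256(json.dumps(rows).encode()).hexdigest()[:16]
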