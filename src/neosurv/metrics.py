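"""Unit-level surveillance rates, stratified by birth-weight group.

All formulas are simple ratios; what matters is the bookkeeping around
them:

* use rate          = 100 x factor-days / patient-days
* agent detection   = 100 x infections-with-agent / infections
* agent/infection   = 100 x detected agents / infections-with-agent
* incidence density = 1000 x infections / patient-days
* device-assoc.     = 1000 x device-associated infections / device-days
* SSI rate          = 100 x SSIs / surgeries (overall and per procedure group)

A zero denominator yields "absent" (None), never 0 or NaN, so reports can
distinguish no exposure from no events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .cohort import (
    Cohort,
    Device,
    HaiType,
    PatientRecord,
    SSI_TYPES,
    ValidationError,
)
from .classify import ClassifiedHAI, HAI_BODY_SYSTEM
from .exposure import ExposureSummary

#: birth-weight strata, half-open bins
STRATA = ("<500 g", "500-999 g", "1000-1499 g", ">=1500 g")
_STRATUM_EDGES = (500, 1000, 1500)


def assign_stratum(birth_weight: int) -> str:
    """Half-open birth-weight bins [0,500), [500,1000), [1000,1500),
    [1500, inf); the last bin holds very preterm infants above 1499 g."""
    if birth_weight <= 0:
        raise ValidationError("birth_weight must be positive")
    for edge, label in zip(_STRATUM_EDGES, STRATA):
        if birth_weight < edge:
            return label
    return STRATA[3]


@dataclass
class StratumAggregate:
    """Counts and denominators for one birth-weight stratum."""

    stratum: str
    n_patients: int = 0
    patient_days: int = 0
    device_days: Dict[Device, int] = field(
        default_factory=lambda: {d: 0 for d in Device})
    antibiotic_days: int = 0
    breast_milk_days: int = 0
    probiotic_days: int = 0
    kangaroo_days: int = 0
    infections: Dict[HaiType, int] = field(
        default_factory=lambda: {t: 0 for t in HaiType})
    device_associated: Dict[Device, int] = field(
        default_factory=lambda: {d: 0 for d in Device})
    mdro_infections: int = 0
    infections_with_agent: int = 0
    agents_detected: int = 0

    @property
    def total_infections(self) -> int:
        return sum(self.infections.values())


def aggregate_by_stratum(
    patients: Sequence[PatientRecord],
    summaries: Dict[str, ExposureSummary],
    infections: Sequence[ClassifiedHAI],
) -> Dict[str, StratumAggregate]:
    """Fold per-patient summaries and the infection line list into the four
    birth-weight strata.  Sums over strata equal the pooled totals by
    construction."""
    aggregates = {label: StratumAggregate(label) for label in STRATA}
    stratum_of = {p.patient_id: assign_stratum(p.birth_weight)
                  for p in patients}

    for pid, summary in summaries.items():
        agg = aggregates[stratum_of[pid]]
        agg.n_patients += 1
        agg.patient_days += summary.patient_days
        for device in Device:
            agg.device_days[device] += summary.device_days[device]
        agg.antibiotic_days += summary.antibiotic_days_total
        agg.breast_milk_days += summary.breast_milk_days
        agg.probiotic_days += summary.probiotic_days
        agg.kangaroo_days += summary.kangaroo_days

    for hai in infections:
        agg = aggregates[stratum_of[hai.patient_id]]
        agg.infections[hai.hai_type] += 1
        if hai.device_association is not None:
            agg.device_associated[hai.device_association] += 1
        if hai.is_mdro:
            agg.mdro_infections += 1
        if hai.organisms:
            agg.infections_with_agent += 1
            agg.agents_detected += len(hai.organisms)
    return aggregates


# ---------------------------------------------------------------------------
# rate formulas

def use_rate(factor_days: int, patient_days: int) -> Optional[float]:
    """Percent of patient-days on which the factor was in use."""
    if factor_days < 0 or patient_days < 0:
        raise ValidationError("negative inputs to use_rate")
    if factor_days > patient_days:
        raise ValidationError(
            f"factor_days {factor_days} exceeds patient_days {patient_days}"
        )
    if patient_days == 0:
        return None
    return 100.0 * factor_days / patient_days


def agent_detection_rate(n_with_agent: int, n_infections: int
                         ) -> Optional[float]:
    """Percent of infections in which at least one agent was detected."""
    if n_with_agent > n_infections:
        raise ValidationError(
            "infections with agent exceed total infections"
        )
    if n_infections == 0:
        return None
    return 100.0 * n_with_agent / n_infections


def agent_per_infection_rate(n_agents: int, n_with_agent: int
                             ) -> Optional[float]:
    """Detected agents per hundred agent-positive infections; exceeds 100
    when infections are polymicrobial."""
    if n_agents < n_with_agent:
        raise ValidationError(
            "agents detected cannot be fewer than agent-positive infections"
        )
    if n_with_agent == 0:
        return None
    return 100.0 * n_agents / n_with_agent


def incidence_density(n_infections: int, patient_days: int
                      ) -> Optional[float]:
    """Infections per 1000 patient-days."""
    if patient_days == 0:
        return None
    return 1000.0 * n_infections / patient_days


def device_associated_density(n_device_associated: int, device_days: int
                              ) -> Optional[float]:
    """Device-associated infections per 1000 device-days."""
    if device_days == 0:
        return None
    return 1000.0 * n_device_associated / device_days


def ssi_rates(
    ssi_cases: Sequence[ClassifiedHAI],
    surgeries: Sequence,
    group_prefix_length: int = 3,
) -> Dict[str, Optional[float]]:
    """Overall SSI percent plus per-procedure-group percents.

    Procedures are grouped by the leading characters of the main ICHI code
    (default 3).  Groups without surgeries report no rate; an SSI without a
    linked surgery is an error.
    """
    for ssi in ssi_cases:
        if ssi.hai_type not in SSI_TYPES:
            raise ValidationError(f"{ssi.hai_type} is not an SSI type")
        if ssi.linked_surgery_id is None:
            raise ValidationError(
                f"{ssi.patient_id}: SSI on {ssi.infection_date} has no "
                "linked surgery"
            )
    surgery_by_id = {s.surgery_id: s for s in surgeries}
    groups: Dict[str, List] = {}
    for s in surgeries:
        groups.setdefault(
            s.main_procedure_code[:group_prefix_length], []).append(s)

    out: Dict[str, Optional[float]] = {}
    out["overall"] = (
        100.0 * len(ssi_cases) / len(surgery_by_id) if surgery_by_id else None
    )
    ssi_by_group: Dict[str, int] = {}
    for ssi in ssi_cases:
        surgery = surgery_by_id.get(ssi.linked_surgery_id)
        if surgery is None:
            raise ValidationError(
                f"SSI linked to unknown surgery {ssi.linked_surgery_id!r}"
            )
        prefix = surgery.main_procedure_code[:group_prefix_length]
        ssi_by_group[prefix] = ssi_by_group.get(prefix, 0) + 1
    for prefix, members in sorted(groups.items()):
        out[prefix] = 100.0 * ssi_by_group.get(prefix, 0) / len(members)
    return out


def stratified_metrics(aggregates: Dict[str, StratumAggregate]) -> List[dict]:
    """Long-format metric rows (metric x stratum plus pooled), ready for the
    unit report CSV/JSON."""
    rows: List[dict] = []
    pooled = StratumAggregate("all")
    for agg in aggregates.values():
        pooled.n_patients += agg.n_patients
        pooled.patient_days += agg.patient_days
        for d in Device:
            pooled.device_days[d] += agg.device_days[d]
            pooled.device_associated[d] += agg.device_associated[d]
        pooled.antibiotic_days += agg.antibiotic_days
        pooled.breast_milk_days += agg.breast_milk_days
        pooled.probiotic_days += agg.probiotic_days
        pooled.kangaroo_days += agg.kangaroo_days
        for t in HaiType:
            pooled.infections[t] += agg.infections[t]
        pooled.mdro_infections += agg.mdro_infections
        pooled.infections_with_agent += agg.infections_with_agent
        pooled.agents_detected += agg.agents_detected

    for label, agg in list(aggregates.items()) + [("all", pooled)]:
        pd_ = agg.patient_days
        rows.append({"stratum": label, "metric": "patients",
                     "value": agg.n_patients})
        rows.append({"stratum": label, "metric": "patient_days",
                     "value": pd_})
        for device in Device:
            rows.append({
                "stratum": label,
                "metric": f"{device.value.lower()}_use_rate_pct",
                "value": use_rate(agg.device_days[device], pd_),
            })
            rows.append({
                "stratum": label,
                "metric": f"{device.value.lower()}_associated_per_1000_device_days",
                "value": device_associated_density(
                    agg.device_associated[device], agg.device_days[device]),
            })
        for name, days in (
            ("antibiotic", agg.antibiotic_days),
            ("breast_milk", agg.breast_milk_days),
            ("probiotic", agg.probiotic_days),
            ("kangaroo", agg.kangaroo_days),
        ):
            rows.append({
                "stratum": label, "metric": f"{name}_use_rate_pct",
                "value": use_rate(days, pd_),
            })
        rows.append({
            "stratum": label, "metric": "hai_per_1000_patient_days",
            "value": incidence_density(agg.total_infections, pd_),
        })
        for t in HaiType:
            rows.append({
                "stratum": label,
                "metric": f"{t.value}_per_1000_patient_days",
                "value": incidence_density(agg.infections[t], pd_),
            })
        rows.append({
            "stratum": label, "metric": "mdro_per_1000_patient_days",
            "value": incidence_density(agg.mdro_infections, pd_),
        })
        rows.append({
            "stratum": label, "metric": "agent_detection_rate_pct",
            "value": agent_detection_rate(
                agg.infections_with_agent, agg.total_infections),
        })
        rows.append({
            "stratum": label, "metric": "agent_per_infection_rate_pct",
            "value": agent_per_infection_rate(
                agg.agents_detected, agg.infections_with_agent),
        })
    return rows
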