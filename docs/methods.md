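# Methods

This note documents the surveillance model the engine implements, the
parameters that govern it, the synthetic-data generator used for testing,
and the numerical/design choices made where the surveillance definitions leave
room.

## Population and follow-up

The surveillance population is live-born infants with birth weight
< 1500 g and/or gestational age < 32 completed weeks, admitted within 120
days of birth. Both comparisons are strict: 1500 g at exactly 32+0 weeks is
excluded. Follow-up ends at death, discharge or transfer; absences of up to
48 hours are bridged into one surveillance episode. With date-granular
inputs the gap between two stays is counted as 24 h per full calendar day
strictly between them, so a two-full-day absence merges and a three-day
absence ends the episode — a conservative, reproducible convention at day
granularity. Days fully absent during a bridged gap are not surveillance
days. A re-admission after a longer gap is reported as a warning and not
enrolled into the episode; the case definitions do not define re-enrollment, so
the engine defaults to a single reported episode per infant.

Day of life is 1-based: the day of birth is day 1. This makes the
date-granular fallback of the 72 h onset rule "day of life ≥ 4", which is
exactly ≥ 72 full hours when the birth time is unknown; when both birth and
onset times are available the comparison is exact in hours.

## Exposure accounting

Every factor is counted in whole surveillance days:

| factor | qualifies when | default threshold |
|---|---|---|
| patient-day | any presence on the unit that day | none |
| device-day (CVC/PVC/INV/NIV) | cumulative device hours ≥ threshold | 12 h |
| antibiotic day | ≥ 1 systemic substance recorded | — |
| exclusive breast-milk day | enteral feeding exclusively breast milk | — |
| probiotic day | oral probiotic given | — |
| kangaroo-care day | skin-to-skin hours ≥ threshold | 2 h |

Hours are accepted as fractions; thresholds are ≥ comparisons on exact
values. Antibiotic days are additionally kept per substance; per-substance
counts are each bounded by patient-days but their sum may exceed the
cumulative count (a day with two substances is one antibiotic day).
Exposure rows outside the surveillance window are ignored with a warning.
Whether a day partially spent absent counts as a patient-day is not
specified by the case definitions; the engine counts any day with recorded
presence.

## Episode assembly and classification

Findings and cultures are grouped per patient and body system (cultures
speak for the system of their specimen type: blood → bloodstream,
respiratory → respiratory, wound → surgical site). Elements chain into one
episode while consecutive elements are at most `episode_max_gap_days`
apart and the episode spans at most `episode_max_span_days`. The case definitions
state ranges (2–3 days between elements, 7–10 days overall); the engine
defaults to the permissive end (gap 3, span 10) and both are configurable.

The infection date is the first symptom day (clinical or
surgical-evidence finding), or the earlier primary-site positive specimen
date when the laboratory result precedes symptoms. Only late-onset
episodes (≥ 72 h after birth) enter the HAI line list.

Within bloodstream episodes laboratory evidence dominates: a recognized
pathogen in blood makes the episode a laboratory-confirmed BSI regardless
of other criteria; a common commensal requires clinical *and* laboratory
support; clinical sepsis requires those findings with *no* detected
organism. Hematogenous meningitis is recorded as primary BSI through a
criterion code rather than a separate type. Respiratory episodes require
clinical, imaging and laboratory findings (pneumonia); gastrointestinal
episodes require clinical plus radiological findings or surgical evidence
alone (NEC); surgical-site episodes require local signs plus a depth
marker, the deepest marker present deciding the subtype. Urinary tract,
bone/joint and cardiovascular infections are outside the surveillance
scope (too rare in this population); their criterion codes are rejected
with an explanatory message. The finding-level criterion sets are
configuration data (a closed, auditable vocabulary); the shipped defaults
are deliberately small single-code sets per category, standing in for the
full clinical criterion lists, which units can extend in YAML.

Device association holds when ≥ `device_assoc_min_days` (3) consecutive
qualifying device-days end on the onset day or the day immediately before
it. Venous catheters are checked CVC before PVC, ventilation INV before
NIV — attribution to the higher-risk device on ties, configurable in
precedence. SSIs attribute to the most recent prior surgery with onset at
most 30 days after surgery, extended to 90 days for deep/organ-space
depths when an implant was placed; ties between same-day surgeries break
on surgery id. The 30-day comparison is `onset − surgery ≤ 30` days.

Repeat suppression is greedy and per organ system: a later episode merges
into the previous registered infection (organisms appended, episode span
extended, not counted) unless ≥ 14 days have passed since that infection's
date *and* at least `symptom_free_min_days` symptom-free calendar days lie
strictly between the episodes. The case definitions require a symptom-free
period without a length; the default is 1 day. A new pathogen alone never
opens a new infection inside the window. Because type and organ system
coincide in this taxonomy, suppression per organ system also enforces the
same-type rule.

Secondary-BSI linking is optional (off by default, `--enable-secondary-bsi`
on the CLI). A laboratory-confirmed BSI is flagged secondary when an
active pneumonia/NEC/SSI of the same patient overlaps it; "active" is
defined here as the 14 days from the primary's infection date (the same
horizon as repeat suppression), configurable. When the primary has
documented organisms, organism concordance is additionally required
(configurable); a primary without organisms (e.g. NEC) links on temporal
overlap alone.

An infection is MDRO-involved iff any of its organisms carries at least
one resistance marker (MRSA, VRE, 3GCR, carbapenem or colistin
resistance); markers are inputs, no MIC interpretation is attempted.

Findings and cultures dated outside a patient's surveillance window are
ignored (with a warning), extending to clinical elements the rule applied to exposure rows: an HAI must occur under surveillance.

## Rates and the standardized infection ratio

All rates are simple ratios (see README for the formulas), stratified into
four birth-weight groups with half-open bins [0,500), [500,1000),
[1000,1500), [1500,∞); the last group holds very preterm infants above
1499 g. Division by zero yields *absent* (null in JSON, empty in CSV),
never 0 or NaN, so "no exposure" and "no events" stay distinguishable.
CSV rates are rounded to 2 decimals; JSON keeps full precision. Specific
SSI rates group procedures by the leading 3 characters of the main ICHI
code by default (configurable); an overall SSI rate is always computed
because procedure counts per group are small in this population.

Expected infections are indirectly standardized over birth-weight stratum
× day-of-life band. Band edges are a free choice of the surveillance configuration; the default
bands are 1–3, 4–7, 8–14, 15–28 and ≥ 29 days, chosen to resolve the
early, unstable phase where risk concentrates. The band edges and the
definitions-config hash are echoed into every report and checked when
aggregating, because benchmarks are only comparable across identical
configurations. SIR is computed overall and per infection type. Expected
= 0 with observed > 0 is reported as incalculable with the observed count,
never as infinity. The ≥ 1500 g stratum contributes to reference data by
default.

Self-benchmarking is the analytic anchor: pooling a single unit's
aggregate into reference rates makes every cell's expected count equal its
observed count, so the SIR is exactly 1.0 — this is asserted in the test
suite and recomputed by `scripts/acceptance.py`.

## Synthetic cohorts and what the tests show

The generator emulates a mid-size unit over a quarter year: ~50 admissions
per run in the default tests, birth-weight mix (5 / 30 / 50 / 15 % across
the four strata) with correlated gestational ages, a geometric length of
stay with mean 35 days, a few percent ineligible/late-admitted/stillborn
records to exercise the inclusion rules, occasional split stays around the
48 h rule, device episodes with partial last-day hours around the 12 h
rule, and late-onset infection hazards of a few events per 1000
patient-days emitted as findings + cultures the classifier can
rediscover. One seeded generator stream is consumed in a fixed
per-patient order, so a seed fixes every table byte-identically.

Within one patient and body system the generator leaves at least
`episode_max_gap_days + 1` days between elements of consecutive planted
events (including non-infection controls: lone commensal cultures and
isolated findings). This guarantees a 1:1 correspondence between planted
events and assembled episodes, which is what makes exact recovery testable;
it is a property of the generator, not an assumption of the classifier.
The recovery oracle re-derives onset gating, device association, surgical
attribution and repeat suppression from the planted truth and the raw
exposure/surgery tables with inline logic, independent of the
episode-assembly path under test.

Consequences for interpretation: passing recovery tests show the rules are
implemented exactly as specified on well-separated events; they do not
show robustness to real-world messiness the generator omits — overlapping
multi-organ presentations, criteria trickling in over many days, specimen
mislabeling, or transfers between facilities. Statistical tests (incidence
density within 3 binomial SE of 1000 × hazard on ~50,000 patient-days; SIR
within 3/√E of 1.0 under true-hazard references) check calibration of the
whole pipeline, at problem sizes chosen to keep the default test run fast
(900 fixed-stay patients for the large run; 100 × 50-patient cohorts for
recovery).

## Known limitations

* Date-granular rules throughout: without recorded times, the 48 h and
  72 h rules operate on full calendar days as described above.
* The bundled organism catalog and criterion vocabulary are small,
  user-extensible defaults, not exhaustive clinical lists.
* No statistical inference on rates or SIRs (no confidence intervals or
  significance tests) — rates and ratios are descriptive by design.
* Antimicrobial use is counted in days, not defined daily doses.
* Re-enrollment after a > 48 h absence and cross-facility linkage are out
  of scope; the engine reports and excludes such episodes.
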