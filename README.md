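# neosurv

A surveillance engine for healthcare-associated infections (HAIs) in
high-risk newborns — very-low-birth-weight (< 1500 g) and very preterm
(< 32 weeks' gestation) infants on neonatal units. It is written for
infection-prevention-and-control teams, neonatologists and surveillance
networks who need reproducible, rule-based case classification and
benchmarkable rates from routinely collected patient-level data.

From six delimited input tables (demographics/admission, unit stays, daily
exposures, surgeries, clinical/laboratory/imaging findings, microbiology)
the engine:

* decides **eligibility** (live-born, birth weight < 1500 g and/or
  gestational age < 32 completed weeks, admitted within 120 days of birth)
  and computes each infant's **surveillance window**, bridging absences of
  up to 48 h;
* accounts **denominators**: patient-days, device-days (central/peripheral
  venous catheter, invasive/noninvasive ventilation; ≥ 12 h cumulative per
  day), antibiotic days (cumulative and per substance), exclusive
  breast-milk, probiotic and kangaroo-care (≥ 2 h) days;
* assembles dated findings and cultures into **infection episodes**
  (elements at most 3 days apart, episode span at most 10 days) and
  classifies them: laboratory-confirmed bloodstream infection (recognized
  pathogen, or common commensal with clinical *and* laboratory support),
  clinical sepsis, pneumonia, necrotizing enterocolitis, and surgical site
  infections in three depths;
* applies the temporal rules: only **late-onset** episodes (≥ 72 h after
  birth) count as healthcare-associated; **device association** requires
  three consecutive device-days ending on the onset day or the day before;
  SSIs attribute to surgery within **30 days** (90 days for deep/organ-space
  infections after an implant); repeats of the same organ system within
  **14 days** (or without a symptom-free day) merge into the registered
  infection; multidrug-resistant organisms are flagged from resistance
  markers (MRSA, VRE, 3GCR, carbapenem/colistin resistance);
* computes the **metrics**, stratified by birth weight
  (<500 g, 500–999 g, 1000–1499 g, ≥1500 g):

  ```
  use rate                 = 100  × factor-days / patient-days
  agent detection rate     = 100  × infections with agent / infections
  agent-per-infection rate = 100  × agents detected / infections with agent
  incidence density        = 1000 × infections / patient-days
  device-assoc. density    = 1000 × device-associated infections / device-days
  SSI rate                 = 100  × SSIs / surgical procedures
  ```

* benchmarks via the **standardized infection ratio**. Expected counts are
  indirectly standardized over birth-weight stratum × day-of-life band:
  E = Σ_c λ_c · d_c with reference rate λ_c and unit patient-days d_c per
  cell, and SIR = O / E. SIR = 1.0 means observed matches expected.

A synthetic-cohort generator (`neosurv.simulate`) produces complete,
seed-reproducible input tables with planted, recoverable infections, so the
whole engine is testable without any real patient data.

## Worked example

```python
from neosurv import SimulationConfig, generate_with_truth, run_unit_analysis
from neosurv.sir import aggregate_reference, compute_sir

cohort, truth = generate_with_truth(SimulationConfig(n_patients=50, seed=42))
analysis = run_unit_analysis(cohort)

pd_total = sum(s.patient_days for s in analysis.summaries.values())
print(analysis.metadata["n_patients_included"], "included;",
      pd_total, "patient-days;", len(analysis.infections), "HAIs")

reference = aggregate_reference([analysis.sir_aggregate])
print("self-benchmark SIR:", compute_sir(analysis.sir_aggregate, reference).sir)
```

prints

```
48 included; 1365 patient-days; 13 HAIs
self-benchmark SIR: 1.0
```

Of the 50 simulated admissions, 48 meet the inclusion criteria and
contribute 1365 surveillance days. Thirteen late-onset infections survive
the classification rules (for seed 42: 5 pneumonia, 2 pathogen and
2 commensal bloodstream infections, 1 clinical sepsis, 1 necrotizing
enterocolitis, 2 organ/space surgical site infections), an overall
incidence density of 9.52 per 1000 patient-days. Benchmarking the unit
against reference rates derived from its own aggregate necessarily yields
SIR = 1.0 — the analytic anchor of the method.

The same workflow is available from the shell:

```bash
neosurv simulate --output unit/ --seed 42 --n-patients 50
neosurv validate --input unit/
neosurv report   --input unit/ --output report/
neosurv aggregate --aggregate report/sir_aggregate.json --output bench/
neosurv sir      --input unit/ --reference bench/reference_rates.yaml \
                 --output sir_out/
```

Unit reports contain the HAI line list, per-patient exposure summary,
stratified metric tables (CSV and JSON) and the shareable per-cell
aggregate; benchmark outputs contain aggregated data only.

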