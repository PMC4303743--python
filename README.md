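# haisurv

Trigger-based semi-automated surveillance of ventilator-associated
pneumonia (VAP) and central line-associated bloodstream infection
(CLABSI) in the intensive care unit.

## The problem

Manual surveillance of hospital-acquired infections requires an infection
prevention practitioner to review chest films and microbiology for *every*
patient-day — slow, expensive and error-prone. Because ICU record systems
already capture device status, antibiotic orders and vital signs daily, a
simple boolean **trigger** can pre-select the handful of patient-days worth
reviewing:

```
VAP trigger(day)    = ventilated(day)
                      AND iv antibiotic on the VAP list(day)
                      AND (T_max > 38 °C  OR  WBC < 4,000/mm³  OR  WBC > 12,000/mm³
                           OR purulent sputum)

CLABSI trigger(day) = central line present(day)
                      AND iv antibiotic on the CLABSI list(day)
                      AND (T_max > 38 °C  OR  SBP_min < 90 mmHg)
```

Only triggered days go to the manual *active* part: VAP is confirmed by
lung infiltrates/consolidations on ≥ 2 consecutive days; CLABSI by a blood
culture growing a pathogen or a catheter tip growing ≥ 10 colonies of one.
Exhaustive ("traditional") screening applies the same confirmation rules
to every patient-day and serves as the gold standard. Because trigger mode
only restricts which days are checked, its false-positive count is
structurally zero — specificity and PPV are 100% by construction — and the
evaluation reduces to sensitivity, NPV, incidence agreement and workload.

The package implements, for epidemiologists and infection-prevention
teams:

- the daily trigger rule with configurable agent lists, thresholds and an
  iv-route filter (so universal enteral decontamination prophylaxis never
  fires it);
- cohort construction: ≥ 48 h length-of-stay inclusion, merging of ≤ 24 h
  readmissions, an 8-week surveillance cap, withdrawal-of-treatment
  censoring, and pneumonia-on-admission exclusion from VAP surveillance;
- case confirmation with first-episode-per-admission accounting and an
  explicit two-reviewer adjudication override;
- device-day denominators (per concurrent line, truncated at infection
  onset), incidence per 1,000 device-days with Poisson-approximation CIs,
  patient-level 2×2 screening performance with Wilson/Clopper–Pearson
  CIs, and workload estimates (≈ 1 min per check);
- a synthetic ICU cohort generator with ground-truth labels and plantable
  trigger-failure modes (late antibiotic start; line removal without
  antibiotics), so every stage is testable without patient data.

## Worked example

```python
from haisurv import incidence_rate, performance_from_counts, workload

incidence_rate(13, 3927).rounded()        # 13 VAP / 3,927 ventilation days
# (3.3, 1.5, 5.1)                         # per 1,000 days (95% CI)

vap = performance_from_counts(tp=12, fn=1, fp=0, tn=409)   # of 422 eligible
round(vap.sensitivity.percent, 1), round(vap.npv.percent, 1)
# (92.3, 99.8)

w = workload(patient_days=6793, vap_trigger_days=359, clabsi_trigger_days=983)
round(w.traditional_hours_per_week, 1), round(w.trigger_minutes_per_week)
# (4.4, 26)                               # 90% workload reduction
```

A 2×2 of (12 both / 1 gold-only / 0 trigger-only / 409 neither) yields
92.3% sensitivity and 99.8% NPV for the trigger screen, and pre-selecting
359 + 983 = 1,342 of 6,793 patient-days cuts the manual review from
4.4 h to 26 min per week.

End to end on synthetic data (`python examples/run_surveillance.py`):

```
== VAP (n eligible = 420) ==
incidence (traditional): 4.7/1,000 device days (95% CI 2.6 to 6.9); 19 events / 4014 days
...
 sensitivity:  84.2%  (62.43 to 94.48)  [16/19]
 specificity: 100.0%  (99.05 to 100.00)  [401/401]
...
workload reduction: 90%
```

Here the generator planted 19 VAP episodes; the trigger missed 3, every
one attributable to a planted antibiotic-start delay — the miss mechanism
the rule is inherently blind to.

The `examples/` directory holds one short script per capability
(simulation, daily triggers, end-to-end surveillance, summary-count
statistics), and the `haisurv` CLI mirrors the weekly batch workflow:

```bash
haisurv simulate --out-dir cohort --seed 1
haisurv evaluate cohort --out-dir results
```

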