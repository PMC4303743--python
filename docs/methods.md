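# Methods

## Surveillance model

The engine operates at patient-day granularity: one record per calendar
day aggregates the day's device status, antibiotic administrations and
clinical-observation extremes (maximum temperature, WBC minimum and
maximum, systolic-pressure minimum, coded sputum descriptors). Daily
aggregation matches how ICU record systems batch surveillance extracts;
where the reduction of multiple daily measurements is ambiguous we use
the daily extreme in the direction of the criterion (e.g. maximum
temperature against the fever threshold).

**Trigger (automated part).** A VAP trigger fires on a day iff the
patient is mechanically ventilated, receives ≥ 1 VAP-list antibiotic via
a qualifying route, and shows ≥ 1 qualifying symptom; the CLABSI trigger
analogously with central-line presence, the CLABSI list, and
fever/hypotension. All comparisons are strict (> 38.0 °C, < 4,000,
> 12,000 /mm³, < 90 mmHg) and all factors must co-occur on the *same*
day — this same-day conjunction is exactly what makes the rule blind to
infections whose treatment starts after the clinical signs subside.
Missing observations evaluate as criterion-not-met; the automated factors
(device, antibiotics) are mandatory inputs and their absence is a parse
error. Only iv administrations qualify by default: in an ICU running
selective digestive decontamination every long-stay patient receives
enteral tobramycin and colistin prophylactically, and tobramycin is on
the VAP treatment list, so without the route filter the trigger would
fire on nearly every febrile ventilated patient. The filter is
configuration, not hard-coded. Agent names are matched case-insensitively
through a configurable synonym map (e.g. "sulfamethoxazole and
trimethoprim" ≡ cotrimoxazole).

**Confirmation (active part).** Candidate days are trigger days (trigger
mode) or all patient-days (traditional mode). VAP requires a run of
≥ 2 consecutive infiltrate/consolidation days intersecting a ± 2-day
window around a candidate day; single-day densities are treated as
transient edema and never confirm. CLABSI requires, within ± 2 days of a
candidate day, a blood culture growing an organism adjudicated as a
pathogen or a catheter-tip culture at/above the ten-colony threshold.
The window half-widths are configuration: no protocol fixes how far
X-ray and culture turnaround may straddle the trigger day, so the choice
is surfaced rather than hidden (widening a window can only add
confirmations). Subjective steps — pathogen vs contaminant, inconclusive
films, "respiratory deterioration" — enter as coded inputs plus an
explicit consensus `Adjudication` record (`reject` vetoes, `confirm`
resolves); a culture of undetermined pathogen class with no adjudication
yields a `needs_review` episode excluded from automated counts. Only the
first episode per admission and infection type is kept, with onset at
the earliest qualifying candidate day. In traditional mode this earliest
candidate can precede the clinical onset by up to the window width; the
resulting shift of the device-day truncation point is ≤ 2 days per
infected stay (≈ 0.7% of the denominator at study scale).

**Cohort rules.** Same-patient stays separated by ≤ 24 h are merged
(readmission later than that counts as a new patient); length of stay is
assessed on timestamps, so exactly 48 h is included and an overnight
47.9-h stay is not. Whether the 48-h minimum applies before or after
merging is not dictated by the protocol; we merge first (configurable).
Day records are censored at day 56 and from the withdrawal-of-treatment
date onward (the withdrawal day itself is censored: no further
diagnostics or targeted antibiotics occur). Pneumonia-on-admission stays
are excluded from VAP surveillance only; CLABSI surveillance covers the
full included cohort.

**Statistics.** Device days accrue until discharge, or until the onset
day (inclusive) for stays with a confirmed episode of that type.
Central-line days default to per-concurrent-line counting — the only
reading under which ≈ 2 line-days per patient-day reconciles with a
study-scale cohort's ≈ 13,900 line days over ≈ 6,800 patient-days — with
a per-patient-day mode for NHSN-style comparisons. The VAP denominator
is computed over the VAP-eligible (pneumonia-free) subset, which is the
reading under which events/denominator estimates the per-ventilation-day
hazard. Incidence per 1,000 device-days carries a normal-approximation
Poisson CI, `rate ± z·1000·√events / device_days`, floored at zero; this
is the method that reproduces the reference rate intervals exactly, and
it degenerates to a zero-width interval at zero events (an exact Poisson
interval is deliberately not silently substituted). Screening
performance is a patient-level 2×2 (trigger vs exhaustive) restricted to
the stays eligible for the type; proportion CIs default to Wilson with
Clopper–Pearson as an option — published interval sets of this kind are
often internally inconsistent with any single method, so point estimates
are the comparable surface. Workload counts one ≈ 1-minute check per
candidate day per infection type over all included stays, 52 weeks per
year; the reduction fraction is `1 − trigger_minutes/traditional_minutes`.

## Synthetic cohort generator

The generator emulates a year of a mixed 24-bed ICU: `n_patients = 553`
includable stays (plus 47 sub-48-h stays to exercise inclusion), length
of stay from a log-normal with raw mean 11.7 d and SD 11.6 d truncated to
[2, 56] d (truncated mean ≈ 11.4 d; a stay of length L spans E[L] + 1
calendar dates, giving ≈ 6,870 expected patient-days), 25% pneumonia on
admission, ventilation on a per-stay prefix of days with overall fraction
0.77 (so the pneumonia-free subset carries ≈ 3,930 ventilation days), and
a per-day central-line count from a Poisson truncated at 4 with mean
2.044 (≈ 13,900 line-days). Infection hazards are memoryless per-device-
day Bernoulli draws: VAP 3.3 × 10⁻³ per ventilated day (eligible stays),
CLABSI 1.7 × 10⁻³ per line-day, yielding ≈ 13 and ≈ 24 expected episodes.
Episodes are planted only up to day min(stay, 54) and ≥ 3 days clear of
any withdrawal date, so confirmability never hinges on the censor
boundary and every trigger-mode miss is attributable to a planted
mechanism.

A planted VAP produces fever (plus probabilistic purulent sputum and
leukocytosis) for 3 days from onset, a 3-day infiltrate run, and iv
ceftazidime starting `onset + delay`, with the delay drawn from a
configurable mass on {0,1,2,3} days (default 0.87/0.03/0.02/0.08,
putting ≈ 8% of episodes beyond the symptom window — about one missed
VAP per 13). A planted CLABSI is either treated — persistent fever until
treatment, blood cultures drawn on every febrile day, iv vancomycin —
or, with probability 0.083 (≈ 2 in 24), managed by line removal without
antibiotics, with only a positive catheter-tip culture; the latter is
invisible to an antibiotic-based trigger by design. Background trigger
noise is generated independently of infection status: unrelated iv
antibiotic courses coinciding with incidental fever/leukocytosis/
hypotension (per-day probabilities 0.062 and 0.153, calibrated in closed
form so ≈ 5.3% of days fire the VAP trigger and ≈ 14.5% the CLABSI
trigger), single-day transient densities (never adjacent, never in a
stay with a real infiltrate run), and contaminant blood cultures. SDD
prophylaxis (enteral tobramycin/colistin/amphotericin B daily, iv
cefotaxime days 1–3) is emitted on every stay to exercise the route
filter. ICU mortality (~23%) and rare withdrawal-of-treatment censoring
(~2 stays/year) are cosmetic covariates.

What passing tests on this generator do show: the rule engine, cohort
accounting, confirmation logic, denominators and the structural
subset/failure-mode claims are correct, and the estimators recover the
configured hazards. What they do not show: robustness to real-data
phenomena the generator omits — deviations from the antibiotic policy,
documentation gaps in nurse-coded fields, infiltrate runs from
non-infectious causes, polymicrobial or ambiguous cultures, correlated
device use and acuity, or between-patient frailty (hazards here are
homogeneous; a heterogeneity hook is reserved in the config).

## Numerical and design choices

- Ties and ordering: first-episode selection takes the minimum onset day
  and is order-invariant; candidate days are scanned in ascending order.
- Catheter-tip growth scales: qualitative +/++/+++ plates (from the
  100 µl subculture) rank at/above the 10-colony threshold;
  `lt10_colonies` ranks below. Only that boundary is load-bearing.
- Radiology/culture dates before admission or > 60 days after admission
  are ignored with a warning; post-discharge dates inside that horizon
  still count, since films and cultures are reviewed ~2 weeks after
  discharge and an episode on the last stay days must remain confirmable.
- Degenerate inputs: zero device-days is an undefined-rate error, an
  empty eligible set is an error for the 2×2, an empty cohort yields
  empty outputs everywhere else.
- The truncated-Poisson rate for the line-count distribution is solved by
  bisection to 80 iterations; truncated log-normal sampling is by
  rejection.
- Reproducibility: a single integer seed drives `numpy.random.default_rng`;
  identical config + seed gives byte-identical output files.

## Known limitations

- Worsening gas exchange (VAP) and cold shivers (CLABSI) are deliberately
  not part of the rule set; neither is free-text processing of radiology
  or nursing notes — findings arrive pre-coded.
- The trigger depends on strict adherence to the antibiotic policy;
  infections treated off-list or untreated are invisible to it (the
  CLABSI line-removal pathway is the modelled instance).
- Onset-day assignment in exhaustive mode is window-limited rather than
  clinical; see the truncation note above.
- The generator draws line counts i.i.d. per day rather than modelling
  line dwell times; per-line attribution of CLABSI to a specific catheter
  is out of scope.
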