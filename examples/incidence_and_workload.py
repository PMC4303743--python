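"""Incidence rates, screening performance and workload from summary counts.

The statistics layer can be driven directly from aggregate surveillance
counts (events, device-days, 2x2 outcomes, trigger-day totals), e.g. to
re-analyse a published surveillance year.
"""

from haisurv import incidence_rate, performance_from_counts, workload

# 13 VAP over 3,927 ventilation days; 24 CLABSI over 13,887 line days
for label, events, dd in (("VAP", 13, 3927), ("CLABSI", 24, 13887)):
    rate = incidence_rate(events, dd)
    r, lo, hi = rate.rounded()
    print(f"{label}: {r}/1,000 device days (95% CI {lo} to {hi})")

# trigger screening vs gold standard, patient level
vap = performance_from_counts(tp=12, fn=1, fp=0, tn=409)
print(f"VAP trigger screening: sensitivity {vap.sensitivity.percent:.1f}%, "
      f"NPV {vap.npv.percent:.1f}%, specificity {vap.specificity.percent:.0f}%, "
      f"PPV {vap.ppv.percent:.0f}%")

# workload: 1 min per patient-day per infection type, 52 weeks
w = workload(patient_days=6793, vap_trigger_days=359, clabsi_trigger_days=983)
print(f"exhaustive screening: {w.traditional_hours:.0f} h/year "
      f"({w.traditional_hours_per_week:.1f} h/week)")
print(f"trigger-based:        {w.trigger_hours:.0f} h/year "
      f"({w.trigger_minutes_per_week:.0f} min/week)")
print(f"workload reduction:   {100 * w.reduction_fraction:.0f}%")
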