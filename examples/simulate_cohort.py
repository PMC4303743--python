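"""Generate a study-scale synthetic ICU cohort and inspect its marginals.

The generator emulates one year of a mixed ICU under surveillance:
~600 raw stays of which 553 meet the 48-h inclusion minimum, truncated
log-normal lengths of stay, 25% pneumonia on admission, ~77% of
patient-days ventilated, ~2 concurrent central lines per patient-day,
and low per-device-day infection hazards with ground-truth labels.
"""

import numpy as np

from haisurv import build_cohort, generate_cohort, paperlike_config, vap_eligible
from haisurv.model import InfectionType

sim = generate_cohort(paperlike_config(seed=0))
built, exclusions = build_cohort(sim.cohort)

print(f"raw stays:        {len(sim.cohort.stays)}")
print(f"included stays:   {len(built.stays)} "
      f"({sum(e.excluded for e in exclusions)} excluded below 48 h)")
print(f"patient-days:     {len(built.days)}")
print(f"mean LOS (days):  {np.mean([s.los_hours / 24 for s in built.stays]):.1f}")
print(f"pneumonia on admission: {sum(s.pneumonia_on_admission for s in built.stays)} "
      f"({100 * np.mean([s.pneumonia_on_admission for s in built.stays]):.0f}%)")
print(f"VAP-eligible stays:     {len(vap_eligible(built.stays))}")
print(f"ventilated day fraction: {np.mean([d.mech_ventilation for d in built.days]):.2f}")
print(f"mean lines per day:      {np.mean([d.n_lines for d in built.days]):.2f}")

vap = [g for g in sim.ground_truth if g.infection_type is InfectionType.VAP]
clabsi = [g for g in sim.ground_truth if g.infection_type is InfectionType.CLABSI]
print(f"planted VAP episodes:    {len(vap)} "
      f"({sum(g.failure_mode != 'none' for g in vap)} with a trigger-failure mode)")
print(f"planted CLABSI episodes: {len(clabsi)} "
      f"({sum(g.line_removal_only for g in clabsi)} managed by line removal only)")
# Each planted episode records its onset day and failure mode, so any
# screening miss downstream can be traced back to its mechanism.
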