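"""Evaluate the daily VAP/CLABSI triggers on single patient-days.

The trigger is a same-day conjunction of three factor groups: device,
infection-specific iv antibiotic, and at least one clinical symptom.
Enteral prophylaxis (selective digestive decontamination) never fires it.
"""

import datetime as dt

from haisurv import evaluate_day
from haisurv.model import AntibioticAdministration, DayRecord, LineType, Route


def day(**kw):
    base = dict(
        stay_id="demo", day_index=1, calendar_date=dt.date(2010, 1, 1),
        mech_ventilation=False,
    )
    base.update(kw)
    return DayRecord(**base)


# ventilated, iv ceftazidime, febrile -> VAP trigger fires
febrile = day(
    mech_ventilation=True,
    antibiotics=[AntibioticAdministration(agent="ceftazidime", route=Route.iv)],
    temp_max=38.6,
)
res = evaluate_day(febrile)
print("ventilated + iv ceftazidime + 38.6 C:")
print(f"  VAP trigger: {res.vap_trigger}  factors: {res.vap_factors.model_dump()}")

# the same clinical picture under enteral SDD tobramycin -> no trigger
sdd = day(
    mech_ventilation=True,
    antibiotics=[AntibioticAdministration(agent="tobramycin", route=Route.enteral)],
    temp_max=39.0,
)
print(f"ventilated + enteral tobramycin + 39.0 C: VAP trigger: "
      f"{evaluate_day(sdd).vap_trigger}  (route filter)")

# triple-lumen line, iv vancomycin, hypotension -> CLABSI trigger fires
shocked = day(
    central_lines={LineType.triple_lumen: 1},
    antibiotics=[AntibioticAdministration(agent="vancomycin", route=Route.iv)],
    temp_max=37.4,
    sbp_min=82,
)
res = evaluate_day(shocked)
print("triple lumen + iv vancomycin + SBP 82:")
print(f"  CLABSI trigger: {res.clabsi_trigger}  factors: {res.clabsi_factors.model_dump()}")

# line removed the day before: the device factor is absent, no trigger
removed = day(
    antibiotics=[AntibioticAdministration(agent="vancomycin", route=Route.iv)],
    temp_max=39.1,
)
print(f"no line + iv vancomycin + 39.1 C: CLABSI trigger: "
      f"{evaluate_day(removed).clabsi_trigger}  (device factor absent)")
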