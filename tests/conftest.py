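import datetime as dt

import pytest

from haisurv.cohort import build_cohort
from haisurv.confirm import run_surveillance
from haisurv.model import (
    AntibioticAdministration,
    DayRecord,
    LineType,
    PatientStay,
    Route,
)
from haisurv.simulate import SimulationConfig, generate_cohort, paperlike_config

BASE = dt.datetime(2010, 1, 1, 8, 0)


def make_stay(
    stay_id="S1",
    patient_id=None,
    admission=BASE,
    los_hours=120.0,
    pneumonia=False,
    withdrawal_ts=None,
) -> PatientStay:
    return PatientStay(
        patient_id=patient_id or f"P-{stay_id}",
        stay_id=stay_id,
        admission_ts=admission,
        discharge_ts=admission + dt.timedelta(hours=los_hours),
        pneumonia_on_admission=pneumonia,
        withdrawal_ts=withdrawal_ts,
    )


def make_day(
    stay_id="S1",
    day_index=1,
    ventilated=False,
    lines=(),
    antibiotics=(),
    temp_max=37.0,
    wbc_min=6000.0,
    wbc_max=9000.0,
    sputum=(),
    sbp_min=120.0,
    admission_date=BASE.date(),
) -> DayRecord:
    line_counts: dict[LineType, int] = {}
    for token in lines:
        lt = LineType(token)
        line_counts[lt] = line_counts.get(lt, 0) + 1
    return DayRecord(
        stay_id=stay_id,
        day_index=day_index,
        calendar_date=admission_date + dt.timedelta(days=day_index - 1),
        mech_ventilation=ventilated,
        central_lines=line_counts,
        antibiotics=[
            AntibioticAdministration(agent=a, route=Route(r)) for a, r in antibiotics
        ],
        temp_max=temp_max,
        wbc_min=wbc_min,
        wbc_max=wbc_max,
        sputum_descriptors=list(sputum),
        sbp_min=sbp_min,
    )


def small_config(seed=0, **overrides) -> SimulationConfig:
    """A fast test-scale configuration with boosted hazards.

    Hazards are scaled up an order of magnitude so small cohorts carry a
    few episodes; the structural properties under test do not depend on
    the hazard level.
    """
    params = dict(
        n_patients=40,
        vap_hazard_per_vent_day=0.033,
        clabsi_hazard_per_line_day=0.017,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def paper_sim():
    """One study-scale synthetic cohort, generated once per session."""
    return generate_cohort(paperlike_config(seed=0))


@pytest.fixture(scope="session")
def paper_built(paper_sim):
    built, exclusions = build_cohort(paper_sim.cohort)
    return built, exclusions


@pytest.fixture(scope="session")
def paper_runs(paper_built):
    built, _ = paper_built
    return (
        run_surveillance(built, "trigger"),
        run_surveillance(built, "traditional"),
    )
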