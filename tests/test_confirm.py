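"""Case confirmation: radiology-run and culture rules, episodes, surveillance modes."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haisurv.cohort import build_cohort
from haisurv.confirm import (
    ConfirmationConfig,
    assign_episodes,
    confirm_clabsi,
    confirm_vap,
    run_surveillance,
)
from haisurv.model import (
    Adjudication,
    Cohort,
    CultureResult,
    GrowthQuantity,
    InfectionEpisode,
    InfectionType,
    PathogenClass,
    RadiologyFinding,
    Specimen,
)

from conftest import BASE, make_stay, small_config
from haisurv.simulate import generate_cohort

CONFIG = ConfirmationConfig()
STAY = make_stay(los_hours=30 * 24)


def findings(day_indices, positive=True):
    return [
        RadiologyFinding(
            stay_id=STAY.stay_id,
            calendar_date=STAY.date_of(d),
            infiltrate_or_consolidation=positive,
        )
        for d in day_indices
    ]


def tip_culture(day, quantity=GrowthQuantity.ge10_colonies, pclass=PathogenClass.pathogen):
    return CultureResult(
        stay_id=STAY.stay_id,
        calendar_date=STAY.date_of(day),
        specimen=Specimen.catheter_tip,
        organism="Staphylococcus aureus",
        quantity=quantity,
        pathogen_class=pclass,
    )


def blood_culture(day, organism="Escherichia coli", pclass=PathogenClass.pathogen):
    return CultureResult(
        stay_id=STAY.stay_id,
        calendar_date=STAY.date_of(day),
        specimen=Specimen.blood_from_line,
        organism=organism,
        quantity=GrowthQuantity.plus if organism != "no growth" else GrowthQuantity.none,
        pathogen_class=pclass,
    )


# --- VAP confirmation -------------------------------------------------------

def test_two_consecutive_infiltrate_days_confirm():
    ep = confirm_vap(STAY, [5], findings([5, 6]), config=CONFIG)
    assert ep is not None and ep.onset_day_index == 5
    assert ep.confirmation_basis["radiology_run_days"] == [5, 6]


def test_single_day_density_never_confirms():
    assert confirm_vap(STAY, [5], findings([5]), config=CONFIG) is None


def test_run_must_intersect_window():
    assert confirm_vap(STAY, [5], findings([10, 11]), config=CONFIG) is None
    assert confirm_vap(STAY, [5], findings([7, 8]), config=CONFIG) is not None


def test_onset_is_earliest_qualifying_candidate():
    ep = confirm_vap(STAY, [9, 4, 6], findings([6, 7]), config=CONFIG)
    assert ep.onset_day_index == 4


def test_vap_adjudication_veto_and_override():
    reject = Adjudication(stay_id=STAY.stay_id, infection_type=InfectionType.VAP, decision="reject")
    assert confirm_vap(STAY, [5], findings([5, 6]), adjudications=[reject], config=CONFIG) is None
    confirm = Adjudication(
        stay_id=STAY.stay_id,
        infection_type=InfectionType.VAP,
        decision="confirm",
        rationale="BAL culture and respiratory deterioration",
    )
    ep = confirm_vap(STAY, [8], [], adjudications=[confirm], config=CONFIG)
    assert ep is not None and ep.onset_day_index == 8
    assert ep.confirmation_basis["adjudication"] == "confirm"


def test_out_of_stay_radiology_is_ignored():
    pre_admission = [
        RadiologyFinding(
            stay_id=STAY.stay_id,
            calendar_date=STAY.admission_date - dt.timedelta(days=d),
            infiltrate_or_consolidation=True,
        )
        for d in (1, 2)
    ]
    assert confirm_vap(STAY, [1, 2], pre_admission, config=CONFIG) is None


def _oracle_confirm(candidates, positive_days, min_run=2, window=2):
    """Exhaustive scan over all runs of >= min_run consecutive positive days."""
    runs = []
    for start in positive_days:
        end = start
        while end + 1 in positive_days:
            end += 1
        if start - 1 not in positive_days and end - start + 1 >= min_run:
            runs.append((start, end))
    for day in sorted(candidates):
        for s, e in runs:
            if s <= day + window and e >= day - window:
                return day
    return None


@settings(max_examples=120, derandomize=True, deadline=None)
@given(
    st.sets(st.integers(min_value=1, max_value=20), min_size=1, max_size=6),
    st.sets(st.integers(min_value=1, max_value=20), min_size=0, max_size=10),
)
def test_vap_confirmation_matches_run_scan_oracle(candidates, positive_days):
    ep = confirm_vap(STAY, candidates, findings(sorted(positive_days)), config=CONFIG)
    expected = _oracle_confirm(candidates, positive_days)
    assert (ep.onset_day_index if ep else None) == expected


def test_widening_radiology_window_never_loses_a_case():
    rng = np.random.default_rng(5)
    for _ in range(150):
        candidates = set(rng.integers(1, 21, size=rng.integers(1, 5)).tolist())
        positive = set(rng.integers(1, 21, size=rng.integers(0, 8)).tolist())
        narrow = confirm_vap(STAY, candidates, findings(sorted(positive)), config=CONFIG)
        wide = confirm_vap(
            STAY,
            candidates,
            findings(sorted(positive)),
            config=ConfirmationConfig(radiology_window_days=4),
        )
        if narrow is not None:
            assert wide is not None


# --- CLABSI confirmation ----------------------------------------------------

def test_tip_culture_at_threshold_confirms():
    ep = confirm_clabsi(STAY, [8], [tip_culture(8)], config=CONFIG)
    assert ep is not None and ep.onset_day_index == 8


def test_no_growth_blood_culture_does_not_confirm():
    assert confirm_clabsi(
        STAY, [8], [blood_culture(8, organism="no growth", pclass=PathogenClass.undetermined)],
        config=CONFIG,
    ) is None


@pytest.mark.parametrize(
    "quantity,confirmed",
    [
        (GrowthQuantity.none, False),
        (GrowthQuantity.lt10_colonies, False),
        (GrowthQuantity.ge10_colonies, True),
        (GrowthQuantity.plus, True),
        (GrowthQuantity.plusplus, True),
        (GrowthQuantity.plusplusplus, True),
    ],
)
def test_tip_quantity_threshold_walkthrough(quantity, confirmed):
    organism = "no growth" if quantity is GrowthQuantity.none else "Staphylococcus aureus"
    culture = CultureResult(
        stay_id=STAY.stay_id,
        calendar_date=STAY.date_of(8),
        specimen=Specimen.catheter_tip,
        organism=organism,
        quantity=quantity,
        pathogen_class=PathogenClass.pathogen,
    )
    ep = confirm_clabsi(STAY, [8], [culture], config=CONFIG)
    assert (ep is not None) is confirmed


def test_contaminant_blood_culture_does_not_confirm():
    assert confirm_clabsi(
        STAY, [8],
        [blood_culture(8, organism="Staphylococcus epidermidis", pclass=PathogenClass.contaminant)],
        config=CONFIG,
    ) is None


def test_undetermined_culture_flags_needs_review():
    ep = confirm_clabsi(
        STAY, [8], [blood_culture(8, pclass=PathogenClass.undetermined)], config=CONFIG
    )
    assert ep is not None and ep.needs_review


def test_undetermined_resolved_by_adjudication():
    cultures = [blood_culture(8, pclass=PathogenClass.undetermined)]
    confirm = Adjudication(
        stay_id=STAY.stay_id, infection_type=InfectionType.CLABSI, decision="confirm"
    )
    ep = confirm_clabsi(STAY, [8], cultures, adjudications=[confirm], config=CONFIG)
    assert ep is not None and not ep.needs_review
    reject = Adjudication(
        stay_id=STAY.stay_id, infection_type=InfectionType.CLABSI, decision="reject"
    )
    assert confirm_clabsi(STAY, [8], cultures, adjudications=[reject], config=CONFIG) is None


def test_culture_outside_window_does_not_confirm():
    assert confirm_clabsi(STAY, [8], [blood_culture(12)], config=CONFIG) is None
    assert confirm_clabsi(STAY, [8], [blood_culture(10)], config=CONFIG) is not None


# --- first-episode assignment ----------------------------------------------

def episode(stay_id, itype, onset):
    return InfectionEpisode(stay_id=stay_id, infection_type=itype, onset_day_index=onset)


def test_first_episode_per_stay_and_type():
    eps = [
        episode("S1", InfectionType.VAP, 20),
        episode("S1", InfectionType.VAP, 5),
        episode("S1", InfectionType.CLABSI, 9),
        episode("S2", InfectionType.VAP, 3),
    ]
    kept = assign_episodes(eps)
    assert len(kept) == 3
    onsets = {(e.stay_id, e.infection_type): e.onset_day_index for e in kept}
    assert onsets[("S1", InfectionType.VAP)] == 5
    assert onsets[("S1", InfectionType.CLABSI)] == 9


def test_assignment_is_order_invariant():
    rng = np.random.default_rng(9)
    eps = [
        episode(f"S{rng.integers(0, 5)}", InfectionType(rng.choice(["VAP", "CLABSI"])), int(d))
        for d in rng.integers(1, 40, size=30)
    ]
    reference = assign_episodes(eps)
    for _ in range(5):
        rng.shuffle(eps)
        assert assign_episodes(eps) == reference


# --- surveillance modes -----------------------------------------------------

def test_traditional_ledger_counts_every_day_per_type(paper_built):
    built, _ = paper_built
    run = run_surveillance(built, "traditional")
    n = len(built.days)
    assert run.ledger.vap_checked_days == n
    assert run.ledger.clabsi_checked_days == n


def test_trigger_ledger_counts_trigger_days(paper_runs):
    trig, _ = paper_runs
    assert trig.ledger.vap_checked_days == trig.screen.summary.vap_trigger_days
    assert trig.ledger.clabsi_checked_days == trig.screen.summary.clabsi_trigger_days
    assert trig.ledger.total_checked < trig.ledger.total_patient_days


def test_empty_cohort_runs_clean():
    run = run_surveillance(Cohort(stays=[], days=[]), "traditional")
    assert run.episodes == [] and run.ledger.total_checked == 0


def test_trigger_episodes_subset_of_traditional():
    sim = generate_cohort(small_config(seed=21))
    built, _ = build_cohort(sim.cohort)
    trig = run_surveillance(built, "trigger")
    gold = run_surveillance(built, "traditional")
    trig_keys = {(e.stay_id, e.infection_type) for e in trig.episodes}
    gold_keys = {(e.stay_id, e.infection_type) for e in gold.episodes}
    assert trig_keys <= gold_keys
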