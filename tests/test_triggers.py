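"""Daily trigger rule: examples, boolean-oracle equivalence, monotonicity."""

import numpy as np
import pytest

from haisurv.model import Route
from haisurv.triggers import (
    TriggerRuleConfig,
    eval_clabsi_trigger,
    eval_vap_trigger,
    evaluate_day,
    screen_cohort,
)

from conftest import make_day

RULES = TriggerRuleConfig()


# --- VAP examples -----------------------------------------------------------

def test_vap_fires_on_ventilation_antibiotic_and_fever():
    day = make_day(ventilated=True, antibiotics=[("ceftazidime", "iv")], temp_max=38.5)
    res = eval_vap_trigger(day, RULES)
    assert res.vap_trigger
    assert res.vap_factors.device == "mechanical_ventilation"
    assert res.vap_factors.antibiotics == ["ceftazidime"]
    assert "fever" in res.vap_factors.symptoms


def test_enteral_sdd_tobramycin_does_not_fire():
    """Prophylactic enteral aminoglycosides are filtered by the iv-only route rule."""
    day = make_day(ventilated=True, antibiotics=[("tobramycin", "enteral")], temp_max=39.0)
    assert not eval_vap_trigger(day, RULES).vap_trigger


def test_ventilation_is_mandatory_for_vap():
    day = make_day(
        ventilated=False,
        antibiotics=[("ceftazidime", "iv")],
        temp_max=39.5,
        wbc_max=20000,
        sputum=["purulent"],
    )
    assert not eval_vap_trigger(day, RULES).vap_trigger


def test_agent_synonym_and_case_are_normalized():
    day = make_day(
        ventilated=True,
        antibiotics=[("Sulfamethoxazole and Trimethoprim", "iv")],
        wbc_min=2000,
    )
    res = eval_vap_trigger(day, RULES)
    assert res.vap_trigger
    assert res.vap_factors.antibiotics == ["cotrimoxazole"]


def test_missing_observations_evaluate_as_not_met():
    day = make_day(
        ventilated=True,
        antibiotics=[("imipenem", "iv")],
        temp_max=None,
        wbc_min=None,
        wbc_max=None,
        sbp_min=None,
    )
    assert not evaluate_day(day, RULES).vap_trigger


# --- CLABSI examples --------------------------------------------------------

def test_clabsi_fires_on_line_vancomycin_hypotension():
    day = make_day(lines=["triple_lumen"], antibiotics=[("vancomycin", "iv")], sbp_min=85)
    res = eval_clabsi_trigger(day, RULES)
    assert res.clabsi_trigger
    assert res.clabsi_factors.device == "central_line:triple_lumen"
    assert res.clabsi_factors.symptoms == ["hypotension"]


def test_clabsi_needs_a_clinical_symptom():
    day = make_day(
        lines=["double_lumen"], antibiotics=[("vancomycin", "iv")], temp_max=37.8, sbp_min=110
    )
    assert not eval_clabsi_trigger(day, RULES).clabsi_trigger


def test_clabsi_device_factor_absent_after_line_removal():
    day = make_day(lines=[], antibiotics=[("vancomycin", "iv")], temp_max=39.2)
    assert not eval_clabsi_trigger(day, RULES).clabsi_trigger


# --- oracle equivalence -----------------------------------------------------

def oracle_flags(day, rules):
    """Independent brute-force restatement of the printed boolean rule."""
    iv_agents = {
        rules.normalize_agent(a.agent) for a in day.antibiotics if a.route in rules.qualifying_routes
    }
    fever = day.temp_max is not None and day.temp_max > rules.fever_threshold_c
    vap_symptom = (
        fever
        or (day.wbc_min is not None and day.wbc_min < rules.wbc_low)
        or (day.wbc_max is not None and day.wbc_max > rules.wbc_high)
        or any(s.lower() in rules.purulent_tokens for s in day.sputum_descriptors)
    )
    clabsi_symptom = fever or (day.sbp_min is not None and day.sbp_min < rules.sbp_threshold)
    has_line = any(
        n > 0 and lt in rules.clabsi_line_types for lt, n in day.central_lines.items()
    )
    vap = day.mech_ventilation and bool(iv_agents & rules.vap_antibiotics) and vap_symptom
    clabsi = has_line and bool(iv_agents & rules.clabsi_antibiotics) and clabsi_symptom
    return vap, clabsi


AGENT_POOL = [
    "ceftazidime", "vancomycin", "ceftriaxone", "tobramycin", "cefotaxime",
    "meropenem", "colistin", "fluconazole", "amoxicillin",
]
LINE_POOL = ["arterial", "dialysis", "single_lumen", "triple_lumen", "quadruple_lumen"]


def random_day(rng):
    n_abx = rng.integers(0, 4)
    return make_day(
        ventilated=bool(rng.random() < 0.5),
        lines=[LINE_POOL[rng.integers(0, len(LINE_POOL))] for _ in range(rng.integers(0, 3))],
        antibiotics=[
            (
                AGENT_POOL[rng.integers(0, len(AGENT_POOL))],
                ["iv", "enteral", "topical"][rng.integers(0, 3)],
            )
            for _ in range(n_abx)
        ],
        temp_max=None if rng.random() < 0.2 else float(rng.uniform(36.0, 40.5)),
        wbc_min=None if rng.random() < 0.2 else float(rng.uniform(1000, 9000)),
        wbc_max=None if rng.random() < 0.2 else float(rng.uniform(9000, 25000)),
        sputum=["purulent"] if rng.random() < 0.3 else ["white"],
        sbp_min=None if rng.random() < 0.2 else float(rng.uniform(60, 150)),
    )


def test_trigger_matches_boolean_oracle_on_random_days():
    rng = np.random.default_rng(42)
    for _ in range(400):
        day = random_day(rng)
        res = evaluate_day(day, RULES)
        assert (res.vap_trigger, res.clabsi_trigger) == oracle_flags(day, RULES)


def test_fired_triggers_always_record_complete_factors():
    rng = np.random.default_rng(7)
    for _ in range(300):
        res = evaluate_day(random_day(rng), RULES)
        if res.vap_trigger:
            assert res.vap_factors.complete
        if res.clabsi_trigger:
            assert res.clabsi_factors.complete


def test_determinism():
    rng = np.random.default_rng(3)
    days = [random_day(rng) for _ in range(50)]
    first = screen_cohort(days, RULES)
    second = screen_cohort(days, RULES)
    assert [r.model_dump() for r in first.results] == [r.model_dump() for r in second.results]


# --- monotonicity -----------------------------------------------------------

def _trigger_days(days, rules):
    s = screen_cohort(days, rules).summary
    return s.vap_trigger_days, s.clabsi_trigger_days


def test_relaxing_the_rule_never_decreases_trigger_days():
    rng = np.random.default_rng(11)
    days = [random_day(rng) for _ in range(300)]
    base_v, base_c = _trigger_days(days, RULES)

    wider_abx = RULES.model_copy(deep=True)
    wider_abx.vap_antibiotics.add("meropenem")
    wider_abx.clabsi_antibiotics.add("meropenem")
    v, c = _trigger_days(days, wider_abx)
    assert v >= base_v and c >= base_c

    extra_route = RULES.model_copy(deep=True)
    extra_route.qualifying_routes.add(Route.enteral)
    v, c = _trigger_days(days, extra_route)
    assert v >= base_v and c >= base_c

    lower_fever = RULES.model_copy(update={"fever_threshold_c": 37.5})
    v, c = _trigger_days(days, lower_fever)
    assert v >= base_v and c >= base_c


def test_no_antibiotics_means_no_trigger_days():
    rng = np.random.default_rng(13)
    days = [random_day(rng).model_copy(update={"antibiotics": []}) for _ in range(100)]
    assert _trigger_days(days, RULES) == (0, 0)
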