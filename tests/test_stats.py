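"""Device-day counting, incidence CIs, 2x2 performance, proportion CIs, workload."""

import math

import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from haisurv.model import InfectionEpisode, InfectionType
from haisurv.stats import (
    device_days,
    incidence_rate,
    performance_from_counts,
    performance_table,
    proportion_ci,
    workload,
)

from conftest import make_day, make_stay


# --- device days ------------------------------------------------------------

def vap_episode(stay_id, onset):
    return InfectionEpisode(
        stay_id=stay_id, infection_type=InfectionType.VAP, onset_day_index=onset
    )


def test_ventilation_days_truncate_at_onset_inclusive():
    days = [make_day(day_index=i, ventilated=True) for i in range(1, 11)]
    dd = device_days(days, [vap_episode("S1", 7)], InfectionType.VAP)
    assert dd.total_device_days == 7


def test_concurrent_lines_count_per_line():
    day = make_day(lines=["arterial", "triple_lumen"])
    assert device_days([day], [], InfectionType.CLABSI, mode="per_line").total_device_days == 2
    assert (
        device_days([day], [], InfectionType.CLABSI, mode="per_patient_day").total_device_days
        == 1
    )


def test_no_devices_counts_zero():
    days = [make_day(day_index=i) for i in range(1, 6)]
    assert device_days(days, [], InfectionType.VAP).total_device_days == 0
    assert device_days(days, [], InfectionType.CLABSI).total_device_days == 0


def test_truncation_never_increases_device_days():
    rng = np.random.default_rng(17)
    for _ in range(50):
        days = [
            make_day(day_index=i, ventilated=bool(rng.random() < 0.7))
            for i in range(1, int(rng.integers(3, 25)))
        ]
        episodes = [vap_episode("S1", int(rng.integers(1, 20)))]
        with_ep = device_days(days, episodes, InfectionType.VAP).total_device_days
        without = device_days(days, [], InfectionType.VAP).total_device_days
        assert with_ep <= without


# --- incidence rates --------------------------------------------------------

@pytest.mark.parametrize(
    "events,dd,expected",
    [
        (13, 3927, (3.3, 1.5, 5.1)),
        (24, 13887, (1.7, 1.0, 2.4)),
        (12, 3927, (3.1, 1.3, 4.8)),
        (22, 13887, (1.6, 0.9, 2.2)),
    ],
)
def test_rate_and_poisson_ci_reproduce_reference_values(events, dd, expected):
    assert incidence_rate(events, dd).rounded() == expected


def test_zero_events_collapse_interval():
    assert incidence_rate(0, 1000).rounded() == (0.0, 0.0, 0.0)


def test_undefined_rate_raises():
    with pytest.raises(ValueError):
        incidence_rate(5, 0)


def test_rate_scaling_property():
    base = incidence_rate(13, 3927)
    scaled = incidence_rate(13 * 4, 3927 * 4)
    assert math.isclose(scaled.rate_per_1000, base.rate_per_1000)
    base_width = base.ci95_high - base.ci95_low
    scaled_width = scaled.ci95_high - scaled.ci95_low
    assert math.isclose(scaled_width, base_width / 2.0, rel_tol=1e-9)


# --- proportion CIs ---------------------------------------------------------

def test_clopper_pearson_boundary_matches_closed_form():
    low, high = proportion_ci(409, 409, method="clopper_pearson")
    assert math.isclose(low, 100 * 0.025 ** (1 / 409), rel_tol=1e-9)
    assert high == 100.0
    assert abs(low - 99.10) < 0.02


def test_wilson_zero_successes_lower_bound():
    low, _ = proportion_ci(0, 10, method="wilson")
    assert low == 0.0


@pytest.mark.parametrize("method,sm_method", [("wilson", "wilson"), ("clopper_pearson", "beta")])
def test_empirical_coverage_near_nominal(method, sm_method):
    """Monte-Carlo coverage at n=50, p=0.9 is ~95% for both interval methods."""
    rng = np.random.default_rng(123)
    n, p, reps = 50, 0.9, 10_000
    counts = rng.binomial(n, p, size=reps)
    low, high = proportion_confint(counts, n, alpha=0.05, method=sm_method)
    coverage = np.mean((low <= p) & (p <= high))
    assert 0.92 <= coverage <= 0.99


def test_proportion_ci_input_validation():
    with pytest.raises(ValueError):
        proportion_ci(1, 0)
    with pytest.raises(ValueError):
        proportion_ci(5, 3)


# --- 2x2 performance --------------------------------------------------------

def test_identical_episode_sets_give_all_perfect_metrics():
    stays = [make_stay(f"S{i}") for i in range(30)]
    eps = [vap_episode("S3", 5), vap_episode("S9", 8)]
    table = performance_table(eps, eps, stays, InfectionType.VAP)
    assert (table.tp, table.fp, table.fn, table.tn) == (2, 0, 0, 28)
    for metric in (table.sensitivity, table.specificity, table.ppv, table.npv):
        assert metric.percent == 100.0


def test_two_by_two_conserves_eligible_count():
    stays = [make_stay(f"S{i}") for i in range(50)]
    trig = [vap_episode("S1", 4), vap_episode("S2", 6)]
    gold = trig + [vap_episode("S7", 9)]
    table = performance_table(trig, gold, stays, InfectionType.VAP)
    assert table.n_eligible == 50
    assert (table.tp, table.fn, table.fp, table.tn) == (2, 1, 0, 47)


def test_empty_eligible_set_raises():
    with pytest.raises(ValueError):
        performance_table([], [], [], InfectionType.VAP)


def test_counts_metrics_consistency():
    table = performance_from_counts(12, 1, 0, 409)
    assert math.isclose(table.sensitivity.percent, 100 * 12 / 13)
    assert math.isclose(table.npv.percent, 100 * 409 / 410)
    assert table.specificity.percent == 100.0 and table.ppv.percent == 100.0


# --- workload ---------------------------------------------------------------

def test_workload_arithmetic_matches_direct_oracle():
    rng = np.random.default_rng(31)
    for _ in range(200):
        pd = int(rng.integers(100, 20000))
        v = int(rng.integers(0, pd))
        c = int(rng.integers(0, pd))
        mpc = float(rng.uniform(0.5, 3.0))
        weeks = float(rng.uniform(10, 60))
        w = workload(pd, v, c, minutes_per_check=mpc, weeks=weeks)
        assert math.isclose(w.traditional_minutes, pd * 2 * mpc)
        assert math.isclose(w.trigger_minutes, (v + c) * mpc)
        assert math.isclose(w.reduction_fraction, 1 - (v + c) * mpc / (pd * 2 * mpc))
        assert math.isclose(w.trigger_minutes_per_week, (v + c) * mpc / weeks)


def test_all_days_triggered_means_no_saving():
    w = workload(100, 100, 100)
    assert w.reduction_fraction == 0.0
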