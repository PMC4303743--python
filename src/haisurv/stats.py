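"""Denominators, incidence rates, 2x2 screening performance, and workload.

Device-day denominators follow the registration rule: ventilation and
central-line days accrue until ICU discharge or death, but for a stay with
a confirmed infection of the corresponding type they accrue only up to and
including the onset day.  Central-line days are counted per concurrent
line by default (a day with an arterial and a triple-lumen catheter is two
line-days); a per-patient-day mode is available for NHSN-style
denominators.

Incidence rates per 1,000 device-days carry a normal-approximation Poisson
confidence interval: ``rate ± z * 1000 * sqrt(events) / device_days``.
Screening performance is a patient-level 2x2 of trigger-based versus
exhaustive (gold standard) surveillance, with binomial proportion CIs
(Wilson by default, Clopper-Pearson optionally).
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, Field
from statsmodels.stats.proportion import proportion_confint

from .model import DayRecord, InfectionEpisode, InfectionType, PatientStay


class DeviceDayCount(BaseModel):
    infection_type: InfectionType
    counting_mode: Literal["per_line", "per_patient_day"]
    total_device_days: int = Field(ge=0)
    per_stay: dict[str, int] = Field(default_factory=dict)


class IncidenceResult(BaseModel):
    events: int = Field(ge=0)
    device_days: int = Field(gt=0)
    rate_per_1000: float
    ci95_low: float
    ci95_high: float

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        """(rate, low, high) at reporting precision."""
        return (
            round(self.rate_per_1000, ndigits),
            round(self.ci95_low, ndigits),
            round(self.ci95_high, ndigits),
        )


class MetricWithCI(BaseModel):
    """A proportion expressed as a percentage with its 95% CI."""

    numerator: int
    denominator: int
    percent: float
    ci_low: float
    ci_high: float


class PerformanceTable(BaseModel):
    infection_type: InfectionType
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: MetricWithCI
    specificity: MetricWithCI
    ppv: MetricWithCI
    npv: MetricWithCI

    @property
    def n_eligible(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class WorkloadEstimate(BaseModel):
    patient_days: int
    vap_trigger_days: int
    clabsi_trigger_days: int
    minutes_per_check: float = 1.0
    weeks: float = 52.0
    traditional_minutes: float
    trigger_minutes: float
    traditional_hours: float
    trigger_hours: float
    traditional_hours_per_week: float
    trigger_hours_per_week: float
    trigger_minutes_per_week: float
    reduction_fraction: float
    vap_trigger_fraction: float
    clabsi_trigger_fraction: float


def device_days(
    days: Iterable[DayRecord],
    episodes: Iterable[InfectionEpisode],
    infection_type: InfectionType | str,
    mode: Literal["per_line", "per_patient_day"] = "per_line",
) -> DeviceDayCount:
    """Count device-days, truncating infected stays at the onset day.

    ``days`` should already be restricted to the stays under surveillance
    for ``infection_type`` (for VAP: the pneumonia-free subset).
    Ventilation is always counted per patient-day; central lines per
    concurrent line unless ``mode="per_patient_day"``.
    """
    infection_type = InfectionType(infection_type)
    onset: dict[str, int] = {
        ep.stay_id: ep.onset_day_index
        for ep in episodes
        if ep.infection_type == infection_type and not ep.needs_review
    }
    per_stay: dict[str, int] = {}
    for day in days:
        cutoff = onset.get(day.stay_id)
        if cutoff is not None and day.day_index > cutoff:
            continue
        if infection_type is InfectionType.VAP:
            contribution = 1 if day.mech_ventilation else 0
        else:
            n = day.n_lines
            contribution = n if mode == "per_line" else (1 if n > 0 else 0)
        if contribution:
            per_stay[day.stay_id] = per_stay.get(day.stay_id, 0) + contribution
    return DeviceDayCount(
        infection_type=infection_type,
        counting_mode=mode,
        total_device_days=sum(per_stay.values()),
        per_stay=per_stay,
    )


def incidence_rate(events: int, device_days: int, z: float = 1.96) -> IncidenceResult:
    """Incidence per 1,000 device-days with a normal-approximation Poisson CI.

    ``rate = 1000 * events / device_days``; the CI half-width is
    ``z * 1000 * sqrt(events) / device_days``, floored at zero.
    """
    if device_days <= 0:
        raise ValueError("device_days must be positive for a defined rate")
    if events < 0:
        raise ValueError("events must be non-negative")
    rate = 1000.0 * events / device_days
    half = z * 1000.0 * math.sqrt(events) / device_days
    return IncidenceResult(
        events=events,
        device_days=device_days,
        rate_per_1000=rate,
        ci95_low=max(0.0, rate - half),
        ci95_high=rate + half,
    )


def proportion_ci(
    successes: int,
    n: int,
    method: Literal["wilson", "clopper_pearson"] = "wilson",
    alpha: float = 0.05,
) -> tuple[float, float]:
    """95% (by default) binomial CI for a proportion, as percentages."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    sm_method = {"wilson": "wilson", "clopper_pearson": "beta"}[method]
    low, high = proportion_confint(successes, n, alpha=alpha, method=sm_method)
    return 100.0 * float(low), 100.0 * float(high)


def _metric(
    numerator: int,
    denominator: int,
    method: Literal["wilson", "clopper_pearson"],
) -> MetricWithCI:
    if denominator == 0:
        return MetricWithCI(
            numerator=0, denominator=0, percent=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"),
        )
    low, high = proportion_ci(numerator, denominator, method=method)
    return MetricWithCI(
        numerator=numerator,
        denominator=denominator,
        percent=100.0 * numerator / denominator,
        ci_low=low,
        ci_high=high,
    )


def performance_from_counts(
    tp: int,
    fn: int,
    fp: int,
    tn: int,
    infection_type: InfectionType | str = InfectionType.VAP,
    ci_method: Literal["wilson", "clopper_pearson"] = "wilson",
) -> PerformanceTable:
    """Screening performance metrics from a patient-level 2x2 table."""
    return PerformanceTable(
        infection_type=InfectionType(infection_type),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=_metric(tp, tp + fn, ci_method),
        specificity=_metric(tn, tn + fp, ci_method),
        ppv=_metric(tp, tp + fp, ci_method),
        npv=_metric(tn, tn + fn, ci_method),
    )


def performance_table(
    trigger_episodes: Iterable[InfectionEpisode],
    gold_episodes: Iterable[InfectionEpisode],
    eligible_stays: Iterable[PatientStay],
    infection_type: InfectionType | str,
    ci_method: Literal["wilson", "clopper_pearson"] = "wilson",
) -> PerformanceTable:
    """Patient-level 2x2 of trigger-based vs exhaustive surveillance.

    tp = stays positive in both; fn = gold-standard only; fp = trigger
    only; tn = neither — restricted to the stays eligible for the type.
    """
    infection_type = InfectionType(infection_type)
    eligible_ids = {s.stay_id for s in eligible_stays}
    if not eligible_ids:
        raise ValueError("eligible stay set is empty")
    trig = {
        e.stay_id
        for e in trigger_episodes
        if e.infection_type == infection_type and e.stay_id in eligible_ids and not e.needs_review
    }
    gold = {
        e.stay_id
        for e in gold_episodes
        if e.infection_type == infection_type and e.stay_id in eligible_ids and not e.needs_review
    }
    tp = len(trig & gold)
    fn = len(gold - trig)
    fp = len(trig - gold)
    tn = len(eligible_ids) - tp - fn - fp
    return performance_from_counts(tp, fn, fp, tn, infection_type, ci_method)


def workload(
    patient_days: int,
    vap_trigger_days: int,
    clabsi_trigger_days: int,
    minutes_per_check: float = 1.0,
    weeks: float = 52.0,
) -> WorkloadEstimate:
    """Manual screening workload of both modes and the trigger's saving.

    Exhaustive screening checks every patient-day once per infection type
    (two checks per day); trigger-based screening checks only fired
    trigger days.  One check takes ``minutes_per_check`` (about 1 min).
    """
    traditional_minutes = patient_days * 2 * minutes_per_check
    trigger_minutes = (vap_trigger_days + clabsi_trigger_days) * minutes_per_check
    reduction = 1.0 - trigger_minutes / traditional_minutes if traditional_minutes else 0.0
    return WorkloadEstimate(
        patient_days=patient_days,
        vap_trigger_days=vap_trigger_days,
        clabsi_trigger_days=clabsi_trigger_days,
        minutes_per_check=minutes_per_check,
        weeks=weeks,
        traditional_minutes=traditional_minutes,
        trigger_minutes=trigger_minutes,
        traditional_hours=traditional_minutes / 60.0,
        trigger_hours=trigger_minutes / 60.0,
        traditional_hours_per_week=traditional_minutes / 60.0 / weeks,
        trigger_hours_per_week=trigger_minutes / 60.0 / weeks,
        trigger_minutes_per_week=trigger_minutes / weeks,
        reduction_fraction=reduction,
        vap_trigger_fraction=vap_trigger_days / patient_days if patient_days else 0.0,
        clabsi_trigger_fraction=clabsi_trigger_days / patient_days if patient_days else 0.0,
    )
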