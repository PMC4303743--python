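"""Assembly of the full surveillance report.

Combines both surveillance runs over one cohort into device-day
denominators, incidence rates per 1,000 device-days with CIs, the
patient-level 2x2 screening-performance block, and the workload estimate.
Rendered as JSON (machine-readable, field-for-field identical to the text
rendering) or as a plain-text block laid out like a classic screening
2x2 table.
"""

from __future__ import annotations

import json
from typing import Literal, Optional

from pydantic import BaseModel

from .cohort import vap_eligible
from .confirm import SurveillanceRun
from .model import Cohort, DetectionMode, InfectionType
from .stats import (
    IncidenceResult,
    PerformanceTable,
    WorkloadEstimate,
    device_days,
    incidence_rate,
    performance_table,
    workload,
)


class TypeReport(BaseModel):
    infection_type: InfectionType
    n_eligible: int
    device_days_traditional: int
    device_days_trigger: int
    incidence_traditional: Optional[IncidenceResult] = None
    incidence_trigger: Optional[IncidenceResult] = None
    performance: Optional[PerformanceTable] = None


class SurveillanceReport(BaseModel):
    n_included_stays: int
    n_patient_days: int
    vap: TypeReport
    clabsi: TypeReport
    workload: Optional[WorkloadEstimate] = None
    warnings: list[str] = []

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=indent)

    def to_text(self) -> str:
        lines: list[str] = []
        lines.append(f"Included stays: {self.n_included_stays}; patient-days: {self.n_patient_days}")
        for tr in (self.vap, self.clabsi):
            name = tr.infection_type.value
            lines.append("")
            lines.append(f"== {name} (n eligible = {tr.n_eligible}) ==")
            for label, inc in (
                ("traditional", tr.incidence_traditional),
                ("trigger", tr.incidence_trigger),
            ):
                if inc is not None:
                    r, lo, hi = inc.rounded()
                    lines.append(
                        f"incidence ({label}): {r}/1,000 device days "
                        f"(95% CI {lo} to {hi}); {inc.events} events / {inc.device_days} days"
                    )
            p = tr.performance
            if p is not None:
                lines.append(f"                 gold {name:<8} gold no-{name}")
                lines.append(f"trigger {name:<8} {p.tp:>8} {p.fp:>12}")
                lines.append(f"trigger no-{name:<5} {p.fn:>8} {p.tn:>12}")
                for metric_name, m in (
                    ("sensitivity", p.sensitivity),
                    ("specificity", p.specificity),
                    ("PPV", p.ppv),
                    ("NPV", p.npv),
                ):
                    lines.append(
                        f"{metric_name:>12}: {m.percent:5.1f}%  "
                        f"({m.ci_low:.2f} to {m.ci_high:.2f})  [{m.numerator}/{m.denominator}]"
                    )
        w = self.workload
        if w is not None:
            lines.append("")
            lines.append("== workload ==")
            lines.append(
                f"trigger days: VAP {w.vap_trigger_days} "
                f"({100 * w.vap_trigger_fraction:.1f}%), "
                f"CLABSI {w.clabsi_trigger_days} ({100 * w.clabsi_trigger_fraction:.1f}%) "
                f"of {w.patient_days} patient-days"
            )
            lines.append(
                f"traditional: {w.traditional_hours:.0f} h total, "
                f"{w.traditional_hours_per_week:.1f} h/week"
            )
            lines.append(
                f"trigger-based: {w.trigger_hours:.0f} h total, "
                f"{w.trigger_minutes_per_week:.0f} min/week"
            )
            lines.append(f"workload reduction: {100 * w.reduction_fraction:.0f}%")
        for warning in self.warnings:
            lines.append(f"WARNING: {warning}")
        return "\n".join(lines)


def build_report(
    cohort: Cohort,
    trigger_run: Optional[SurveillanceRun] = None,
    traditional_run: Optional[SurveillanceRun] = None,
    minutes_per_check: float = 1.0,
    weeks: float = 52.0,
    line_mode: Literal["per_line", "per_patient_day"] = "per_line",
    ci_method: Literal["wilson", "clopper_pearson"] = "wilson",
) -> SurveillanceReport:
    """Build the report from one or both surveillance runs on a built cohort.

    The trigger-vs-gold performance block requires both runs; with a single
    run the comparison is omitted with a warning.
    """
    warnings: list[str] = []
    eligible_vap = vap_eligible(cohort.stays)
    eligible_ids = {s.stay_id for s in eligible_vap}
    vap_days = [d for d in cohort.days if d.stay_id in eligible_ids]

    def type_report(infection_type: InfectionType) -> TypeReport:
        days = vap_days if infection_type is InfectionType.VAP else cohort.days
        eligible = eligible_vap if infection_type is InfectionType.VAP else cohort.stays
        tr = TypeReport(
            infection_type=infection_type,
            n_eligible=len(eligible),
            device_days_traditional=0,
            device_days_trigger=0,
        )
        for label, run in (("traditional", traditional_run), ("trigger", trigger_run)):
            if run is None:
                continue
            dd = device_days(days, run.episodes, infection_type, mode=line_mode)
            events = sum(
                e.infection_type == infection_type and e.stay_id in {s.stay_id for s in eligible}
                for e in run.episodes
            )
            setattr(tr, f"device_days_{label}", dd.total_device_days)
            if dd.total_device_days > 0:
                setattr(tr, f"incidence_{label}", incidence_rate(events, dd.total_device_days))
            else:
                warnings.append(f"{infection_type.value}: no device days in {label} mode")
        if trigger_run is not None and traditional_run is not None:
            tr.performance = performance_table(
                trigger_run.episodes,
                traditional_run.episodes,
                eligible,
                infection_type,
                ci_method=ci_method,
            )
        return tr

    if trigger_run is None or traditional_run is None:
        warnings.append("single surveillance mode supplied; trigger-vs-gold comparison omitted")

    wl: Optional[WorkloadEstimate] = None
    if trigger_run is not None and trigger_run.mode is DetectionMode.trigger:
        wl = workload(
            patient_days=len(cohort.days),
            vap_trigger_days=trigger_run.ledger.vap_checked_days,
            clabsi_trigger_days=trigger_run.ledger.clabsi_checked_days,
            minutes_per_check=minutes_per_check,
            weeks=weeks,
        )

    return SurveillanceReport(
        n_included_stays=len(cohort.stays),
        n_patient_days=len(cohort.days),
        vap=type_report(InfectionType.VAP),
        clabsi=type_report(InfectionType.CLABSI),
        workload=wl,
        warnings=warnings,
    )
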