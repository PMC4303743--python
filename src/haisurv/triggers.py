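"""The automated part of the surveillance: daily VAP and CLABSI triggers.

A trigger fires on a patient-day when three factor groups co-occur on that
day: the device (mechanical ventilation for VAP, any qualifying central
line for CLABSI), the start or continuation of an infection-specific
antibiotic via a qualifying route, and at least one clinical symptom
(fever > 38 C; for VAP additionally WBC < 4,000 or > 12,000 /mm3 or
purulent sputum; for CLABSI hypotension with systolic pressure < 90 mmHg).

Only systemic (iv) administrations count by default: in an ICU using
selective digestive decontamination every long-stay patient receives
enteral tobramycin and colistin prophylactically, and tobramycin is on the
VAP treatment list — without the route filter the trigger would fire on
essentially every febrile ventilated patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .model import DayRecord, LineType, Route, TriggerFactors, TriggerResult

DEFAULT_VAP_ANTIBIOTICS = frozenset(
    {
        "ceftriaxone",
        "levofloxacin",
        "ciprofloxacin",
        "cotrimoxazole",
        "ceftazidime",
        "tobramycin",
        "gentamicin",
        "imipenem",
        "fluconazole",
        "voriconazole",
    }
)

DEFAULT_CLABSI_ANTIBIOTICS = frozenset(
    {
        "vancomycin",
        "flucloxacillin",
        "ceftriaxone",
        "ciprofloxacin",
        "imipenem",
        "fluconazole",
        "voriconazole",
    }
)

#: agent-name synonyms applied (case-insensitively) before list membership
DEFAULT_SYNONYMS: dict[str, str] = {
    "sulfamethoxazole and trimethoprim": "cotrimoxazole",
    "sulfamethoxazole/trimethoprim": "cotrimoxazole",
    "trimethoprim-sulfamethoxazole": "cotrimoxazole",
    "trimethoprim/sulfamethoxazole": "cotrimoxazole",
}


class TriggerRuleConfig(BaseModel):
    """Thresholds and agent lists of the daily trigger rule.

    All comparisons are strict, as defined: fever is ``temp_max > 38.0``,
    leukopenia ``wbc_min < 4000``, leukocytosis ``wbc_max > 12000``,
    hypotension ``sbp_min < 90``.
    """

    vap_antibiotics: set[str] = Field(default_factory=lambda: set(DEFAULT_VAP_ANTIBIOTICS))
    clabsi_antibiotics: set[str] = Field(default_factory=lambda: set(DEFAULT_CLABSI_ANTIBIOTICS))
    qualifying_routes: set[Route] = Field(default_factory=lambda: {Route.iv})
    fever_threshold_c: float = Field(default=38.0, gt=0)
    wbc_low: float = Field(default=4000.0, gt=0)
    wbc_high: float = Field(default=12000.0, gt=0)
    sbp_threshold: float = Field(default=90.0, gt=0)
    purulent_tokens: set[str] = Field(default_factory=lambda: {"purulent"})
    clabsi_line_types: set[LineType] = Field(default_factory=lambda: set(LineType))
    synonyms: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_SYNONYMS))

    @field_validator("vap_antibiotics", "clabsi_antibiotics")
    @classmethod
    def _non_empty(cls, v: set[str]) -> set[str]:
        if not v:
            raise ValueError("antibiotic set must be non-empty")
        return {a.lower() for a in v}

    def normalize_agent(self, name: str) -> str:
        key = name.strip().lower()
        return self.synonyms.get(key, key)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TriggerRuleConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        # sets serialise as lists; keep them sorted for stable files
        for key in ("vap_antibiotics", "clabsi_antibiotics", "qualifying_routes",
                    "purulent_tokens", "clabsi_line_types"):
            data[key] = sorted(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _qualifying_agents(
    day: DayRecord, agent_set: set[str], rules: TriggerRuleConfig
) -> list[str]:
    out: list[str] = []
    for adm in day.antibiotics:
        if adm.route in rules.qualifying_routes:
            agent = rules.normalize_agent(adm.agent)
            if agent in agent_set and agent not in out:
                out.append(agent)
    return out


def _vap_symptoms(day: DayRecord, rules: TriggerRuleConfig) -> list[str]:
    symptoms: list[str] = []
    if day.temp_max is not None and day.temp_max > rules.fever_threshold_c:
        symptoms.append("fever")
    if day.wbc_min is not None and day.wbc_min < rules.wbc_low:
        symptoms.append("wbc_low")
    if day.wbc_max is not None and day.wbc_max > rules.wbc_high:
        symptoms.append("wbc_high")
    if any(tok.strip().lower() in rules.purulent_tokens for tok in day.sputum_descriptors):
        symptoms.append("purulent_sputum")
    return symptoms


def _clabsi_symptoms(day: DayRecord, rules: TriggerRuleConfig) -> list[str]:
    symptoms: list[str] = []
    if day.temp_max is not None and day.temp_max > rules.fever_threshold_c:
        symptoms.append("fever")
    if day.sbp_min is not None and day.sbp_min < rules.sbp_threshold:
        symptoms.append("hypotension")
    return symptoms


def eval_vap_trigger(day: DayRecord, rules: TriggerRuleConfig | None = None) -> TriggerResult:
    """Evaluate the VAP trigger for one patient-day.

    Fires iff the patient is mechanically ventilated AND receives at least
    one VAP-specific antibiotic via a qualifying route AND shows at least
    one qualifying clinical symptom, all on the same day.  Missing
    observations count as criterion-not-met.
    """
    rules = rules or TriggerRuleConfig()
    agents = _qualifying_agents(day, rules.vap_antibiotics, rules)
    symptoms = _vap_symptoms(day, rules)
    fired = day.mech_ventilation and bool(agents) and bool(symptoms)
    factors = TriggerFactors(
        device="mechanical_ventilation" if (fired and day.mech_ventilation) else None,
        antibiotics=agents if fired else [],
        symptoms=symptoms if fired else [],
    )
    return TriggerResult(
        stay_id=day.stay_id, day_index=day.day_index, vap_trigger=fired, vap_factors=factors
    )


def eval_clabsi_trigger(day: DayRecord, rules: TriggerRuleConfig | None = None) -> TriggerResult:
    """Evaluate the CLABSI trigger for one patient-day.

    Fires iff at least one qualifying central line is present AND at least
    one CLABSI-specific antibiotic is given via a qualifying route AND the
    day shows fever or hypotension.
    """
    rules = rules or TriggerRuleConfig()
    lines = sorted(
        lt.value for lt, n in day.central_lines.items() if n > 0 and lt in rules.clabsi_line_types
    )
    agents = _qualifying_agents(day, rules.clabsi_antibiotics, rules)
    symptoms = _clabsi_symptoms(day, rules)
    fired = bool(lines) and bool(agents) and bool(symptoms)
    factors = TriggerFactors(
        device=("central_line:" + "+".join(lines)) if fired else None,
        antibiotics=agents if fired else [],
        symptoms=symptoms if fired else [],
    )
    return TriggerResult(
        stay_id=day.stay_id, day_index=day.day_index, clabsi_trigger=fired, clabsi_factors=factors
    )


def evaluate_day(day: DayRecord, rules: TriggerRuleConfig | None = None) -> TriggerResult:
    """Joint VAP + CLABSI trigger evaluation of one patient-day."""
    rules = rules or TriggerRuleConfig()
    vap = eval_vap_trigger(day, rules)
    clabsi = eval_clabsi_trigger(day, rules)
    return TriggerResult(
        stay_id=day.stay_id,
        day_index=day.day_index,
        vap_trigger=vap.vap_trigger,
        clabsi_trigger=clabsi.clabsi_trigger,
        vap_factors=vap.vap_factors,
        clabsi_factors=clabsi.clabsi_factors,
    )


@dataclass
class TriggerSummary:
    total_days: int
    vap_trigger_days: int
    clabsi_trigger_days: int
    any_trigger_days: int

    @property
    def vap_fraction(self) -> float:
        return self.vap_trigger_days / self.total_days if self.total_days else 0.0

    @property
    def clabsi_fraction(self) -> float:
        return self.clabsi_trigger_days / self.total_days if self.total_days else 0.0


@dataclass
class ScreenResult:
    results: list[TriggerResult]
    summary: TriggerSummary

    def trigger_days_by_stay(self, infection: str) -> dict[str, list[int]]:
        """Map stay_id -> sorted day indices with a fired trigger of one type."""
        attr = "vap_trigger" if infection.upper() == "VAP" else "clabsi_trigger"
        out: dict[str, list[int]] = {}
        for res in self.results:
            if getattr(res, attr):
                out.setdefault(res.stay_id, []).append(res.day_index)
        for v in out.values():
            v.sort()
        return out


def screen_cohort(
    days: list[DayRecord], rules: TriggerRuleConfig | None = None
) -> ScreenResult:
    """Run the daily trigger over every patient-day of a cohort."""
    rules = rules or TriggerRuleConfig()
    results = [evaluate_day(d, rules) for d in days]
    summary = TriggerSummary(
        total_days=len(results),
        vap_trigger_days=sum(r.vap_trigger for r in results),
        clabsi_trigger_days=sum(r.clabsi_trigger for r in results),
        any_trigger_days=sum(r.vap_trigger or r.clabsi_trigger for r in results),
    )
    return ScreenResult(results=results, summary=summary)
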