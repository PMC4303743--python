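"""Core domain types for ICU infection surveillance.

One :class:`DayRecord` aggregates a single patient-day — the granularity at
which the daily trigger rule operates.  Device status, antibiotic
administrations and the daily extremes of the clinical observations
(maximum temperature, WBC minimum/maximum, systolic-pressure minimum) live
on the day record; radiology findings and culture results are separate
date-keyed streams because they arrive asynchronously from other hospital
systems.

Record types validate field types and ranges on construction; *cross-field*
clinical invariants (discharge before admission, WBC min above max, growth
reported for a sterile culture, dangling stay references, ...) are reported
by :func:`validate_cohort` so that malformed input can be surfaced as a
structured report instead of a parse crash.
"""

from __future__ import annotations

import datetime as dt
import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, Field


class LineType(str, enum.Enum):
    """Central-line categories registered by the ICU record system."""

    arterial = "arterial"
    dialysis = "dialysis"
    single_lumen = "single_lumen"
    double_lumen = "double_lumen"
    triple_lumen = "triple_lumen"
    quadruple_lumen = "quadruple_lumen"


class Route(str, enum.Enum):
    iv = "iv"
    enteral = "enteral"
    topical = "topical"


class Specimen(str, enum.Enum):
    blood_from_line = "blood_from_line"
    peripheral_blood = "peripheral_blood"
    catheter_tip = "catheter_tip"
    sputum = "sputum"
    bal = "bal"


class GrowthQuantity(str, enum.Enum):
    """Reported culture growth.

    Catheter tips are subcultured from a 100 ul suspension and growth is
    reported either as a colony count relative to the 10-colony positivity
    rule or on the qualitative +/++/+++ scale.  ``QUANTITY_RANK`` orders the
    two scales jointly: a "+" plate implies at least the 10-colony threshold.
    """

    none = "none"
    lt10_colonies = "lt10_colonies"
    ge10_colonies = "ge10_colonies"
    plus = "plus"
    plusplus = "plusplus"
    plusplusplus = "plusplusplus"


QUANTITY_RANK: dict[GrowthQuantity, int] = {
    GrowthQuantity.none: 0,
    GrowthQuantity.lt10_colonies: 1,
    GrowthQuantity.ge10_colonies: 2,
    GrowthQuantity.plus: 2,
    GrowthQuantity.plusplus: 3,
    GrowthQuantity.plusplusplus: 4,
}


class PathogenClass(str, enum.Enum):
    pathogen = "pathogen"
    contaminant = "contaminant"
    undetermined = "undetermined"


class InfectionType(str, enum.Enum):
    VAP = "VAP"
    CLABSI = "CLABSI"


class DetectionMode(str, enum.Enum):
    trigger = "trigger"
    traditional = "traditional"


NO_GROWTH = "no growth"


class PatientStay(BaseModel):
    """One ICU admission episode."""

    patient_id: str
    stay_id: str
    admission_ts: dt.datetime
    discharge_ts: Optional[dt.datetime] = None
    pneumonia_on_admission: bool = False
    icu_death: bool = False
    #: moment life-prolonging treatment was stopped (censoring point)
    withdrawal_ts: Optional[dt.datetime] = None

    @property
    def admission_date(self) -> dt.date:
        return self.admission_ts.date()

    @property
    def los_hours(self) -> Optional[float]:
        if self.discharge_ts is None:
            return None
        return (self.discharge_ts - self.admission_ts).total_seconds() / 3600.0

    def day_index_of(self, date: dt.date) -> int:
        """1-based day-of-stay index of a calendar date."""
        return (date - self.admission_date).days + 1

    def date_of(self, day_index: int) -> dt.date:
        return self.admission_date + dt.timedelta(days=day_index - 1)


class AntibioticAdministration(BaseModel):
    agent: str
    route: Route

    def __hash__(self) -> int:  # used in set-based oracle tests
        return hash((self.agent, self.route))


class DayRecord(BaseModel):
    """One patient-day of device, antibiotic and observation data.

    The device and antibiotic fields (the automated trigger factors) are
    mandatory; the clinical observations may be absent and then simply do
    not satisfy any threshold criterion.
    """

    stay_id: str
    day_index: int = Field(ge=1)
    calendar_date: dt.date
    mech_ventilation: bool
    central_lines: dict[LineType, int] = Field(default_factory=dict)
    antibiotics: list[AntibioticAdministration] = Field(default_factory=list)
    temp_max: Optional[float] = None
    wbc_min: Optional[float] = None
    wbc_max: Optional[float] = None
    sputum_descriptors: list[str] = Field(default_factory=list)
    sbp_min: Optional[float] = None

    @property
    def n_lines(self) -> int:
        return sum(self.central_lines.values())


class RadiologyFinding(BaseModel):
    stay_id: str
    calendar_date: dt.date
    infiltrate_or_consolidation: bool
    verified_by_radiologist: bool = True


class CultureResult(BaseModel):
    stay_id: str
    calendar_date: dt.date
    specimen: Specimen
    line_type: Optional[LineType] = None
    organism: str
    quantity: GrowthQuantity = GrowthQuantity.none
    pathogen_class: PathogenClass = PathogenClass.undetermined


class TriggerFactors(BaseModel):
    """Which sub-criteria satisfied a fired trigger."""

    device: Optional[str] = None
    antibiotics: list[str] = Field(default_factory=list)
    symptoms: list[str] = Field(default_factory=list)

    @property
    def complete(self) -> bool:
        return bool(self.device) and bool(self.antibiotics) and bool(self.symptoms)


class TriggerResult(BaseModel):
    stay_id: str
    day_index: int
    vap_trigger: bool = False
    clabsi_trigger: bool = False
    vap_factors: TriggerFactors = Field(default_factory=TriggerFactors)
    clabsi_factors: TriggerFactors = Field(default_factory=TriggerFactors)


class Adjudication(BaseModel):
    """Consensus decision of the two-person manual review."""

    stay_id: str
    infection_type: InfectionType
    decision: str = Field(pattern="^(confirm|reject)$")
    rationale: str = ""


class InfectionEpisode(BaseModel):
    stay_id: str
    infection_type: InfectionType
    onset_day_index: int = Field(ge=1)
    detected_by: str = Field(default="traditional", pattern="^(trigger|traditional|both)$")
    confirmation_basis: dict = Field(default_factory=dict)
    #: set when the only microbiological evidence is of undetermined
    #: pathogen class and no adjudication resolves it
    needs_review: bool = False


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str
    stay_id: Optional[str] = None


@dataclass
class ValidationReport:
    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, severity: str, message: str, stay_id: Optional[str] = None) -> None:
        issue = ValidationIssue(severity, message, stay_id)
        (self.errors if severity == "error" else self.warnings).append(issue)


def validate_cohort(
    stays: list[PatientStay],
    days: list[DayRecord],
    radiology: list[RadiologyFinding] = (),
    cultures: list[CultureResult] = (),
) -> ValidationReport:
    """Report invariant violations across a cohort without mutating it.

    Errors: duplicate stay ids, discharge before admission, withdrawal
    outside the stay, dangling stay references, duplicate day indices,
    WBC minimum above maximum, growth quantity on a sterile culture.
    Warnings: non-physiologic temperature (outside 25-45 C), duplicate
    radiology findings for one stay-date (later entries override).
    """
    report = ValidationReport()

    seen_ids: set[str] = set()
    for stay in stays:
        if stay.stay_id in seen_ids:
            report.add("error", f"duplicate stay_id {stay.stay_id!r}", stay.stay_id)
        seen_ids.add(stay.stay_id)
        if stay.discharge_ts is not None and stay.discharge_ts < stay.admission_ts:
            report.add("error", "discharge before admission", stay.stay_id)
        if stay.withdrawal_ts is not None:
            if stay.withdrawal_ts < stay.admission_ts or (
                stay.discharge_ts is not None and stay.withdrawal_ts > stay.discharge_ts
            ):
                report.add("error", "withdrawal timestamp outside stay", stay.stay_id)

    day_keys: Counter = Counter()
    for day in days:
        if day.stay_id not in seen_ids:
            report.add("error", f"day record references unknown stay {day.stay_id!r}", day.stay_id)
        day_keys[(day.stay_id, day.day_index)] += 1
        if day.wbc_min is not None and day.wbc_max is not None and day.wbc_min > day.wbc_max:
            report.add("error", f"wbc_min > wbc_max on day {day.day_index}", day.stay_id)
        if day.temp_max is not None and not (25.0 <= day.temp_max <= 45.0):
            report.add(
                "warning",
                f"temp_max {day.temp_max} outside physiologic range on day {day.day_index}",
                day.stay_id,
            )
    for (stay_id, day_index), n in day_keys.items():
        if n > 1:
            report.add("error", f"duplicate day_index {day_index}", stay_id)

    rad_keys: Counter = Counter()
    for finding in radiology:
        if finding.stay_id not in seen_ids:
            report.add("error", f"radiology references unknown stay {finding.stay_id!r}", finding.stay_id)
        rad_keys[(finding.stay_id, finding.calendar_date)] += 1
    for (stay_id, date), n in rad_keys.items():
        if n > 1:
            report.add("warning", f"multiple radiology findings on {date}; later entries override", stay_id)

    for culture in cultures:
        if culture.stay_id not in seen_ids:
            report.add("error", f"culture references unknown stay {culture.stay_id!r}", culture.stay_id)
        if culture.organism == NO_GROWTH and culture.quantity != GrowthQuantity.none:
            report.add("error", "growth quantity reported for a sterile culture", culture.stay_id)

    return report


@dataclass
class Cohort:
    """Bundle of the per-stream record lists making up one surveillance cohort."""

    stays: list[PatientStay]
    days: list[DayRecord]
    radiology: list[RadiologyFinding] = field(default_factory=list)
    cultures: list[CultureResult] = field(default_factory=list)
    adjudications: list[Adjudication] = field(default_factory=list)

    def days_by_stay(self) -> dict[str, list[DayRecord]]:
        out: dict[str, list[DayRecord]] = {s.stay_id: [] for s in self.stays}
        for day in self.days:
            out.setdefault(day.stay_id, []).append(day)
        for records in out.values():
            records.sort(key=lambda d: d.day_index)
        return out

    @property
    def n_patient_days(self) -> int:
        return len(self.days)
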