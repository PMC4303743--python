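"""Inclusion, exclusion, readmission merging and censoring rules.

The surveillance population is built in three steps: consecutive ICU stays
of the same patient separated by no more than 24 h are merged into one
admission (later readmissions count as new patients); stays shorter than
48 h are excluded; and each included stay's day records are censored at
eight weeks of stay and at the date life-prolonging treatment was
withdrawn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from pydantic import BaseModel, Field

from .model import Cohort, DayRecord, PatientStay


class CohortConfig(BaseModel):
    min_los_hours: float = Field(default=48.0, gt=0)
    max_surveillance_days: int = Field(default=56, gt=0)
    readmission_merge_hours: float = Field(default=24.0, gt=0)
    #: merge readmissions before applying the 48-h minimum (the order is not
    #: dictated by the surveillance protocol; merging first is the default)
    merge_before_inclusion: bool = True


@dataclass
class ExclusionEntry:
    stay_id: str
    rule: str  # "short_stay" | "open_stay" (flag only)
    detail: str
    excluded: bool = True


class OverlappingStaysError(ValueError):
    pass


def merge_readmissions(
    stays: list[PatientStay], config: CohortConfig | None = None
) -> list[PatientStay]:
    """Merge same-patient stays whose gap is within the readmission window.

    Consecutive stays of one patient with ``gap <= readmission_merge_hours``
    become a single admission spanning from the first admission to the last
    discharge; the pneumonia-on-admission flag is taken from the first stay
    (it describes the state at the original admission).  Overlapping stays
    are a data error.
    """
    config = config or CohortConfig()
    by_patient: dict[str, list[PatientStay]] = {}
    for stay in stays:
        by_patient.setdefault(stay.patient_id, []).append(stay)

    merged: list[PatientStay] = []
    for patient_id, patient_stays in by_patient.items():
        patient_stays = sorted(patient_stays, key=lambda s: s.admission_ts)
        current: Optional[PatientStay] = None
        for stay in patient_stays:
            if current is None:
                current = stay
                continue
            if current.discharge_ts is None:
                raise OverlappingStaysError(
                    f"patient {patient_id!r}: stay {current.stay_id!r} has no "
                    f"discharge but is followed by {stay.stay_id!r}"
                )
            gap_h = (stay.admission_ts - current.discharge_ts).total_seconds() / 3600.0
            if gap_h < 0:
                raise OverlappingStaysError(
                    f"patient {patient_id!r}: stays {current.stay_id!r} and "
                    f"{stay.stay_id!r} overlap"
                )
            if gap_h <= config.readmission_merge_hours:
                current = current.model_copy(
                    update={
                        "discharge_ts": stay.discharge_ts,
                        "icu_death": stay.icu_death,
                        "withdrawal_ts": stay.withdrawal_ts or current.withdrawal_ts,
                    }
                )
            else:
                merged.append(current)
                current = stay
        if current is not None:
            merged.append(current)
    merged.sort(key=lambda s: (s.admission_ts, s.stay_id))
    return merged


def apply_inclusion(
    stays: list[PatientStay],
    days: Iterable[DayRecord] = (),
    config: CohortConfig | None = None,
) -> tuple[list[PatientStay], list[ExclusionEntry]]:
    """Keep stays meeting the minimum length of stay.

    A stay of exactly the minimum (48 h) is included.  Stays without a
    discharge timestamp cannot be assessed and are kept but flagged
    ``open_stay`` in the log.
    """
    config = config or CohortConfig()
    included: list[PatientStay] = []
    log: list[ExclusionEntry] = []
    for stay in stays:
        los = stay.los_hours
        if los is None:
            included.append(stay)
            log.append(
                ExclusionEntry(stay.stay_id, "open_stay", "no discharge timestamp", excluded=False)
            )
        elif los < config.min_los_hours:
            log.append(
                ExclusionEntry(
                    stay.stay_id,
                    "short_stay",
                    f"LOS {los:.1f} h < {config.min_los_hours:g} h",
                )
            )
        else:
            included.append(stay)
    return included, log


def censor_days(
    stay: PatientStay,
    days: Iterable[DayRecord],
    config: CohortConfig | None = None,
) -> list[DayRecord]:
    """Apply the 8-week cap and withdrawal-of-treatment censoring.

    Day records beyond ``max_surveillance_days`` are dropped, as are all
    days on or after the withdrawal date — from the moment life-prolonging
    treatment stops, no further diagnostics or targeted antibiotics occur,
    so the withdrawal day itself is censored.
    """
    config = config or CohortConfig()
    withdrawal_date = stay.withdrawal_ts.date() if stay.withdrawal_ts is not None else None
    kept = [
        d
        for d in days
        if d.day_index <= config.max_surveillance_days
        and (withdrawal_date is None or d.calendar_date < withdrawal_date)
    ]
    kept.sort(key=lambda d: d.day_index)
    return kept


def vap_eligible(stays: list[PatientStay]) -> list[PatientStay]:
    """Stays under VAP surveillance: those without pneumonia on admission.

    CLABSI surveillance uses the full included set.
    """
    return [s for s in stays if not s.pneumonia_on_admission]


def build_cohort(
    raw: Cohort, config: CohortConfig | None = None
) -> tuple[Cohort, list[ExclusionEntry]]:
    """Full cohort construction: merge readmissions, include, censor.

    Returns the surveillance-ready cohort (ancillary streams restricted to
    included stays) and the exclusion log.  Idempotent: applying it to its
    own output changes nothing.
    """
    config = config or CohortConfig()
    stays = raw.stays
    if config.merge_before_inclusion:
        stays = merge_readmissions(stays, config)
        included, log = apply_inclusion(stays, raw.days, config)
    else:
        included, log = apply_inclusion(stays, raw.days, config)
        included = merge_readmissions(included, config)

    included_ids = {s.stay_id for s in included}
    days_by_stay: dict[str, list[DayRecord]] = {}
    for day in raw.days:
        days_by_stay.setdefault(day.stay_id, []).append(day)

    censored_days: list[DayRecord] = []
    for stay in included:
        censored_days.extend(censor_days(stay, days_by_stay.get(stay.stay_id, []), config))

    cohort = Cohort(
        stays=included,
        days=censored_days,
        radiology=[r for r in raw.radiology if r.stay_id in included_ids],
        cultures=[c for c in raw.cultures if c.stay_id in included_ids],
        adjudications=[a for a in raw.adjudications if a.stay_id in included_ids],
    )
    return cohort, log
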