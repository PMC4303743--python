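"""The active part of the surveillance: case confirmation.

Candidate patient-days (trigger days in trigger mode; every patient-day in
traditional, exhaustive mode) are checked against coded radiology and
microbiology:

* VAP is confirmed when lung infiltrates/consolidations appear on at least
  two *consecutive* days and that run intersects a window around a
  candidate day.  A single-day density never confirms (transient
  hydrostatic edema).
* CLABSI is confirmed when, within a window around a candidate day, a
  blood culture grows an organism adjudicated as a pathogen, or a catheter
  tip grows at least ten colonies of a pathogen.

Subjective judgement (pathogen vs contaminant, inconclusive chest films)
enters only through coded inputs and an explicit two-reviewer
:class:`~haisurv.model.Adjudication` record: ``reject`` vetoes a
rule-confirmed case, ``confirm`` resolves an otherwise inconclusive one.
The reported onset day is the earliest candidate day satisfying the rule,
and only the first episode of each infection type per admission counts.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from pydantic import BaseModel, Field

from .cohort import vap_eligible
from .model import (
    QUANTITY_RANK,
    Adjudication,
    Cohort,
    CultureResult,
    DetectionMode,
    GrowthQuantity,
    InfectionEpisode,
    InfectionType,
    NO_GROWTH,
    PathogenClass,
    PatientStay,
    RadiologyFinding,
    Specimen,
)
from .triggers import ScreenResult, TriggerRuleConfig, screen_cohort

logger = logging.getLogger(__name__)

#: radiology/culture dates more than this many days after admission (or any
#: date before admission) are treated as erroneous and ignored
_MAX_PLAUSIBLE_DAY = 60


class ConfirmationConfig(BaseModel):
    radiology_min_consecutive_days: int = Field(default=2, ge=1)
    #: half-width (days) of the search window around a candidate day
    radiology_window_days: int = Field(default=2, ge=0)
    culture_window_days: int = Field(default=2, ge=0)
    tip_min_quantity: GrowthQuantity = GrowthQuantity.ge10_colonies


def _dedupe_findings(findings: Iterable[RadiologyFinding]) -> dict[dt.date, RadiologyFinding]:
    """One finding per date; later entries override earlier ones."""
    out: dict[dt.date, RadiologyFinding] = {}
    for f in findings:
        if f.calendar_date in out:
            logger.warning(
                "stay %s: overriding radiology finding on %s", f.stay_id, f.calendar_date
            )
        out[f.calendar_date] = f
    return out


def infiltrate_runs(
    stay: PatientStay, findings: Iterable[RadiologyFinding]
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive days with infiltrates, as day-index spans.

    Findings dated before admission or implausibly late are ignored with a
    warning.  Post-discharge findings within the plausible horizon still
    count: chest films are read and reports filed after the ICU episode.
    """
    by_date = _dedupe_findings(findings)
    positive_days: set[int] = set()
    for date, finding in by_date.items():
        idx = stay.day_index_of(date)
        if idx < 1 or idx > _MAX_PLAUSIBLE_DAY:
            logger.warning(
                "stay %s: radiology finding on %s outside the stay; ignored",
                stay.stay_id,
                date,
            )
            continue
        if finding.infiltrate_or_consolidation:
            positive_days.add(idx)

    runs: list[tuple[int, int]] = []
    for day in sorted(positive_days):
        if runs and day == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], day)
        else:
            runs.append((day, day))
    return runs


def _find_adjudication(
    adjudications: Iterable[Adjudication], stay_id: str, infection_type: InfectionType
) -> Optional[Adjudication]:
    for adj in adjudications:
        if adj.stay_id == stay_id and adj.infection_type == infection_type:
            return adj
    return None


def confirm_vap(
    stay: PatientStay,
    candidate_days: Iterable[int],
    radiology: Iterable[RadiologyFinding],
    cultures: Iterable[CultureResult] = (),
    adjudications: Iterable[Adjudication] = (),
    config: ConfirmationConfig | None = None,
) -> Optional[InfectionEpisode]:
    """Confirm a VAP episode from coded radiology around candidate days.

    Confirmed iff a run of at least ``radiology_min_consecutive_days``
    consecutive infiltrate days intersects ``candidate ± radiology_window``
    for some candidate day; the onset day is the earliest such candidate.
    A ``reject`` adjudication vetoes; a ``confirm`` adjudication resolves an
    inconclusive case (no qualifying run) at the earliest candidate day.
    """
    config = config or ConfirmationConfig()
    candidates = sorted(set(candidate_days))
    if not candidates:
        return None

    adj = _find_adjudication(adjudications, stay.stay_id, InfectionType.VAP)
    if adj is not None and adj.decision == "reject":
        return None

    runs = [
        r
        for r in infiltrate_runs(stay, radiology)
        if r[1] - r[0] + 1 >= config.radiology_min_consecutive_days
    ]
    w = config.radiology_window_days
    for day in candidates:
        for start, end in runs:
            if start <= day + w and end >= day - w:
                return InfectionEpisode(
                    stay_id=stay.stay_id,
                    infection_type=InfectionType.VAP,
                    onset_day_index=day,
                    confirmation_basis={
                        "radiology_run_days": [start, end],
                        "adjudication": adj.decision if adj else None,
                    },
                )
    if adj is not None and adj.decision == "confirm":
        return InfectionEpisode(
            stay_id=stay.stay_id,
            infection_type=InfectionType.VAP,
            onset_day_index=candidates[0],
            confirmation_basis={"adjudication": "confirm", "rationale": adj.rationale},
        )
    return None


def _qualifying_culture(culture: CultureResult, config: ConfirmationConfig) -> bool:
    if culture.organism == NO_GROWTH:
        return False
    if culture.specimen in (Specimen.blood_from_line, Specimen.peripheral_blood):
        return culture.pathogen_class == PathogenClass.pathogen
    if culture.specimen == Specimen.catheter_tip:
        return (
            culture.pathogen_class == PathogenClass.pathogen
            and QUANTITY_RANK[culture.quantity] >= QUANTITY_RANK[config.tip_min_quantity]
        )
    return False


def _undetermined_culture(culture: CultureResult, config: ConfirmationConfig) -> bool:
    if culture.organism == NO_GROWTH or culture.pathogen_class != PathogenClass.undetermined:
        return False
    if culture.specimen in (Specimen.blood_from_line, Specimen.peripheral_blood):
        return True
    if culture.specimen == Specimen.catheter_tip:
        return QUANTITY_RANK[culture.quantity] >= QUANTITY_RANK[config.tip_min_quantity]
    return False


def confirm_clabsi(
    stay: PatientStay,
    candidate_days: Iterable[int],
    cultures: Iterable[CultureResult],
    adjudications: Iterable[Adjudication] = (),
    config: ConfirmationConfig | None = None,
) -> Optional[InfectionEpisode]:
    """Confirm a CLABSI episode from culture results around candidate days.

    Evidence is a blood culture growing a pathogen, or a catheter-tip
    culture at/above the ten-colony threshold growing a pathogen, dated
    within ``candidate ± culture_window``.  Cultures whose pathogen-vs-
    contaminant status is undetermined confirm nothing by themselves: if
    they are the only evidence the episode is flagged ``needs_review``
    (excluded from automated counts) unless an adjudication resolves it.
    """
    config = config or ConfirmationConfig()
    candidates = sorted(set(candidate_days))
    if not candidates:
        return None

    adj = _find_adjudication(adjudications, stay.stay_id, InfectionType.CLABSI)
    if adj is not None and adj.decision == "reject":
        return None

    dated: list[tuple[int, CultureResult]] = []
    for culture in cultures:
        idx = stay.day_index_of(culture.calendar_date)
        if idx < 1 - config.culture_window_days or idx > _MAX_PLAUSIBLE_DAY:
            logger.warning(
                "stay %s: culture on %s outside the stay; ignored",
                stay.stay_id,
                culture.calendar_date,
            )
            continue
        dated.append((idx, culture))

    w = config.culture_window_days
    first_undetermined: Optional[tuple[int, CultureResult]] = None
    for day in candidates:
        for idx, culture in dated:
            if abs(idx - day) > w:
                continue
            if _qualifying_culture(culture, config):
                return InfectionEpisode(
                    stay_id=stay.stay_id,
                    infection_type=InfectionType.CLABSI,
                    onset_day_index=day,
                    confirmation_basis={
                        "culture": {
                            "specimen": culture.specimen.value,
                            "organism": culture.organism,
                            "quantity": culture.quantity.value,
                            "day_index": idx,
                        },
                        "adjudication": adj.decision if adj else None,
                    },
                )
            if first_undetermined is None and _undetermined_culture(culture, config):
                first_undetermined = (day, culture)

    if adj is not None and adj.decision == "confirm":
        onset = first_undetermined[0] if first_undetermined else candidates[0]
        return InfectionEpisode(
            stay_id=stay.stay_id,
            infection_type=InfectionType.CLABSI,
            onset_day_index=onset,
            confirmation_basis={"adjudication": "confirm", "rationale": adj.rationale},
        )
    if first_undetermined is not None:
        day, culture = first_undetermined
        return InfectionEpisode(
            stay_id=stay.stay_id,
            infection_type=InfectionType.CLABSI,
            onset_day_index=day,
            needs_review=True,
            confirmation_basis={
                "culture": {
                    "specimen": culture.specimen.value,
                    "organism": culture.organism,
                    "pathogen_class": "undetermined",
                }
            },
        )
    return None


def assign_episodes(confirmed: Iterable[InfectionEpisode]) -> list[InfectionEpisode]:
    """Keep only the first episode per (stay, infection type).

    Order-invariant: ties on onset day are broken deterministically.
    """
    best: dict[tuple[str, InfectionType], InfectionEpisode] = {}
    for ep in confirmed:
        key = (ep.stay_id, ep.infection_type)
        if key not in best or ep.onset_day_index < best[key].onset_day_index:
            best[key] = ep
    return sorted(best.values(), key=lambda e: (e.stay_id, e.infection_type.value))


@dataclass
class CheckedDayLedger:
    """Patient-days whose radiology/cultures were manually checked, per type."""

    vap_checked_days: int = 0
    clabsi_checked_days: int = 0
    total_patient_days: int = 0

    @property
    def total_checked(self) -> int:
        return self.vap_checked_days + self.clabsi_checked_days


@dataclass
class SurveillanceRun:
    mode: DetectionMode
    episodes: list[InfectionEpisode]
    needs_review: list[InfectionEpisode]
    ledger: CheckedDayLedger
    screen: Optional[ScreenResult] = None
    extra: dict = field(default_factory=dict)


def run_surveillance(
    cohort: Cohort,
    mode: DetectionMode | str = DetectionMode.trigger,
    rules: TriggerRuleConfig | None = None,
    config: ConfirmationConfig | None = None,
) -> SurveillanceRun:
    """Run one surveillance mode end to end on a built, censored cohort.

    In trigger mode the candidate days are the fired trigger days; in
    traditional (exhaustive) mode every patient-day is a candidate.  The
    checked-day ledger counts candidate days per infection type over all
    included stays — the workload driver.  VAP confirmation is applied only
    to VAP-eligible stays (no pneumonia on admission); CLABSI confirmation
    to all included stays.
    """
    mode = DetectionMode(mode)
    rules = rules or TriggerRuleConfig()
    config = config or ConfirmationConfig()

    days_by_stay = cohort.days_by_stay()
    rad_by_stay: dict[str, list[RadiologyFinding]] = {}
    for f in cohort.radiology:
        rad_by_stay.setdefault(f.stay_id, []).append(f)
    cult_by_stay: dict[str, list[CultureResult]] = {}
    for c in cohort.cultures:
        cult_by_stay.setdefault(c.stay_id, []).append(c)

    screen: Optional[ScreenResult] = None
    if mode is DetectionMode.trigger:
        screen = screen_cohort(cohort.days, rules)
        vap_candidates = screen.trigger_days_by_stay("VAP")
        clabsi_candidates = screen.trigger_days_by_stay("CLABSI")
        ledger = CheckedDayLedger(
            vap_checked_days=screen.summary.vap_trigger_days,
            clabsi_checked_days=screen.summary.clabsi_trigger_days,
            total_patient_days=screen.summary.total_days,
        )
    else:
        all_days = {sid: [d.day_index for d in recs] for sid, recs in days_by_stay.items()}
        vap_candidates = all_days
        clabsi_candidates = all_days
        n = len(cohort.days)
        ledger = CheckedDayLedger(
            vap_checked_days=n, clabsi_checked_days=n, total_patient_days=n
        )

    confirmed: list[InfectionEpisode] = []
    review: list[InfectionEpisode] = []

    eligible = vap_eligible(cohort.stays)
    for stay in eligible:
        candidates = vap_candidates.get(stay.stay_id, [])
        if not candidates:
            continue
        ep = confirm_vap(
            stay,
            candidates,
            rad_by_stay.get(stay.stay_id, []),
            cult_by_stay.get(stay.stay_id, []),
            cohort.adjudications,
            config,
        )
        if ep is not None:
            ep = ep.model_copy(update={"detected_by": mode.value})
            (review if ep.needs_review else confirmed).append(ep)

    for stay in cohort.stays:
        candidates = clabsi_candidates.get(stay.stay_id, [])
        if not candidates:
            continue
        ep = confirm_clabsi(
            stay,
            candidates,
            cult_by_stay.get(stay.stay_id, []),
            cohort.adjudications,
            config,
        )
        if ep is not None:
            ep = ep.model_copy(update={"detected_by": mode.value})
            (review if ep.needs_review else confirmed).append(ep)

    episodes = assign_episodes(confirmed)
    logger.info(
        "%s mode: %d episodes (%d VAP, %d CLABSI), %d flagged for review, "
        "%d+%d checked days",
        mode.value,
        len(episodes),
        sum(e.infection_type is InfectionType.VAP for e in episodes),
        sum(e.infection_type is InfectionType.CLABSI for e in episodes),
        len(review),
        ledger.vap_checked_days,
        ledger.clabsi_checked_days,
    )
    return SurveillanceRun(
        mode=mode, episodes=episodes, needs_review=review, ledger=ledger, screen=screen
    )
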