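"""Synthetic mixed-ICU cohort generator with ground-truth infection labels.

The generator emulates the kind of population a 24-bed mixed ICU produces
over a year of surveillance: ~553 included stays with a truncated
log-normal length of stay (mean 11.7 d, SD 11.6 d, range 2-56 d), 25%
pneumonia on admission, roughly three quarters of patient-days ventilated,
about two concurrent central lines per patient-day, and low per-device-day
infection hazards (VAP 3.3/1,000 ventilation days, CLABSI 1.7/1,000 line
days).  Universal digestive-decontamination prophylaxis (enteral
tobramycin/colistin/amphotericin B, iv cefotaxime on days 1-3) is emitted
on every stay so that the trigger's iv-route filter is exercised.

Every planted infection carries a ground-truth label including its
*failure mode*: an antibiotic-start delay of >= 1 day (VAP treatment
started after the clinical signs have resolved), or management by central
line removal without antibiotics (CLABSI) — the two mechanisms by which a
trigger-based screen can miss a case.  By construction a planted episode
with neither failure mode is always detectable in trigger mode, and the
exhaustive (traditional) mode always detects every planted episode, so
that screening performance on synthetic data is fully accounted for.

Background "trigger noise" — antibiotics given for unrelated indications
coinciding with incidental fever, single-day transient densities on chest
film, contaminant blood cultures — is generated independently of
infection status and calibrated so that roughly 5.3% of patient-days fire
the VAP trigger and 14.5% the CLABSI trigger.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats as sps

from .model import (
    AntibioticAdministration,
    Cohort,
    CultureResult,
    DayRecord,
    GrowthQuantity,
    InfectionType,
    LineType,
    PathogenClass,
    PatientStay,
    RadiologyFinding,
    Route,
    Specimen,
)

_BASE_DATE = dt.date(2009, 10, 1)

_LINE_TYPE_WEIGHTS: dict[LineType, float] = {
    LineType.arterial: 0.35,
    LineType.dialysis: 0.05,
    LineType.single_lumen: 0.10,
    LineType.double_lumen: 0.15,
    LineType.triple_lumen: 0.25,
    LineType.quadruple_lumen: 0.10,
}

_CLABSI_ORGANISMS = [
    "Staphylococcus aureus",
    "Enterococcus faecalis",
    "Escherichia coli",
    "Candida albicans",
]


class BackgroundNoise(BaseModel):
    """Per-day probabilities of non-infection coincidences.

    ``vap_coincidence_p``: a VAP-list antibiotic given iv for another
    indication together with a qualifying symptom; fires the VAP trigger
    on ventilated days.  ``clabsi_coincidence_p``: likewise with a
    CLABSI-list agent plus fever/hypotension.  Defaults are calibrated
    from the closed-form day-fraction expectations so that trigger-day
    fractions approach 5.3% (VAP) and 14.5% (CLABSI).
    """

    vap_coincidence_p: float = Field(default=0.062, ge=0, le=1)
    clabsi_coincidence_p: float = Field(default=0.153, ge=0, le=1)
    lone_infiltrate_p: float = Field(default=0.01, ge=0, le=1)
    contaminant_culture_p: float = Field(default=0.005, ge=0, le=1)


class SimulationConfig(BaseModel):
    n_patients: int = Field(default=553, gt=0)
    #: additional stays shorter than 48 h, to exercise the inclusion filter
    n_short_stays: int = Field(default=0, ge=0)
    los_mean_days: float = Field(default=11.7, gt=0)
    los_sd_days: float = Field(default=11.6, gt=0)
    los_min_days: float = Field(default=2.0, gt=0)
    los_max_days: float = Field(default=56.0, gt=0)
    pneumonia_on_admission_p: float = Field(default=0.25, ge=0, le=1)
    ventilation_day_fraction: float = Field(default=0.77, ge=0, le=1)
    mean_lines_per_day: float = Field(default=2.044, ge=0)
    max_lines_per_day: int = Field(default=4, ge=1)
    vap_hazard_per_vent_day: float = Field(default=3.3e-3, ge=0, le=1)
    clabsi_hazard_per_line_day: float = Field(default=1.7e-3, ge=0, le=1)
    #: probability mass on the delay (days) between infection onset and the
    #: start of targeted iv antibiotics
    antibiotic_delay_days: dict[int, float] = Field(
        default_factory=lambda: {0: 0.87, 1: 0.03, 2: 0.02, 3: 0.08}
    )
    #: days the qualifying clinical signs of an untreated VAP persist
    vap_symptom_duration_days: int = Field(default=3, ge=1)
    treatment_duration_days: int = Field(default=5, ge=1)
    infiltrate_run_days: int = Field(default=3, ge=2)
    #: probability a CLABSI is managed by line removal without antibiotics
    clabsi_line_removal_only_p: float = Field(default=0.083, ge=0, le=1)
    background_trigger_noise: BackgroundNoise = Field(default_factory=BackgroundNoise)
    #: probability a non-onset infected day shows its qualifying symptoms
    symptom_sensitivity: float = Field(default=0.95, ge=0, le=1)
    withdrawal_p: float = Field(default=0.0036, ge=0, le=1)
    icu_mortality_p: float = Field(default=0.23, ge=0, le=1)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _feasible(self) -> "SimulationConfig":
        if self.los_min_days >= self.los_max_days:
            raise ValueError("los_min_days must be below los_max_days")
        total = sum(self.antibiotic_delay_days.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("antibiotic delay probabilities must sum to 1")
        if any(k < 0 or p < 0 for k, p in self.antibiotic_delay_days.items()):
            raise ValueError("antibiotic delay support/mass must be non-negative")
        if self.ventilation_day_fraction == 0 and self.vap_hazard_per_vent_day > 0:
            raise ValueError("VAP hazard is positive but no day is ventilated")
        if self.mean_lines_per_day == 0 and self.clabsi_hazard_per_line_day > 0:
            raise ValueError("CLABSI hazard is positive but no central lines are placed")
        return self


@dataclass
class GroundTruthEpisode:
    stay_id: str
    infection_type: InfectionType
    onset_day_index: int
    antibiotic_delay_days: int = 0
    line_removal_only: bool = False

    @property
    def failure_mode(self) -> str:
        if self.line_removal_only:
            return "line_removal_only"
        if self.antibiotic_delay_days >= 1:
            return "antibiotic_delay"
        return "none"


@dataclass
class SimulatedCohort:
    """Raw (pre-inclusion) cohort plus the planted episode labels."""

    cohort: Cohort
    ground_truth: list[GroundTruthEpisode] = field(default_factory=list)
    config: Optional[SimulationConfig] = None

    def ground_truth_by_stay(self, infection_type: InfectionType) -> dict[str, GroundTruthEpisode]:
        return {
            gt.stay_id: gt for gt in self.ground_truth if gt.infection_type == infection_type
        }


# ---------------------------------------------------------------------------
# closed-form expectations

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def truncated_lognormal_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Mean of a log-normal with raw mean/sd, truncated to [lo, hi]."""
    mu, sigma = _lognormal_params(mean, sd)
    a = (math.log(lo) - mu) / sigma
    b = (math.log(hi) - mu) / sigma
    denom = sps.norm.cdf(b) - sps.norm.cdf(a)
    num = sps.norm.cdf(b - sigma) - sps.norm.cdf(a - sigma)
    return math.exp(mu + sigma**2 / 2.0) * num / denom


def truncated_poisson_lambda(target_mean: float, max_count: int) -> float:
    """Poisson rate whose truncation to {0..max_count} has the target mean."""
    if target_mean <= 0:
        return 0.0
    if target_mean >= max_count:
        raise ValueError("target mean must be below the truncation bound")

    def trunc_mean(lam: float) -> float:
        ks = np.arange(max_count + 1)
        pmf = sps.poisson.pmf(ks, lam)
        return float((ks * pmf).sum() / pmf.sum())

    lo, hi = target_mean, 10.0 * max_count
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if trunc_mean(mid) < target_mean:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def expected_mean_los(config: SimulationConfig) -> float:
    return truncated_lognormal_mean(
        config.los_mean_days, config.los_sd_days, config.los_min_days, config.los_max_days
    )


def expected_patient_days(config: SimulationConfig) -> float:
    """Expected day records: a stay of length L spans E[L] + 1 calendar dates."""
    return config.n_patients * (expected_mean_los(config) + 1.0)


def expected_ventilation_days(config: SimulationConfig) -> float:
    """Expected ventilation days of the VAP-surveillance (pneumonia-free) subset."""
    return (
        expected_patient_days(config)
        * (1.0 - config.pneumonia_on_admission_p)
        * config.ventilation_day_fraction
    )


def expected_line_days(config: SimulationConfig) -> float:
    return expected_patient_days(config) * config.mean_lines_per_day


def expected_vap_count(config: SimulationConfig) -> float:
    return expected_ventilation_days(config) * config.vap_hazard_per_vent_day


def expected_clabsi_count(config: SimulationConfig) -> float:
    return expected_line_days(config) * config.clabsi_hazard_per_line_day


def paperlike_config(seed: int = 0) -> SimulationConfig:
    """The shipped study-scale configuration.

    553 includable stays plus 47 sub-48-h stays; marginals chosen so the
    expected totals are ~6,800 patient-days, ~3,900 eligible ventilation
    days, ~13,900 central-line days, ~13 VAP and ~24 CLABSI.
    """
    return SimulationConfig(n_short_stays=47, seed=seed)


# ---------------------------------------------------------------------------
# generation

def _sample_truncated_lognormal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    mu, sigma = _lognormal_params(mean, sd)
    for _ in range(10_000):
        x = math.exp(rng.normal(mu, sigma))
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated log-normal rejection sampling failed")


def _sample_delay(rng: np.random.Generator, pmf: dict[int, float]) -> int:
    ks = sorted(pmf)
    ps = np.array([pmf[k] for k in ks], dtype=float)
    return int(rng.choice(ks, p=ps / ps.sum()))


def _sample_line_types(rng: np.random.Generator, k: int) -> dict[LineType, int]:
    if k == 0:
        return {}
    types = list(_LINE_TYPE_WEIGHTS)
    weights = np.array(list(_LINE_TYPE_WEIGHTS.values()))
    draws = rng.choice(len(types), size=k, p=weights / weights.sum())
    out: dict[LineType, int] = {}
    for i in draws:
        out[types[int(i)]] = out.get(types[int(i)], 0) + 1
    return out


class _StayPlan:
    """Mutable per-stay scratch state assembled before emitting records."""

    def __init__(self, n_days: int):
        self.fever: set[int] = set()
        self.wbc_high: set[int] = set()
        self.wbc_low: set[int] = set()
        self.purulent: set[int] = set()
        self.hypotension: set[int] = set()
        self.antibiotics: dict[int, list[tuple[str, Route]]] = {d: [] for d in range(1, n_days + 1)}
        self.n_days = n_days

    def add_abx(self, day: int, agent: str, route: Route) -> None:
        if 1 <= day <= self.n_days:
            self.antibiotics[day].append((agent, route))


def generate_cohort(
    config: SimulationConfig | None = None, seed: int | None = None
) -> SimulatedCohort:
    """Generate a raw cohort with planted, labelled infection episodes.

    Reproducible: identical config and seed give identical output.  The
    returned cohort is *raw* — run it through
    :func:`haisurv.cohort.build_cohort` before surveillance.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    lam = (
        truncated_poisson_lambda(config.mean_lines_per_day, config.max_lines_per_day)
        if config.mean_lines_per_day > 0
        else 0.0
    )

    stays: list[PatientStay] = []
    days: list[DayRecord] = []
    radiology: list[RadiologyFinding] = []
    cultures: list[CultureResult] = []
    ground_truth: list[GroundTruthEpisode] = []

    noise = config.background_trigger_noise
    sympdur = config.vap_symptom_duration_days
    treatdur = config.treatment_duration_days

    for i in range(config.n_patients):
        stay_id = f"S{i:04d}"
        patient_id = f"P{i:04d}"
        admission = dt.datetime.combine(
            _BASE_DATE + dt.timedelta(days=int(rng.integers(0, 365))), dt.time()
        ) + dt.timedelta(minutes=int(rng.integers(0, 24 * 60)))
        los = _sample_truncated_lognormal(
            rng, config.los_mean_days, config.los_sd_days, config.los_min_days, config.los_max_days
        )
        discharge = admission + dt.timedelta(days=los)
        n_days = (discharge.date() - admission.date()).days + 1
        pneumonia = bool(rng.random() < config.pneumonia_on_admission_p)
        death = bool(rng.random() < config.icu_mortality_p)

        withdrawal_ts: Optional[dt.datetime] = None
        withdrawal_day: Optional[int] = None
        if n_days >= 6 and rng.random() < config.withdrawal_p:
            withdrawal_day = int(rng.integers(4, n_days))
            withdrawal_ts = dt.datetime.combine(
                admission.date() + dt.timedelta(days=withdrawal_day - 1), dt.time(12, 0)
            )
            death = True

        # planting horizon: keep planted episodes clear of the 8-week cap and
        # any withdrawal censor so that confirmability never depends on which
        # mode looks (see failure-mode accounting)
        horizon = min(n_days, 54)
        if withdrawal_day is not None:
            horizon = min(horizon, withdrawal_day - 3)

        n_vent = int(rng.binomial(n_days, config.ventilation_day_fraction))
        line_counts = [0] * (n_days + 1)  # 1-based
        if lam > 0:
            for d in range(1, n_days + 1):
                while True:
                    k = int(rng.poisson(lam))
                    if k <= config.max_lines_per_day:
                        break
                line_counts[d] = k

        plan = _StayPlan(n_days)
        # universal SDD prophylaxis: enteral topical agents every day,
        # systemic cefotaxime the first three days — none fire the trigger
        for d in range(1, n_days + 1):
            plan.add_abx(d, "tobramycin", Route.enteral)
            plan.add_abx(d, "colistin", Route.enteral)
            plan.add_abx(d, "amphotericin B", Route.enteral)
        for d in range(1, min(3, n_days) + 1):
            plan.add_abx(d, "cefotaxime", Route.iv)

        # --- VAP -----------------------------------------------------------
        vap_onset: Optional[int] = None
        if not pneumonia and config.vap_hazard_per_vent_day > 0:
            for d in range(1, min(n_vent, horizon) + 1):
                if rng.random() < config.vap_hazard_per_vent_day:
                    vap_onset = d
                    break
        if vap_onset is not None:
            delay = _sample_delay(rng, config.antibiotic_delay_days)
            for offset in range(sympdur):
                d = vap_onset + offset
                if d > n_days:
                    break
                if offset == 0 or rng.random() < config.symptom_sensitivity:
                    plan.fever.add(d)
                if rng.random() < 0.7:
                    plan.purulent.add(d)
                if rng.random() < 0.5:
                    plan.wbc_high.add(d)
            for d in range(vap_onset + delay, min(vap_onset + delay + treatdur, n_days + 1)):
                plan.add_abx(d, "ceftazidime", Route.iv)
            for offset in range(config.infiltrate_run_days):
                radiology.append(
                    RadiologyFinding(
                        stay_id=stay_id,
                        calendar_date=admission.date() + dt.timedelta(days=vap_onset - 1 + offset),
                        infiltrate_or_consolidation=True,
                    )
                )
            cultures.append(
                CultureResult(
                    stay_id=stay_id,
                    calendar_date=admission.date() + dt.timedelta(days=vap_onset - 1),
                    specimen=Specimen.sputum,
                    organism="Pseudomonas aeruginosa",
                    quantity=GrowthQuantity.plusplus,
                    pathogen_class=PathogenClass.pathogen,
                )
            )
            ground_truth.append(
                GroundTruthEpisode(
                    stay_id=stay_id,
                    infection_type=InfectionType.VAP,
                    onset_day_index=vap_onset,
                    antibiotic_delay_days=delay,
                )
            )

        # --- CLABSI --------------------------------------------------------
        clabsi_onset: Optional[int] = None
        if config.clabsi_hazard_per_line_day > 0:
            for d in range(1, horizon + 1):
                k = line_counts[d]
                if k and rng.random() < 1.0 - (1.0 - config.clabsi_hazard_per_line_day) ** k:
                    clabsi_onset = d
                    break
        if clabsi_onset is not None:
            organism = _CLABSI_ORGANISMS[int(rng.integers(0, len(_CLABSI_ORGANISMS)))]
            removal_only = bool(rng.random() < config.clabsi_line_removal_only_p)
            if removal_only:
                plan.fever.add(clabsi_onset)
                if clabsi_onset + 1 <= n_days and rng.random() < config.symptom_sensitivity:
                    plan.fever.add(clabsi_onset + 1)
                cultures.append(
                    CultureResult(
                        stay_id=stay_id,
                        calendar_date=admission.date() + dt.timedelta(days=clabsi_onset - 1),
                        specimen=Specimen.catheter_tip,
                        line_type=LineType.triple_lumen,
                        organism=organism,
                        quantity=GrowthQuantity.ge10_colonies,
                        pathogen_class=PathogenClass.pathogen,
                    )
                )
                delay = 0
            else:
                delay = _sample_delay(rng, config.antibiotic_delay_days)
                # fever persists until treatment starts; blood cultures are
                # drawn from the lines on every febrile day (culture policy)
                for d in range(clabsi_onset, min(clabsi_onset + delay + 2, n_days + 1)):
                    plan.fever.add(d)
                if rng.random() < 0.4:
                    plan.hypotension.add(clabsi_onset)
                for d in range(clabsi_onset, min(clabsi_onset + delay, n_days) + 1):
                    cultures.append(
                        CultureResult(
                            stay_id=stay_id,
                            calendar_date=admission.date() + dt.timedelta(days=d - 1),
                            specimen=Specimen.blood_from_line,
                            line_type=LineType.triple_lumen,
                            organism=organism,
                            quantity=GrowthQuantity.plus,
                            pathogen_class=PathogenClass.pathogen,
                        )
                    )
                for d in range(
                    clabsi_onset + delay, min(clabsi_onset + delay + treatdur, n_days + 1)
                ):
                    plan.add_abx(d, "vancomycin", Route.iv)
                # the infected line stays in until treatment is under way
                for d in range(clabsi_onset, min(clabsi_onset + delay + 2, n_days + 1)):
                    line_counts[d] = max(line_counts[d], 1)
            ground_truth.append(
                GroundTruthEpisode(
                    stay_id=stay_id,
                    infection_type=InfectionType.CLABSI,
                    onset_day_index=clabsi_onset,
                    antibiotic_delay_days=delay,
                    line_removal_only=removal_only,
                )
            )

        # --- background noise ---------------------------------------------
        has_vap_gt = vap_onset is not None
        lone_infiltrate_days: set[int] = set()
        for d in range(1, n_days + 1):
            if rng.random() < noise.vap_coincidence_p:
                plan.add_abx(d, "ceftazidime", Route.iv)
                u = rng.random()
                if u < 0.5:
                    plan.fever.add(d)
                elif u < 0.8:
                    plan.wbc_high.add(d)
                else:
                    plan.purulent.add(d)
            if rng.random() < noise.clabsi_coincidence_p:
                plan.add_abx(d, "vancomycin", Route.iv)
                if rng.random() < 0.7:
                    plan.fever.add(d)
                else:
                    plan.hypotension.add(d)
            if rng.random() < noise.contaminant_culture_p:
                cultures.append(
                    CultureResult(
                        stay_id=stay_id,
                        calendar_date=admission.date() + dt.timedelta(days=d - 1),
                        specimen=Specimen.blood_from_line,
                        organism="Staphylococcus epidermidis",
                        quantity=GrowthQuantity.plus,
                        pathogen_class=PathogenClass.contaminant,
                    )
                )
            # transient single-day densities; never adjacent, never in a
            # stay with a planted infiltrate run (a lone day cannot extend
            # into a confirmable two-day run)
            if (
                not has_vap_gt
                and rng.random() < noise.lone_infiltrate_p
                and (d - 1) not in lone_infiltrate_days
                and (d + 1) not in lone_infiltrate_days
            ):
                lone_infiltrate_days.add(d)
                radiology.append(
                    RadiologyFinding(
                        stay_id=stay_id,
                        calendar_date=admission.date() + dt.timedelta(days=d - 1),
                        infiltrate_or_consolidation=True,
                    )
                )

        # --- emit day records ---------------------------------------------
        for d in range(1, n_days + 1):
            if d in plan.fever:
                temp = float(rng.uniform(38.3, 39.8))
            else:
                temp = min(37.9, float(rng.normal(37.0, 0.4)))
            wbc_mid = float(rng.uniform(6000, 10500))
            wbc_min = wbc_mid - float(rng.uniform(0, 1500))
            wbc_max = wbc_mid + float(rng.uniform(0, 1300))
            if d in plan.wbc_low:
                wbc_min = float(rng.uniform(1500, 3800))
            else:
                wbc_min = max(wbc_min, 4200.0)
            if d in plan.wbc_high:
                wbc_max = float(rng.uniform(12500, 22000))
            else:
                wbc_max = min(wbc_max, 11800.0)
            sbp = (
                float(rng.uniform(65, 88))
                if d in plan.hypotension
                else float(rng.uniform(95, 140))
            )
            ventilated = d <= n_vent
            sputum: list[str] = []
            if ventilated:
                sputum.append("white" if rng.random() < 0.6 else "yellow")
            if d in plan.purulent:
                sputum.append("purulent")
            days.append(
                DayRecord(
                    stay_id=stay_id,
                    day_index=d,
                    calendar_date=admission.date() + dt.timedelta(days=d - 1),
                    mech_ventilation=ventilated,
                    central_lines=_sample_line_types(rng, line_counts[d]),
                    antibiotics=[
                        AntibioticAdministration(agent=a, route=r)
                        for a, r in plan.antibiotics[d]
                    ],
                    temp_max=round(temp, 1),
                    wbc_min=round(wbc_min),
                    wbc_max=round(max(wbc_min, wbc_max)),
                    sputum_descriptors=sputum,
                    sbp_min=round(sbp),
                )
            )

        stays.append(
            PatientStay(
                patient_id=patient_id,
                stay_id=stay_id,
                admission_ts=admission,
                discharge_ts=discharge.replace(second=0, microsecond=0),
                pneumonia_on_admission=pneumonia,
                icu_death=death,
                withdrawal_ts=withdrawal_ts,
            )
        )

    # --- sub-48-h stays (excluded by the inclusion filter) -----------------
    for j in range(config.n_short_stays):
        stay_id = f"X{j:04d}"
        admission = dt.datetime.combine(
            _BASE_DATE + dt.timedelta(days=int(rng.integers(0, 365))), dt.time()
        ) + dt.timedelta(minutes=int(rng.integers(0, 24 * 60)))
        los_h = float(rng.uniform(4.0, 47.0))
        discharge = admission + dt.timedelta(hours=los_h)
        n_days = (discharge.date() - admission.date()).days + 1
        for d in range(1, n_days + 1):
            days.append(
                DayRecord(
                    stay_id=stay_id,
                    day_index=d,
                    calendar_date=admission.date() + dt.timedelta(days=d - 1),
                    mech_ventilation=bool(rng.random() < 0.5),
                    central_lines=_sample_line_types(rng, int(rng.integers(0, 3))),
                    antibiotics=[],
                    temp_max=round(min(37.9, float(rng.normal(37.0, 0.4))), 1),
                    wbc_min=round(float(rng.uniform(4500, 8000))),
                    wbc_max=round(float(rng.uniform(8000, 11500))),
                    sbp_min=round(float(rng.uniform(95, 140))),
                )
            )
        stays.append(
            PatientStay(
                patient_id=f"Q{j:04d}",
                stay_id=stay_id,
                admission_ts=admission,
                discharge_ts=discharge.replace(second=0, microsecond=0),
                pneumonia_on_admission=bool(rng.random() < config.pneumonia_on_admission_p),
            )
        )

    radiology.sort(key=lambda r: (r.stay_id, r.calendar_date))
    cultures.sort(key=lambda c: (c.stay_id, c.calendar_date, c.specimen.value))
    ground_truth.sort(key=lambda g: (g.stay_id, g.infection_type.value))
    return SimulatedCohort(
        cohort=Cohort(stays=stays, days=days, radiology=radiology, cultures=cultures),
        ground_truth=ground_truth,
        config=config,
    )
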