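"""CSV and JSON-lines serialization of cohort streams.

The CSV dialect is one row per record with fixed, documented headers.
List-valued day fields are semicolon-delimited tokens:

* ``central_lines`` — one token per concurrent line, the line type
  repeated per count (``arterial;triple_lumen;triple_lumen``);
* ``antibiotics`` — ``agent:route`` tokens (``vancomycin:iv``);
* ``sputum_descriptors`` — plain tokens.

The JSON-lines dialect stores each record's native-structure dump, one
object per line.  Automated trigger factors (device status, antibiotics)
are mandatory in the day stream: a day row with an unparseable or absent
``mech_ventilation`` raises :class:`MandatoryFieldError` listing the
offending rows, mirroring the registration rule that no missing data are
allowed for the automated part.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .model import (
    Adjudication,
    AntibioticAdministration,
    Cohort,
    CultureResult,
    DayRecord,
    GrowthQuantity,
    InfectionEpisode,
    InfectionType,
    LineType,
    PathogenClass,
    PatientStay,
    RadiologyFinding,
    Route,
    Specimen,
    TriggerResult,
)
from .simulate import GroundTruthEpisode

STAY_FIELDS = [
    "patient_id", "stay_id", "admission_ts", "discharge_ts",
    "pneumonia_on_admission", "icu_death", "withdrawal_ts",
]
DAY_FIELDS = [
    "stay_id", "day_index", "calendar_date", "mech_ventilation", "central_lines",
    "antibiotics", "temp_max", "wbc_min", "wbc_max", "sputum_descriptors", "sbp_min",
]
RADIOLOGY_FIELDS = ["stay_id", "calendar_date", "infiltrate_or_consolidation", "verified_by_radiologist"]
CULTURE_FIELDS = ["stay_id", "calendar_date", "specimen", "line_type", "organism", "quantity", "pathogen_class"]
ADJUDICATION_FIELDS = ["stay_id", "infection_type", "decision", "rationale"]
GROUND_TRUTH_FIELDS = ["stay_id", "infection_type", "onset_day_index", "antibiotic_delay_days", "line_removal_only"]
EPISODE_FIELDS = ["stay_id", "infection_type", "onset_day_index", "detected_by", "needs_review", "confirmation_basis"]
TRIGGER_FIELDS = ["stay_id", "day_index", "vap_trigger", "clabsi_trigger", "factors"]

#: automated-part columns of the day stream; these may never be missing
MANDATORY_DAY_FIELDS = ["stay_id", "day_index", "calendar_date", "mech_ventilation",
                        "central_lines", "antibiotics"]


class MandatoryFieldError(ValueError):
    """A day row is missing data for an automated trigger factor."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(f"{message} (rows: {list(rows)[:20]}{'...' if len(rows) > 20 else ''})")
        self.rows = list(rows)


def _fmt_bool(v: bool) -> str:
    return "true" if v else "false"


def _parse_bool(v: str) -> bool:
    if v.lower() in ("true", "1", "yes"):
        return True
    if v.lower() in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


def _fmt_opt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return _fmt_bool(v)
    if isinstance(v, (dt.datetime, dt.date)):
        return v.isoformat()
    return str(v)


def _stay_row(s: PatientStay) -> dict:
    return {
        "patient_id": s.patient_id,
        "stay_id": s.stay_id,
        "admission_ts": s.admission_ts.isoformat(),
        "discharge_ts": _fmt_opt(s.discharge_ts),
        "pneumonia_on_admission": _fmt_bool(s.pneumonia_on_admission),
        "icu_death": _fmt_bool(s.icu_death),
        "withdrawal_ts": _fmt_opt(s.withdrawal_ts),
    }


def _parse_stay(row: dict) -> PatientStay:
    return PatientStay(
        patient_id=row["patient_id"],
        stay_id=row["stay_id"],
        admission_ts=dt.datetime.fromisoformat(row["admission_ts"]),
        discharge_ts=dt.datetime.fromisoformat(row["discharge_ts"]) if row.get("discharge_ts") else None,
        pneumonia_on_admission=_parse_bool(row["pneumonia_on_admission"]),
        icu_death=_parse_bool(row.get("icu_death") or "false"),
        withdrawal_ts=dt.datetime.fromisoformat(row["withdrawal_ts"]) if row.get("withdrawal_ts") else None,
    )


def _day_row(d: DayRecord) -> dict:
    lines: list[str] = []
    for lt in sorted(d.central_lines, key=lambda x: x.value):
        lines.extend([lt.value] * d.central_lines[lt])
    return {
        "stay_id": d.stay_id,
        "day_index": d.day_index,
        "calendar_date": d.calendar_date.isoformat(),
        "mech_ventilation": _fmt_bool(d.mech_ventilation),
        "central_lines": ";".join(lines),
        "antibiotics": ";".join(f"{a.agent}:{a.route.value}" for a in d.antibiotics),
        "temp_max": _fmt_opt(d.temp_max),
        "wbc_min": _fmt_opt(d.wbc_min),
        "wbc_max": _fmt_opt(d.wbc_max),
        "sputum_descriptors": ";".join(d.sputum_descriptors),
        "sbp_min": _fmt_opt(d.sbp_min),
    }


def _parse_day(row: dict) -> DayRecord:
    lines: dict[LineType, int] = {}
    for tok in filter(None, (row.get("central_lines") or "").split(";")):
        lt = LineType(tok.strip())
        lines[lt] = lines.get(lt, 0) + 1
    abx = []
    for tok in filter(None, (row.get("antibiotics") or "").split(";")):
        agent, _, route = tok.rpartition(":")
        abx.append(AntibioticAdministration(agent=agent.strip(), route=Route(route.strip())))
    return DayRecord(
        stay_id=row["stay_id"],
        day_index=int(row["day_index"]),
        calendar_date=dt.date.fromisoformat(row["calendar_date"]),
        mech_ventilation=_parse_bool(row["mech_ventilation"]),
        central_lines=lines,
        antibiotics=abx,
        temp_max=float(row["temp_max"]) if row.get("temp_max") else None,
        wbc_min=float(row["wbc_min"]) if row.get("wbc_min") else None,
        wbc_max=float(row["wbc_max"]) if row.get("wbc_max") else None,
        sputum_descriptors=[t for t in (row.get("sputum_descriptors") or "").split(";") if t],
        sbp_min=float(row["sbp_min"]) if row.get("sbp_min") else None,
    )


def _check_mandatory_day_rows(rows: list[dict]) -> None:
    bad: list[int] = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        for f in ("stay_id", "day_index", "calendar_date", "mech_ventilation"):
            if row.get(f) in (None, ""):
                bad.append(i)
                break
        else:
            if row.get("central_lines") is None or row.get("antibiotics") is None:
                bad.append(i)
    if bad:
        raise MandatoryFieldError(
            "automated surveillance factors are mandatory; missing data", bad
        )


# ---------------------------------------------------------------------------
# generic stream writers/readers

def _write_csv(path: Path, fieldnames: list[str], rows: Iterable[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)


def _read_csv(path: Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def _write_jsonl(path: Path, records: Iterable[dict]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, default=str) + "\n")


def _read_jsonl(path: Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


_STREAMS = {
    "stays": STAY_FIELDS,
    "days": DAY_FIELDS,
    "radiology": RADIOLOGY_FIELDS,
    "cultures": CULTURE_FIELDS,
    "adjudications": ADJUDICATION_FIELDS,
    "ground_truth": GROUND_TRUTH_FIELDS,
}


def write_cohort(
    cohort: Cohort,
    out_dir: str | Path,
    fmt: str = "csv",
    ground_truth: Optional[list[GroundTruthEpisode]] = None,
) -> list[Path]:
    """Write a cohort's streams to ``out_dir``; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    streams: dict[str, list[dict]] = {
        "stays": [_stay_row(s) for s in cohort.stays],
        "days": [_day_row(d) for d in cohort.days],
        "radiology": [
            {
                "stay_id": r.stay_id,
                "calendar_date": r.calendar_date.isoformat(),
                "infiltrate_or_consolidation": _fmt_bool(r.infiltrate_or_consolidation),
                "verified_by_radiologist": _fmt_bool(r.verified_by_radiologist),
            }
            for r in cohort.radiology
        ],
        "cultures": [
            {
                "stay_id": c.stay_id,
                "calendar_date": c.calendar_date.isoformat(),
                "specimen": c.specimen.value,
                "line_type": c.line_type.value if c.line_type else "",
                "organism": c.organism,
                "quantity": c.quantity.value,
                "pathogen_class": c.pathogen_class.value,
            }
            for c in cohort.cultures
        ],
        "adjudications": [
            {
                "stay_id": a.stay_id,
                "infection_type": a.infection_type.value,
                "decision": a.decision,
                "rationale": a.rationale,
            }
            for a in cohort.adjudications
        ],
    }
    if ground_truth is not None:
        streams["ground_truth"] = [
            {
                "stay_id": g.stay_id,
                "infection_type": g.infection_type.value,
                "onset_day_index": g.onset_day_index,
                "antibiotic_delay_days": g.antibiotic_delay_days,
                "line_removal_only": _fmt_bool(g.line_removal_only),
            }
            for g in ground_truth
        ]

    paths: list[Path] = []
    if fmt == "csv":
        for name, rows in streams.items():
            path = out_dir / f"{name}.csv"
            _write_csv(path, _STREAMS[name], rows)
            paths.append(path)
    elif fmt == "jsonl":
        native: dict[str, list[dict]] = {
            "stays": [s.model_dump(mode="json") for s in cohort.stays],
            "days": [d.model_dump(mode="json") for d in cohort.days],
            "radiology": [r.model_dump(mode="json") for r in cohort.radiology],
            "cultures": [c.model_dump(mode="json") for c in cohort.cultures],
            "adjudications": [a.model_dump(mode="json") for a in cohort.adjudications],
        }
        if ground_truth is not None:
            native["ground_truth"] = [
                {
                    "stay_id": g.stay_id,
                    "infection_type": g.infection_type.value,
                    "onset_day_index": g.onset_day_index,
                    "antibiotic_delay_days": g.antibiotic_delay_days,
                    "line_removal_only": g.line_removal_only,
                }
                for g in ground_truth
            ]
        for name, rows in native.items():
            path = out_dir / f"{name}.jsonl"
            _write_jsonl(path, rows)
            paths.append(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return paths


def _stream_rows(in_dir: Path, name: str) -> tuple[str, list[dict]]:
    csv_path = in_dir / f"{name}.csv"
    jsonl_path = in_dir / f"{name}.jsonl"
    if csv_path.exists():
        return "csv", _read_csv(csv_path)
    if jsonl_path.exists():
        return "jsonl", _read_jsonl(jsonl_path)
    return "csv", []


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort directory (CSV or JSON-lines streams)."""
    in_dir = Path(in_dir)
    day_fmt, day_rows = _stream_rows(in_dir, "days")
    if day_fmt == "csv":
        _check_mandatory_day_rows(day_rows)
        days = [_parse_day(r) for r in day_rows]
    else:
        bad = [
            i
            for i, r in enumerate(day_rows, start=1)
            if any(r.get(f) is None for f in ("stay_id", "day_index", "calendar_date",
                                              "mech_ventilation", "central_lines", "antibiotics"))
        ]
        if bad:
            raise MandatoryFieldError(
                "automated surveillance factors are mandatory; missing data", bad
            )
        days = [DayRecord.model_validate(r) for r in day_rows]

    stay_fmt, stay_rows = _stream_rows(in_dir, "stays")
    stays = (
        [_parse_stay(r) for r in stay_rows]
        if stay_fmt == "csv"
        else [PatientStay.model_validate(r) for r in stay_rows]
    )

    rad_fmt, rad_rows = _stream_rows(in_dir, "radiology")
    if rad_fmt == "jsonl":
        radiology = [RadiologyFinding.model_validate(r) for r in rad_rows]
    else:
        radiology = [
            RadiologyFinding(
                stay_id=r["stay_id"],
                calendar_date=dt.date.fromisoformat(r["calendar_date"]),
                infiltrate_or_consolidation=_parse_bool(r["infiltrate_or_consolidation"]),
                verified_by_radiologist=_parse_bool(r.get("verified_by_radiologist") or "true"),
            )
            for r in rad_rows
        ]

    cult_fmt, cult_rows = _stream_rows(in_dir, "cultures")
    if cult_fmt == "jsonl":
        cultures = [CultureResult.model_validate(r) for r in cult_rows]
    else:
        cultures = [
            CultureResult(
                stay_id=r["stay_id"],
                calendar_date=dt.date.fromisoformat(r["calendar_date"]),
                specimen=Specimen(r["specimen"]),
                line_type=LineType(r["line_type"]) if r.get("line_type") else None,
                organism=r["organism"],
                quantity=GrowthQuantity(r["quantity"]),
                pathogen_class=PathogenClass(r["pathogen_class"]),
            )
            for r in cult_rows
        ]

    adj_fmt, adj_rows = _stream_rows(in_dir, "adjudications")
    if adj_fmt == "jsonl":
        adjudications = [Adjudication.model_validate(r) for r in adj_rows]
    else:
        adjudications = [
            Adjudication(
                stay_id=r["stay_id"],
                infection_type=InfectionType(r["infection_type"]),
                decision=r["decision"],
                rationale=r.get("rationale") or "",
            )
            for r in adj_rows
        ]

    return Cohort(
        stays=stays, days=days, radiology=radiology, cultures=cultures,
        adjudications=adjudications,
    )


def read_ground_truth(in_dir: str | Path) -> list[GroundTruthEpisode]:
    fmt, rows = _stream_rows(Path(in_dir), "ground_truth")
    out = []
    for r in rows:
        removal = r["line_removal_only"]
        out.append(
            GroundTruthEpisode(
                stay_id=r["stay_id"],
                infection_type=InfectionType(r["infection_type"]),
                onset_day_index=int(r["onset_day_index"]),
                antibiotic_delay_days=int(r["antibiotic_delay_days"]),
                line_removal_only=removal if isinstance(removal, bool) else _parse_bool(removal),
            )
        )
    return out


# ---------------------------------------------------------------------------
# surveillance outputs

def write_trigger_results(results: Iterable[TriggerResult], path: str | Path) -> None:
    rows = [
        {
            "stay_id": r.stay_id,
            "day_index": r.day_index,
            "vap_trigger": _fmt_bool(r.vap_trigger),
            "clabsi_trigger": _fmt_bool(r.clabsi_trigger),
            "factors": json.dumps(
                {"vap": r.vap_factors.model_dump(), "clabsi": r.clabsi_factors.model_dump()}
            ),
        }
        for r in results
    ]
    _write_csv(Path(path), TRIGGER_FIELDS, rows)


def write_episodes(episodes: Iterable[InfectionEpisode], path: str | Path) -> None:
    rows = [
        {
            "stay_id": e.stay_id,
            "infection_type": e.infection_type.value,
            "onset_day_index": e.onset_day_index,
            "detected_by": e.detected_by,
            "needs_review": _fmt_bool(e.needs_review),
            "confirmation_basis": json.dumps(e.confirmation_basis),
        }
        for e in episodes
    ]
    _write_csv(Path(path), EPISODE_FIELDS, rows)


def read_episodes(path: str | Path) -> list[InfectionEpisode]:
    return [
        InfectionEpisode(
            stay_id=r["stay_id"],
            infection_type=InfectionType(r["infection_type"]),
            onset_day_index=int(r["onset_day_index"]),
            detected_by=r["detected_by"],
            needs_review=_parse_bool(r.get("needs_review") or "false"),
            confirmation_basis=json.loads(r.get("confirmation_basis") or "{}"),
        )
        for r in _read_csv(Path(path))
    ]


def write_exclusion_log(entries, path: str | Path) -> None:
    _write_csv(
        Path(path),
        ["stay_id", "rule", "detail", "excluded"],
        [
            {"stay_id": e.stay_id, "rule": e.rule, "detail": e.detail, "excluded": _fmt_bool(e.excluded)}
            for e in entries
        ],
    )
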