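"""CSV readers and writers for the registry and administrative schemas.

All files are UTF-8 CSV with a header row and ISO-8601 dates. Empty
code slots in the hospital-discharge schema are empty strings.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._dates import parse_date
from .attribution import AttributedEvent, DrugEvent, HospitalEpisode, OutpatientEvent
from .codelists import Stream
from .cohort import PatientRecord, Phase, PhaseAssignment, VitalStatus

PATIENT_COLUMNS = [
    "pid", "sex", "birth_date", "diagnosis_date", "topography",
    "vital_status", "death_date", "death_cause_cancer",
]
HD_COLUMNS = (
    ["pid", "admission_date", "discharge_date"]
    + [f"diag{i}" for i in range(1, 7)]
    + [f"proc{i}" for i in range(1, 7)]
    + ["drg"]
)
OPS_COLUMNS = ["pid", "date", "code"]
DRUG_COLUMNS = ["pid", "date", "atc"]


def _require(path: Path) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return path


def _read(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(_require(path), dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_patients(path) -> list[PatientRecord]:
    df = _read(path, PATIENT_COLUMNS)
    out = []
    for rec in df.to_dict(orient="records"):
        death = parse_date(rec["death_date"])
        cause = rec["death_cause_cancer"].strip().lower()
        out.append(
            PatientRecord(
                pid=rec["pid"],
                sex=rec["sex"],
                birth_date=parse_date(rec["birth_date"]),
                diagnosis_date=parse_date(rec["diagnosis_date"]),
                topography=rec["topography"],
                vital_status=VitalStatus(rec["vital_status"]),
                death_date=death,
                death_cause_cancer=(cause in {"true", "1"}) if cause else None,
            )
        )
    return out


def write_patients(patients: Iterable[PatientRecord], path) -> None:
    rows = [
        {
            "pid": p.pid,
            "sex": p.sex,
            "birth_date": p.birth_date.isoformat(),
            "diagnosis_date": p.diagnosis_date.isoformat(),
            "topography": p.topography,
            "vital_status": p.vital_status.value,
            "death_date": p.death_date.isoformat() if p.death_date else "",
            "death_cause_cancer": (
                "" if p.death_cause_cancer is None else str(p.death_cause_cancer).lower()
            ),
        }
        for p in patients
    ]
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)


def read_hd(path) -> list[HospitalEpisode]:
    df = _read(path, HD_COLUMNS)
    out = []
    for rec in df.to_dict(orient="records"):
        out.append(
            HospitalEpisode(
                pid=rec["pid"],
                admission_date=parse_date(rec["admission_date"]),
                discharge_date=parse_date(rec["discharge_date"]),
                diagnoses=tuple(rec[f"diag{i}"] for i in range(1, 7)),
                procedures=tuple(rec[f"proc{i}"] for i in range(1, 7)),
                drg=rec["drg"],
            )
        )
    return out


def write_hd(episodes: Iterable[HospitalEpisode], path) -> None:
    rows = []
    for e in episodes:
        row = {
            "pid": e.pid,
            "admission_date": e.admission_date.isoformat(),
            "discharge_date": e.discharge_date.isoformat(),
            "drg": e.drg,
        }
        for i in range(6):
            row[f"diag{i + 1}"] = e.diagnoses[i] if i < len(e.diagnoses) else ""
            row[f"proc{i + 1}"] = e.procedures[i] if i < len(e.procedures) else ""
        rows.append(row)
    pd.DataFrame(rows, columns=HD_COLUMNS).to_csv(path, index=False)


def read_ops(path) -> list[OutpatientEvent]:
    df = _read(path, OPS_COLUMNS)
    return [
        OutpatientEvent(pid=r["pid"], date=parse_date(r["date"]), code=r["code"])
        for r in df.to_dict(orient="records")
    ]


def write_ops(events: Iterable[OutpatientEvent], path) -> None:
    rows = [
        {"pid": e.pid, "date": e.date.isoformat(), "code": e.code} for e in events
    ]
    pd.DataFrame(rows, columns=OPS_COLUMNS).to_csv(path, index=False)


def read_drugs(path, stream: Stream | str) -> list[DrugEvent]:
    stream = Stream(stream)
    df = _read(path, DRUG_COLUMNS)
    return [
        DrugEvent(pid=r["pid"], date=parse_date(r["date"]), atc=r["atc"], stream=stream)
        for r in df.to_dict(orient="records")
    ]


def write_drugs(events: Iterable[DrugEvent], path) -> None:
    rows = [
        {"pid": e.pid, "date": e.date.isoformat(), "atc": e.atc} for e in events
    ]
    pd.DataFrame(rows, columns=DRUG_COLUMNS).to_csv(path, index=False)


ASSIGNMENT_COLUMNS = ["pid", "phase", "window_start", "window_end"]


def write_assignments(assignments: Iterable[PhaseAssignment], path) -> None:
    rows = [
        {
            "pid": a.pid,
            "phase": a.phase.value,
            "window_start": a.window_start.isoformat() if a.window_start else "",
            "window_end": a.window_end.isoformat() if a.window_end else "",
        }
        for a in assignments
    ]
    pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS).to_csv(path, index=False)


def read_assignments(path) -> dict[str, PhaseAssignment]:
    df = _read(path, ASSIGNMENT_COLUMNS)
    out = {}
    for r in df.to_dict(orient="records"):
        out[r["pid"]] = PhaseAssignment(
            pid=r["pid"],
            phase=Phase(r["phase"]),
            window_start=parse_date(r["window_start"]),
            window_end=parse_date(r["window_end"]),
        )
    return out


ATTRIBUTED_COLUMNS = [
    "pid", "stream", "event_date", "matched_code", "category",
    "subcategory", "phase", "excluded_from_frequency",
]


def write_attributed(events: Iterable[AttributedEvent], path) -> None:
    rows = [
        {
            "pid": e.pid,
            "stream": e.stream.value,
            "event_date": e.event_date.isoformat(),
            "matched_code": e.matched_code,
            "category": e.category,
            "subcategory": e.subcategory,
            "phase": e.phase.value,
            "excluded_from_frequency": str(e.excluded_from_frequency).lower(),
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=ATTRIBUTED_COLUMNS).to_csv(path, index=False)


def read_attributed(path) -> list[AttributedEvent]:
    df = _read(path, ATTRIBUTED_COLUMNS)
    return [
        AttributedEvent(
            pid=r["pid"],
            stream=Stream(r["stream"]),
            event_date=parse_date(r["event_date"]),
            matched_code=r["matched_code"],
            category=r["category"],
            subcategory=r["subcategory"],
            phase=Phase(r["phase"]),
            excluded_from_frequency=r["excluded_from_frequency"].strip().lower()
            in {"true", "1"},
        )
        for r in df.to_dict(orient="records")
    ]
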