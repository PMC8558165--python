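"""Cross-sectional phase-of-care assignment.

Every patient alive on the prevalence date and previously diagnosed is
assigned to exactly one of three mutually exclusive phases of care:

* **initial** — diagnosed within the 12 months before the prevalence
  date and alive 12 months after it (the first year after diagnosis);
* **final** — dies of cancer within the 12 months after the prevalence
  date, regardless of diagnosis date (the last year of life);
* **continuing** — diagnosed more than 12 months before the prevalence
  date and alive 12 months after it (everything in between).

Patients dying of non-cancer causes inside that follow-up year are
censored: they belong to no phase and contribute no observation window.

Each non-censored patient contributes one 12-calendar-month observation
window: from diagnosis forward (initial), from death backward (final),
or centred on the prevalence date, 6 months either side (continuing).
All intervals are half-open ``[start, end)``; "within 12 months before"
includes the boundary 12 months back and excludes the index date itself.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass

import pandas as pd

from ._dates import add_months


class VitalStatus(str, enum.Enum):
    ALIVE = "ALIVE"
    DEAD = "DEAD"


class Phase(str, enum.Enum):
    INITIAL = "INITIAL"
    CONTINUING = "CONTINUING"
    FINAL = "FINAL"
    CENSORED = "CENSORED"


#: Phases that carry an observation window, in reporting order.
OBSERVED_PHASES = (Phase.INITIAL, Phase.CONTINUING, Phase.FINAL)


class NotPrevalentError(ValueError):
    """The patient is not a prevalent case on the given prevalence date."""


@dataclass(frozen=True)
class PatientRecord:
    """Registry record anchoring phase assignment.

    ``topography`` is the ICD-O-3 site code (e.g. ``C50.9`` for breast);
    it is carried through for stratified reuse but not interpreted here.
    """

    pid: str
    sex: str
    birth_date: dt.date
    diagnosis_date: dt.date
    topography: str = ""
    vital_status: VitalStatus = VitalStatus.ALIVE
    death_date: dt.date | None = None
    death_cause_cancer: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "vital_status", VitalStatus(self.vital_status))
        dead = self.vital_status is VitalStatus.DEAD
        if dead != (self.death_date is not None):
            raise ValueError(
                f"patient {self.pid}: vital_status {self.vital_status.value} "
                f"inconsistent with death_date {self.death_date}"
            )
        if self.death_date is not None and self.diagnosis_date > self.death_date:
            raise ValueError(
                f"patient {self.pid}: diagnosis after death "
                f"({self.diagnosis_date} > {self.death_date})"
            )


@dataclass(frozen=True)
class PhaseAssignment:
    """A patient's phase on the prevalence date plus her 12-month window.

    Censored patients carry no window (both bounds None).
    """

    pid: str
    phase: Phase
    window_start: dt.date | None
    window_end: dt.date | None


def build_window(
    phase: Phase, patient: PatientRecord, prevalence_date: dt.date
) -> tuple[dt.date, dt.date]:
    """The 12-calendar-month observation window ``[start, end)`` for a phase.

    Initial: from diagnosis onwards. Final: from death backwards.
    Continuing: 6 months before to 6 months after the prevalence date.
    """
    phase = Phase(phase)
    if phase is Phase.INITIAL:
        return patient.diagnosis_date, add_months(patient.diagnosis_date, 12)
    if phase is Phase.FINAL:
        assert patient.death_date is not None
        return add_months(patient.death_date, -12), patient.death_date
    if phase is Phase.CONTINUING:
        return add_months(prevalence_date, -6), add_months(prevalence_date, 6)
    raise ValueError("censored patients have no observation window")


def assign_phase(patient: PatientRecord, prevalence_date: dt.date) -> PhaseAssignment:
    """Classify one prevalent patient into her phase of care.

    Raises :class:`NotPrevalentError` if the patient was diagnosed on or
    after the prevalence date, or had already died before it.
    """
    if patient.diagnosis_date >= prevalence_date:
        raise NotPrevalentError(
            f"patient {patient.pid}: diagnosed {patient.diagnosis_date}, "
            f"on/after prevalence date {prevalence_date}"
        )
    if patient.death_date is not None and patient.death_date < prevalence_date:
        raise NotPrevalentError(
            f"patient {patient.pid}: died {patient.death_date}, "
            f"before prevalence date {prevalence_date}"
        )

    follow_up_end = add_months(prevalence_date, 12)
    if patient.death_date is not None and patient.death_date < follow_up_end:
        # Death in the year after the prevalence date: last year of life
        # if cancer caused it, censored otherwise.
        if patient.death_cause_cancer:
            phase = Phase.FINAL
        else:
            return PhaseAssignment(patient.pid, Phase.CENSORED, None, None)
    elif patient.diagnosis_date >= add_months(prevalence_date, -12):
        phase = Phase.INITIAL
    else:
        phase = Phase.CONTINUING
    start, end = build_window(phase, patient, prevalence_date)
    return PhaseAssignment(patient.pid, phase, start, end)


def assign_phases(
    patients, prevalence_date: dt.date
) -> dict[str, PhaseAssignment]:
    """Vector form of :func:`assign_phase`, keyed by patient id."""
    return {p.pid: assign_phase(p, prevalence_date) for p in patients}


def phase_census(patients, prevalence_date: dt.date) -> pd.DataFrame:
    """Counts and percent shares of patients per phase of care.

    Shares are computed over the non-censored cohort (the patients that
    enter the pattern tables); censored patients are reported with count
    only. Returns a frame indexed by phase with ``n`` and ``share_pct``
    (full precision, NaN for CENSORED and for an empty census).
    """
    counts = {ph: 0 for ph in Phase}
    for p in patients:
        counts[assign_phase(p, prevalence_date).phase] += 1
    observed = sum(counts[ph] for ph in OBSERVED_PHASES)
    rows = []
    for ph in OBSERVED_PHASES:
        share = 100.0 * counts[ph] / observed if observed else float("nan")
        rows.append({"phase": ph.value, "n": counts[ph], "share_pct": share})
    rows.append(
        {"phase": Phase.CENSORED.value, "n": counts[Phase.CENSORED],
         "share_pct": float("nan")}
    )
    return pd.DataFrame(rows).set_index("phase")
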