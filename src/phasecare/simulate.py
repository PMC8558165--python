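"""Seeded generator of a linked registry + administrative dataset.

The generator emulates the statistical structure the attribution method
assumes: a cross-sectional cohort of cancer patients alive on a
prevalence date, each with a diagnosis date drawn uniformly over the
accrual window and an exponential post-diagnosis survival time, linked
to four administrative event streams (hospital discharges, outpatient
services, pharmacy prescriptions, hospital drugs).

Per patient and per code, event dates follow a piecewise-constant
Poisson process: a background rate ``lambda0`` (events/patient-year)
applies over the whole data-availability window — this is non-cancer
care, present before diagnosis too — and a phase-specific excess rate
is added after diagnosis: ``lambda_initial`` over the first 12 months,
``lambda_final`` over the last 12 months of life, ``lambda_continuing``
in between (final takes precedence where the periods overlap). Codes
with a positive excess rate in any phase are the *planted truth*: the
ground-truth cancer-related codes the self-control method should
recover. Null codes (equal pre/post intensity) and unlisted filler
codes exercise the attribution filtering non-trivially.

Hospital events are packaged into discharge episodes: the generating
code lands in a random slot of the appropriate kind (procedure or
diagnosis), the remaining slots are filled with never-listed filler
codes, and the main-diagnosis slot is always populated.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from ._dates import add_months, years_between
from .attribution import DrugEvent, HospitalEpisode, OutpatientEvent
from .codelists import CodeEntry, CodeList, CodingSystem, Stream
from .cohort import PatientRecord, Phase, VitalStatus

#: Never-listed codes used to pad hospital episode slots. They are not
#: candidates anywhere, so padding cannot leak signal into the tests.
FILLER_DIAGNOSES = ("401.9", "272.4", "530.81", "715.90", "486", "285.9")
FILLER_PROCEDURES = ("38.93", "93.59", "96.71", "99.29")


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimCode:
    """One code of the simulated coding universe.

    ``listed`` marks membership of the expert D-list; excess rates are
    events/patient-year added on top of ``lambda0`` in each phase.
    """

    code: str
    system: CodingSystem
    stream: Stream
    category: str
    subcategory: str = ""
    listed: bool = True
    excluded_from_frequency: bool = False
    lambda_initial: float = 0.0
    lambda_continuing: float = 0.0
    lambda_final: float = 0.0
    lambda0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "system", CodingSystem(self.system))
        object.__setattr__(self, "stream", Stream(self.stream))
        for name in ("lambda_initial", "lambda_continuing", "lambda_final", "lambda0"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0 for code {self.code}")

    @property
    def planted(self) -> bool:
        return (self.lambda_initial > 0 or self.lambda_continuing > 0
                or self.lambda_final > 0)

    def entry(self) -> CodeEntry:
        return CodeEntry(
            code=self.code, system=self.system, stream=self.stream,
            category=self.category, subcategory=self.subcategory,
            excluded_from_frequency=self.excluded_from_frequency,
        )


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset."""

    n_patients: int
    codes: tuple[SimCode, ...]
    accrual_start: dt.date = dt.date(2003, 1, 1)
    accrual_end: dt.date = dt.date(2010, 12, 31)
    prevalence_date: dt.date = dt.date(2011, 1, 1)
    data_start: dt.date = dt.date(2009, 1, 1)
    data_end: dt.date = dt.date(2011, 12, 31)
    noncancer_death_fraction: float = 0.2
    survival_mean_years: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not (0.0 <= self.noncancer_death_fraction <= 1.0):
            raise ConfigError("noncancer_death_fraction must be in [0, 1]")
        if self.survival_mean_years <= 0:
            raise ConfigError("survival_mean_years must be positive")
        if self.accrual_start > self.accrual_end:
            raise ConfigError("accrual window is empty")
        if self.accrual_end >= self.prevalence_date:
            raise ConfigError("accrual must end before the prevalence date")
        self.codes = tuple(self.codes)

    def dlist(self) -> CodeList:
        """The configured expert D-list (all listed codes)."""
        return CodeList(
            tuple(c.entry() for c in self.codes if c.listed), label="D-list"
        )

    def candidates(self) -> list[CodeEntry]:
        """Candidate universe for C-list derivation: every simulated
        code, listed or not."""
        return [c.entry() for c in self.codes]


def planted_truth(cfg: SimulationConfig) -> CodeList:
    """Ground-truth cancer-related codes: positive excess in any phase."""
    return CodeList(
        tuple(c.entry() for c in cfg.codes if c.planted), label="planted-truth"
    )


def _uniform_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    """Uniform date in [start, end] inclusive."""
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def generate_cohort(cfg: SimulationConfig, seed: int | None = None) -> list[PatientRecord]:
    """Draw prevalent patients until the configured cohort size is met.

    Diagnosis dates are uniform over the accrual window; survival after
    diagnosis is exponential with the configured mean; candidates dead
    before the prevalence date are discarded (the cohort is prevalence-
    based). Deaths more than 12 months after the prevalence date are
    beyond registry follow-up and recorded as alive.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    follow_up_end = add_months(cfg.prevalence_date, 12)
    patients: list[PatientRecord] = []
    draws = 0
    while len(patients) < cfg.n_patients:
        draws += 1
        if draws > 200 * cfg.n_patients:
            raise ConfigError("cohort generation not converging; check survival config")
        diagnosis = _uniform_date(rng, cfg.accrual_start, cfg.accrual_end)
        age = float(np.clip(rng.normal(62.0, 12.0), 25.0, 95.0))
        birth = diagnosis - dt.timedelta(days=int(age * 365.25))
        survival_days = float(rng.exponential(cfg.survival_mean_years * 365.25))
        death = diagnosis + dt.timedelta(days=max(1, int(survival_days)))
        if death <= cfg.prevalence_date:
            continue  # not alive on prevalence date
        if death < follow_up_end:
            status, death_date = VitalStatus.DEAD, death
            cause_cancer = bool(rng.random() >= cfg.noncancer_death_fraction)
        else:
            status, death_date, cause_cancer = VitalStatus.ALIVE, None, None
        patients.append(
            PatientRecord(
                pid=f"P{len(patients) + 1:06d}",
                sex="F",
                birth_date=birth,
                diagnosis_date=diagnosis,
                topography="C50.9",
                vital_status=status,
                death_date=death_date,
                death_cause_cancer=cause_cancer,
            )
        )
    return patients


def _phase_segments(
    cfg: SimulationConfig, p: PatientRecord
) -> list[tuple[dt.date, dt.date, Phase | None]]:
    """Piecewise-constant intensity segments inside the data window.

    ``None`` phase = pre-diagnosis (background only). Post-diagnosis,
    the last 12 months of life are FINAL; before that, the first 12
    months since diagnosis are INITIAL and the remainder CONTINUING.
    """
    start, end = cfg.data_start, cfg.data_end + dt.timedelta(days=1)  # half-open
    if p.death_date is not None:
        end = min(end, p.death_date)
    if start >= end:
        return []
    d = p.diagnosis_date
    initial_end = add_months(d, 12)
    final_start = add_months(p.death_date, -12) if p.death_date else None

    def phase_at(t: dt.date) -> Phase | None:
        if t < d:
            return None
        if final_start is not None and t >= final_start:
            return Phase.FINAL
        return Phase.INITIAL if t < initial_end else Phase.CONTINUING

    cuts = {start, end}
    for b in (d, initial_end, final_start):
        if b is not None and start < b < end:
            cuts.add(b)
    bounds = sorted(cuts)
    return [(a, b, phase_at(a)) for a, b in zip(bounds, bounds[1:])]


def _code_rate(code: SimCode, phase: Phase | None) -> float:
    if phase is None:
        return code.lambda0
    excess = {
        Phase.INITIAL: code.lambda_initial,
        Phase.CONTINUING: code.lambda_continuing,
        Phase.FINAL: code.lambda_final,
    }[phase]
    return code.lambda0 + excess


def _make_episode(
    rng: np.random.Generator, pid: str, date: dt.date, code: SimCode
) -> HospitalEpisode:
    los = int(rng.integers(1, 11))
    n_diag = int(rng.integers(1, 3))
    n_proc = int(rng.integers(0, 3))
    diags = list(rng.choice(FILLER_DIAGNOSES, size=n_diag, replace=False))
    procs = list(rng.choice(FILLER_PROCEDURES, size=n_proc, replace=False))
    if code.system is CodingSystem.ICD9CM_PROC:
        procs.insert(int(rng.integers(0, len(procs) + 1)), code.code)
    else:
        diags.insert(int(rng.integers(0, len(diags) + 1)), code.code)
    return HospitalEpisode(
        pid=pid,
        admission_date=date,
        discharge_date=date + dt.timedelta(days=los),
        diagnoses=tuple(diags[:6]),
        procedures=tuple(procs[:6]),
        drg=f"D{int(rng.integers(100, 600)):03d}",
    )


@dataclass
class EventTables:
    hd: list[HospitalEpisode] = field(default_factory=list)
    ops: list[OutpatientEvent] = field(default_factory=list)
    dp: list[DrugEvent] = field(default_factory=list)
    hp: list[DrugEvent] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {"HD": len(self.hd), "OPS": len(self.ops),
                "DP": len(self.dp), "HP": len(self.hp)}


def generate_events(
    cfg: SimulationConfig, patients: list[PatientRecord], seed: int | None = None
) -> EventTables:
    """Draw the four administrative event tables for a cohort.

    Seeded independently of the cohort draw (offset +1) so the two
    stages compose deterministically.
    """
    base = cfg.seed if seed is None else seed
    rng = np.random.default_rng((base + 1) % 2**31)
    tables = EventTables()
    for p in patients:
        segments = _phase_segments(cfg, p)
        for code in cfg.codes:
            for seg_start, seg_end, phase in segments:
                rate = _code_rate(code, phase)
                if rate <= 0:
                    continue
                exposure = years_between(seg_start, seg_end)
                n = int(rng.poisson(rate * exposure))
                for _ in range(n):
                    date = seg_start + dt.timedelta(
                        days=int(rng.integers(0, max(1, (seg_end - seg_start).days)))
                    )
                    if code.stream is Stream.HD:
                        tables.hd.append(_make_episode(rng, p.pid, date, code))
                    elif code.stream is Stream.OPS:
                        tables.ops.append(OutpatientEvent(p.pid, date, code.code))
                    elif code.stream is Stream.DP:
                        tables.dp.append(DrugEvent(p.pid, date, code.code, Stream.DP))
                    else:
                        tables.hp.append(DrugEvent(p.pid, date, code.code, Stream.HP))
    return tables


def selfcontrol_subcohort(
    cfg: SimulationConfig, patients: list[PatientRecord]
) -> list[PatientRecord]:
    """Patients usable as their own controls: diagnosed in the last
    accrual year (their pre-diagnosis history falls inside the data
    window) and alive 12 months after the prevalence date."""
    last_year_start = add_months(cfg.accrual_end + dt.timedelta(days=1), -12)
    follow_up_end = add_months(cfg.prevalence_date, 12)
    return [
        p for p in patients
        if p.diagnosis_date >= last_year_start
        and (p.death_date is None or p.death_date >= follow_up_end)
    ]


# ---------------------------------------------------------------------------
# Configuration I/O

_DATE_FIELDS = ("accrual_start", "accrual_end", "prevalence_date",
                "data_start", "data_end")


def config_from_dict(payload: dict) -> SimulationConfig:
    payload = dict(payload)
    codes = tuple(SimCode(**c) for c in payload.pop("codes"))
    for f in _DATE_FIELDS:
        if f in payload and not isinstance(payload[f], dt.date):
            payload[f] = dt.date.fromisoformat(str(payload[f]))
    return SimulationConfig(codes=codes, **payload)


def load_config(path: str | Path) -> SimulationConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"simulation config not found: {path}")
    return config_from_dict(yaml.safe_load(path.read_text()))


def demo_config(seed: int | None = None) -> SimulationConfig:
    """The shipped demo profile (500 patients, 10 planted + 20 null
    codes over a 36-code illustrative D-list)."""
    from importlib.resources import files

    cfg = config_from_dict(
        yaml.safe_load(files("phasecare.data").joinpath("demo_config.yaml").read_text())
    )
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    return cfg
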