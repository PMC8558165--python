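"""Event linkage, cancer-relatedness flagging and window selection.

Administrative events are linked to registry patients by exact match on
the pseudonymous id, flagged as cancer-related by D-list membership, and
restricted to each patient's phase-specific 12-month observation window.

A hospital discharge carries up to six ICD-9-CM diagnoses and six
procedures; the episode is cancer-related if *any* of the (up to) twelve
codes is listed. For tabulation each cancer-related episode is assigned
a single category: by default the category of the first listed code in
slot order — main procedure, secondary procedures, then main diagnosis,
secondary diagnoses — reflecting the "main cancer-related
intervention/procedure" semantics of discharge abstracts, with a
category-priority alternative available for sensitivity analyses.
Hospital episodes are anchored to their admission date for window
membership. Outpatient and drug events are single-code records and
contribute one row each.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .codelists import CodeEntry, CodeList, CodingSystem, Stream
from .cohort import Phase, PhaseAssignment

#: Category-priority ranking used by the optional classification rule.
CATEGORY_PRIORITY = (
    "Surgery",
    "Chemotherapy",
    "Radiotherapy",
    "Hormone therapy",
    "Biologic therapy",
    "Diagnosis and monitoring",
    "Support therapy",
    "Transfusion",
)


@dataclass(frozen=True)
class HospitalEpisode:
    """One hospital discharge record (HD stream)."""

    pid: str
    admission_date: dt.date
    discharge_date: dt.date
    diagnoses: tuple[str, ...]  # slot 0 = main, up to 6
    procedures: tuple[str, ...] = ()  # slot 0 = main, up to 6
    drg: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "diagnoses", tuple(c for c in self.diagnoses if str(c).strip())
        )
        object.__setattr__(
            self, "procedures", tuple(c for c in self.procedures if str(c).strip())
        )
        if self.admission_date > self.discharge_date:
            raise ValueError(
                f"episode for {self.pid}: admission {self.admission_date} "
                f"after discharge {self.discharge_date}"
            )
        if not self.diagnoses:
            raise ValueError(f"episode for {self.pid}: at least one diagnosis required")
        if len(self.diagnoses) > 6 or len(self.procedures) > 6:
            raise ValueError(f"episode for {self.pid}: more than 6 codes in a slot group")


@dataclass(frozen=True)
class OutpatientEvent:
    """One outpatient service record (OPS stream)."""

    pid: str
    date: dt.date
    code: str

    def __post_init__(self) -> None:
        if not str(self.code).strip():
            raise ValueError(f"outpatient event for {self.pid}: empty code")


@dataclass(frozen=True)
class DrugEvent:
    """One drug record — pharmacy prescription (DP) or hospital drug (HP)."""

    pid: str
    date: dt.date
    atc: str
    stream: Stream = Stream.DP

    def __post_init__(self) -> None:
        stream = Stream(self.stream)
        object.__setattr__(self, "stream", stream)
        if stream not in (Stream.DP, Stream.HP):
            raise ValueError(f"drug event stream must be DP or HP, got {stream}")


@dataclass(frozen=True)
class AttributedEvent:
    """A cancer-related event inside its patient's observation window."""

    pid: str
    stream: Stream
    event_date: dt.date
    matched_code: str
    category: str
    subcategory: str
    phase: Phase
    excluded_from_frequency: bool = False


@dataclass
class LinkResult:
    """Events grouped by patient id, with the unlinkable remainder."""

    groups: dict[str, list]
    unmatched: list = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return sum(len(v) for v in self.groups.values())


def link_events(patients: Iterable, events: Iterable) -> LinkResult:
    """Group events by exact patient-id match; count conservation holds:
    matched + unmatched = input."""
    pids = {p.pid for p in patients}
    groups: dict[str, list] = {pid: [] for pid in pids}
    unmatched: list = []
    for e in events:
        if e.pid in pids:
            groups[e.pid].append(e)
        else:
            unmatched.append(e)
    return LinkResult(groups=groups, unmatched=unmatched)


def _slot_entries(episode: HospitalEpisode, dlist: CodeList) -> list[CodeEntry]:
    """D-list entries matched by the episode's codes, in slot order
    (procedures main→secondary, then diagnoses main→secondary).

    A procedure slot only matches an ICD9CM_PROC entry and a diagnosis
    slot only an ICD9CM_DIAG entry, so a code shared between the two
    namespaces cannot cross-match.
    """
    hits: list[CodeEntry] = []
    for code in episode.procedures:
        entry = dlist.lookup(code, Stream.HD)
        if entry is not None and entry.system is CodingSystem.ICD9CM_PROC:
            hits.append(entry)
    for code in episode.diagnoses:
        entry = dlist.lookup(code, Stream.HD)
        if entry is not None and entry.system is CodingSystem.ICD9CM_DIAG:
            hits.append(entry)
    return hits


def flag_hospitalization(
    episode: HospitalEpisode, dlist: CodeList
) -> tuple[bool, list[str]]:
    """Cancer-related iff at least one of the ≤12 codes is listed.

    Returns the matched codes (as written on the list) in slot order.
    """
    hits = _slot_entries(episode, dlist)
    return bool(hits), [e.code for e in hits]


def classify_hospitalization(
    episode: HospitalEpisode, dlist: CodeList, rule: str = "slot_order"
) -> tuple[str, str]:
    """Single (category, subcategory) for a cancer-related episode.

    ``slot_order`` (default): the first listed code in slot order wins.
    ``category_priority``: among all matched codes, the one whose
    category ranks highest in :data:`CATEGORY_PRIORITY` wins (ties by
    slot order; unranked categories rank last).
    """
    hits = _slot_entries(episode, dlist)
    if not hits:
        raise ValueError("classify_hospitalization called on a non-cancer-related episode")
    if rule == "slot_order":
        chosen = hits[0]
    elif rule == "category_priority":
        def rank(entry: CodeEntry) -> int:
            try:
                return CATEGORY_PRIORITY.index(entry.category)
            except ValueError:
                return len(CATEGORY_PRIORITY)
        chosen = min(hits, key=lambda e: (rank(e), hits.index(e)))
    else:
        raise ValueError(f"unknown classification rule: {rule}")
    return chosen.category, chosen.subcategory


@dataclass
class SelectionStats:
    """Per-stream conservation bookkeeping for window selection."""

    total: int = 0
    retained: int = 0
    not_cancer_related: int = 0
    out_of_window: int = 0
    no_window: int = 0  # events of censored/unassigned patients

    def conserved(self) -> bool:
        return (
            self.retained + self.not_cancer_related
            + self.out_of_window + self.no_window == self.total
        )


def _in_window(date: dt.date, assignment: PhaseAssignment) -> bool:
    assert assignment.window_start is not None and assignment.window_end is not None
    return assignment.window_start <= date < assignment.window_end


def select_in_window(
    linked: Mapping[str, Sequence],
    assignments: Mapping[str, PhaseAssignment],
    dlist: CodeList,
    rule: str = "slot_order",
) -> tuple[list[AttributedEvent], dict[Stream, SelectionStats]]:
    """Attribute linked events to phases.

    Keeps exactly the cancer-related events whose anchoring date (HD:
    admission date; others: event date) falls in the owning patient's
    half-open observation window; each retained event carries the
    patient's phase. Censored patients contribute nothing. Returns the
    attributed events and per-stream conservation statistics.
    """
    out: list[AttributedEvent] = []
    stats: dict[Stream, SelectionStats] = {s: SelectionStats() for s in Stream}

    for pid, events in linked.items():
        assignment = assignments.get(pid)
        for e in events:
            if isinstance(e, HospitalEpisode):
                stream, date = Stream.HD, e.admission_date
            elif isinstance(e, OutpatientEvent):
                stream, date = Stream.OPS, e.date
            else:
                stream, date = Stream(e.stream), e.date
            st = stats[stream]
            st.total += 1
            if assignment is None or assignment.phase is Phase.CENSORED:
                st.no_window += 1
                continue
            if isinstance(e, HospitalEpisode):
                related, _ = flag_hospitalization(e, dlist)
                if not related:
                    st.not_cancer_related += 1
                    continue
                if not _in_window(date, assignment):
                    st.out_of_window += 1
                    continue
                category, subcategory = classify_hospitalization(e, dlist, rule=rule)
                # A discharge is one row; representative matched code is
                # the classifying one.
                hits = _slot_entries(e, dlist)
                chosen = next(
                    h for h in hits if (h.category, h.subcategory) == (category, subcategory)
                )
                out.append(
                    AttributedEvent(
                        pid=pid, stream=Stream.HD, event_date=date,
                        matched_code=chosen.code, category=category,
                        subcategory=subcategory, phase=assignment.phase,
                        excluded_from_frequency=chosen.excluded_from_frequency,
                    )
                )
                st.retained += 1
            else:
                code = e.code if isinstance(e, OutpatientEvent) else e.atc
                entry = dlist.lookup(code, stream)
                if entry is None:
                    st.not_cancer_related += 1
                    continue
                if not _in_window(date, assignment):
                    st.out_of_window += 1
                    continue
                out.append(
                    AttributedEvent(
                        pid=pid, stream=stream, event_date=date,
                        matched_code=entry.code, category=entry.category,
                        subcategory=entry.subcategory, phase=assignment.phase,
                        excluded_from_frequency=entry.excluded_from_frequency,
                    )
                )
                st.retained += 1
    return out, stats


def event_code_occurrences(
    hd: Iterable[HospitalEpisode] = (),
    ops: Iterable[OutpatientEvent] = (),
    drugs: Iterable[DrugEvent] = (),
) -> list[tuple[str, dt.date, str, Stream]]:
    """Flatten event tables into (pid, date, normalized-ish code, stream)
    code occurrences for per-code analyses.

    Hospital episodes contribute one occurrence per recorded code (each
    of the ≤12 slots), anchored at the admission date, since per-code
    comparisons operate on codes rather than whole discharges.
    """
    occ: list[tuple[str, dt.date, str, Stream]] = []
    for e in hd:
        for code in (*e.procedures, *e.diagnoses):
            occ.append((e.pid, e.admission_date, code, Stream.HD))
    for e in ops:
        occ.append((e.pid, e.date, e.code, Stream.OPS))
    for e in drugs:
        occ.append((e.pid, e.date, e.atc, Stream(e.stream)))
    return occ
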