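"""Cancer-related code lists (D-lists) and the lists derived from them.

The attribution method starts from expert-drawn lists of codes that
identify cancer-related care: ICD-9-CM procedure and diagnosis codes for
hospital discharges, national outpatient procedure codes, and ATC codes
for drugs. Each code carries a clinically relevant category (Surgery,
Chemotherapy, "Diagnosis and monitoring", ...) and optionally a
sub-category. An administrative event is cancer-related exactly when its
code is a member of the list for its service stream.

Code matching is exact on a normalized form: whitespace stripped,
upper-cased, and dots removed from ICD-9-CM-style codes (both dotted and
undotted forms circulate in discharge abstracts and regional outpatient
nomenclatures). ATC codes are compared verbatim after upper-casing. No
prefix semantics are applied by default — a list code matches only
itself — because the lists enumerate explicit codes and prefix matching
would silently widen them; an opt-in ATC prefix mode exists for
sensitivity analyses.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd


class CodingSystem(str, enum.Enum):
    """Coding system a list entry belongs to."""

    ICD9CM_PROC = "ICD9CM_PROC"
    ICD9CM_DIAG = "ICD9CM_DIAG"
    OUTPATIENT_NATIONAL = "OUTPATIENT_NATIONAL"
    ATC = "ATC"


class Stream(str, enum.Enum):
    """Administrative service stream.

    HD: hospital discharges; OPS: outpatient services; DP: pharmacy
    drug prescriptions; HP: hospital-administered (high-cost) drugs.
    """

    HD = "HD"
    OPS = "OPS"
    DP = "DP"
    HP = "HP"


#: Which coding systems are admissible in each stream.
_STREAM_SYSTEMS: dict[Stream, frozenset[CodingSystem]] = {
    Stream.HD: frozenset({CodingSystem.ICD9CM_PROC, CodingSystem.ICD9CM_DIAG}),
    Stream.OPS: frozenset({CodingSystem.OUTPATIENT_NATIONAL}),
    Stream.DP: frozenset({CodingSystem.ATC}),
    Stream.HP: frozenset({CodingSystem.ATC}),
}


class CodeListError(ValueError):
    """Raised for schema or invariant violations in a code list."""


def normalize_code(code: str, system: CodingSystem | None = None) -> str:
    """Canonical form used for membership comparison.

    ICD-9-CM and outpatient-nomenclature codes lose their dots
    (``85.21`` == ``8521``); ATC codes keep their structure. When the
    system is unknown (an incoming event code), dots are removed — ATC
    codes never contain dots, so this is lossless across systems.
    """
    c = code.strip().upper()
    if system is CodingSystem.ATC:
        return c
    return c.replace(".", "")


@dataclass(frozen=True)
class CodeEntry:
    """One cancer-related code with its classification.

    Parameters
    ----------
    code :
        The code as written in the source list (dotted ICD-9-CM forms
        are accepted and normalized for matching).
    system :
        Coding system; must be admissible for ``stream``.
    stream :
        Service stream the code applies to.
    category, subcategory :
        Clinically relevant grouping used by the frequency tables.
    excluded_from_frequency :
        True for codes (standard blood tests, genetic markers) that stay
        on the list for attribution but are dropped from outpatient
        frequency tables, where their per-test record volume would swamp
        the distribution.
    """

    code: str
    system: CodingSystem
    stream: Stream
    category: str
    subcategory: str = ""
    excluded_from_frequency: bool = False

    def __post_init__(self) -> None:
        if not self.code or not self.code.strip():
            raise CodeListError("code must be nonempty")
        if not self.category or not self.category.strip():
            raise CodeListError(f"category must be nonempty (code {self.code!r})")
        system = CodingSystem(self.system)
        stream = Stream(self.stream)
        object.__setattr__(self, "system", system)
        object.__setattr__(self, "stream", stream)
        if system not in _STREAM_SYSTEMS[stream]:
            raise CodeListError(
                f"system {system.value} is not valid for stream {stream.value} "
                f"(code {self.code!r})"
            )

    @property
    def key(self) -> tuple[str, Stream]:
        """(normalized code, stream) — the membership key."""
        return normalize_code(self.code, self.system), self.stream


@dataclass
class CodeList:
    """A validated collection of :class:`CodeEntry` with unique keys."""

    entries: tuple[CodeEntry, ...]
    label: str = "D-list"
    _index: dict[tuple[str, Stream], CodeEntry] = field(
        init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.entries = tuple(self.entries)
        index: dict[tuple[str, Stream], CodeEntry] = {}
        duplicates = []
        for e in self.entries:
            if e.key in index:
                duplicates.append(e.key)
            index[e.key] = e
        if duplicates:
            dups = ", ".join(f"({c}, {s.value})" for c, s in duplicates)
            raise CodeListError(f"duplicate (code, stream) pairs: {dups}")
        self._index = index

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CodeEntry]:
        return iter(self.entries)

    def __contains__(self, key: tuple[str, Stream | str]) -> bool:
        code, stream = key
        return self.lookup(code, stream) is not None

    def lookup(
        self, code: str, stream: Stream | str, *, atc_prefix: bool = False
    ) -> CodeEntry | None:
        """Return the matching entry, or None.

        With ``atc_prefix=True``, a DP/HP code also matches a shorter
        listed ATC code that is its prefix (longest listed prefix wins).
        """
        stream = Stream(stream)
        norm = normalize_code(code)
        hit = self._index.get((norm, stream))
        if hit is not None:
            return hit
        if atc_prefix and stream in (Stream.DP, Stream.HP):
            for cut in range(len(norm) - 1, 0, -1):
                hit = self._index.get((norm[:cut], stream))
                if hit is not None:
                    return hit
        return None

    def codes_for_stream(self, stream: Stream | str) -> list[CodeEntry]:
        stream = Stream(stream)
        return [e for e in self.entries if e.stream is stream]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": [e.code for e in self.entries],
                "system": [e.system.value for e in self.entries],
                "stream": [e.stream.value for e in self.entries],
                "category": [e.category for e in self.entries],
                "subcategory": [e.subcategory for e in self.entries],
                "excluded_from_frequency": [
                    e.excluded_from_frequency for e in self.entries
                ],
            }
        )


def is_cancer_related(code: str, stream: Stream | str, codelist: CodeList) -> bool:
    """True iff (code, stream) is a member of the list after normalization."""
    return codelist.lookup(code, stream) is not None


_REQUIRED_COLUMNS = ("code", "system", "stream", "category")
_ALL_COLUMNS = _REQUIRED_COLUMNS + ("subcategory", "excluded_from_frequency")

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f", "", "nan"}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise CodeListError(f"cannot interpret {value!r} as a boolean flag")


def _entries_from_records(records: Iterable[dict]) -> list[CodeEntry]:
    entries = []
    for rec in records:
        missing = [c for c in _REQUIRED_COLUMNS if c not in rec or rec[c] is None]
        if missing:
            raise CodeListError(f"missing required column(s): {', '.join(missing)}")
        sub = rec.get("subcategory", "")
        if sub is None or str(sub).lower() == "nan":
            sub = ""
        entries.append(
            CodeEntry(
                code=str(rec["code"]),
                system=CodingSystem(str(rec["system"]).strip()),
                stream=Stream(str(rec["stream"]).strip()),
                category=str(rec["category"]).strip(),
                subcategory=str(sub).strip(),
                excluded_from_frequency=_parse_bool(
                    rec.get("excluded_from_frequency", False)
                ),
            )
        )
    return entries


def load_codelist(path: str | Path, fmt: str | None = None, label: str | None = None) -> CodeList:
    """Read a code list from CSV or JSON.

    CSV schema: header row ``code,system,stream,category,subcategory,
    excluded_from_frequency`` (the last two optional, defaulting to
    empty/false). The JSON mirror is a list of objects with the same
    keys, optionally wrapped as ``{"label": ..., "entries": [...]}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"code list file not found: {path}")
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    fmt = fmt.lower()
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise CodeListError(
                f"missing required column(s): {', '.join(missing)} in {path}"
            )
        records = df.to_dict(orient="records")
    elif fmt == "json":
        payload = json.loads(path.read_text())
        if isinstance(payload, dict):
            label = label or payload.get("label")
            records = payload["entries"]
        else:
            records = payload
    else:
        raise ValueError(f"unknown code list format: {fmt}")
    return CodeList(tuple(_entries_from_records(records)), label=label or "D-list")


def save_codelist(codelist: CodeList, path: str | Path, fmt: str | None = None) -> None:
    """Write a code list; inverse of :func:`load_codelist`."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    fmt = fmt.lower()
    if fmt == "csv":
        codelist.to_frame().to_csv(path, index=False)
    elif fmt == "json":
        payload = {
            "label": codelist.label,
            "entries": codelist.to_frame().to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown code list format: {fmt}")
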