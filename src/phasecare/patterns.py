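"""Phase-stratified patterns of care: frequency tables, top-code
rankings and the phase-weighted category distribution.

Frequency tables report, for one service stream, absolute counts and
within-phase percent distributions of attributed events by category and
sub-category, one column pair per phase of care. Percents are computed
at full precision over the phase total and rounded half-away-from-zero
to one decimal for display, the convention of the published tables.

The phase-weighted distribution answers a different question: in which
phase is a category of care concentrated, once the very different sizes
of the phase cohorts are removed? For category counts ``count_p`` and
phase cohort sizes ``n_p`` the share of phase ``p`` is

    share_p = (count_p / n_p) / sum_q (count_q / n_q) * 100,

i.e. per-patient event rates normalized across phases. This
interpretation reproduces the published phase-concentration figures
(surgery 91% initial, hospital radiotherapy 62% final, ...) from the
published counts and cohort sizes, which pins down the otherwise
ambiguous "weighted by the percent distribution of patients" phrasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .attribution import AttributedEvent
from .codelists import Stream
from .cohort import OBSERVED_PHASES, Phase

#: Streams that get frequency tables. HP occurrences are qualitative
#: only (incomplete capture) and are never tabulated.
TABULATED_STREAMS = (Stream.HD, Stream.OPS, Stream.DP)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (0.25 -> 0.3 at 1 digit), matching the
    published tables rather than banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FrequencyTable:
    """Category × phase counts and within-phase percents for one stream.

    ``table`` columns: ``category, subcategory, N_<phase>, pct_<phase>``
    for the three observed phases, with category-level rows carrying an
    empty subcategory and a trailing ``Total`` row. ``flags`` records
    degenerate phases (empty phase totals reported as 0.0%).
    """

    stream: Stream
    table: pd.DataFrame
    phase_totals: dict[Phase, int]
    flags: list[str]


def _percent(count: int, total: int) -> float:
    return 100.0 * count / total if total else 0.0


def percent_table(
    counts: Mapping[tuple[str, str], Mapping[Phase, int]],
    phase_totals: Mapping[Phase, int],
    stream: Stream,
    category_order: Sequence[tuple[str, str]] | None = None,
) -> FrequencyTable:
    """Build a frequency table from pre-aggregated counts.

    ``counts`` maps (category, subcategory) — subcategory ``""`` for the
    category-level row — to per-phase absolute counts. Percents are
    always computed over ``phase_totals`` (sub-categories too, matching
    the published layout). This entry point is shared by
    :func:`tabulate` and by reproduction of published tables from their
    printed counts.
    """
    keys = list(category_order) if category_order is not None else sorted(counts)
    flags = [
        f"phase {ph.value} has no events; percents reported as 0.0"
        for ph in OBSERVED_PHASES
        if not phase_totals.get(ph, 0)
    ]
    rows = []
    for cat, sub in keys:
        row: dict = {"category": cat, "subcategory": sub}
        for ph in OBSERVED_PHASES:
            n = counts.get((cat, sub), {}).get(ph, 0)
            row[f"N_{ph.value.lower()}"] = n
            row[f"pct_{ph.value.lower()}"] = round_half_away(
                _percent(n, phase_totals.get(ph, 0)), 1
            )
        rows.append(row)
    total_row: dict = {"category": "Total", "subcategory": ""}
    for ph in OBSERVED_PHASES:
        t = phase_totals.get(ph, 0)
        total_row[f"N_{ph.value.lower()}"] = t
        total_row[f"pct_{ph.value.lower()}"] = 100.0 if t else 0.0
    rows.append(total_row)
    return FrequencyTable(
        stream=stream,
        table=pd.DataFrame(rows),
        phase_totals={ph: phase_totals.get(ph, 0) for ph in OBSERVED_PHASES},
        flags=flags,
    )


def tabulate(events: Iterable[AttributedEvent], stream: Stream | str) -> FrequencyTable:
    """Frequency table of attributed events for one stream.

    Events flagged ``excluded_from_frequency`` (standard blood tests,
    genetic markers on the outpatient list) contribute nothing. The DP
    table carries categories only, matching its published layout; other
    streams also break categories into sub-categories. Hospital
    discharges arrive as one attributed row per episode, so the table
    counts discharges, not codes.
    """
    stream = Stream(stream)
    if stream not in TABULATED_STREAMS:
        raise ValueError(f"stream {stream.value} is not tabulated (qualitative only)")
    selected = [
        e for e in events
        if Stream(e.stream) is stream and not e.excluded_from_frequency
    ]
    with_subcats = stream is not Stream.DP
    counts: dict[tuple[str, str], dict[Phase, int]] = {}
    phase_totals: dict[Phase, int] = {ph: 0 for ph in OBSERVED_PHASES}
    for e in selected:
        ph = Phase(e.phase)
        phase_totals[ph] += 1
        keys = [(e.category, "")]
        if with_subcats and e.subcategory:
            keys.append((e.category, e.subcategory))
        for key in keys:
            counts.setdefault(key, {ph2: 0 for ph2 in OBSERVED_PHASES})[ph] += 1

    # Categories ordered by descending initial-phase count (the layout
    # of the published tables), sub-categories nested likewise.
    def cat_sort(cat: str):
        c = counts.get((cat, ""), {})
        return (-sum(c.values()), cat)

    categories = sorted({cat for cat, sub in counts if not sub}, key=cat_sort)
    order: list[tuple[str, str]] = []
    for cat in categories:
        order.append((cat, ""))
        subs = sorted(
            (k for k in counts if k[0] == cat and k[1]),
            key=lambda k: (-sum(counts[k].values()), k[1]),
        )
        order.extend(subs)
    return percent_table(counts, phase_totals, stream, category_order=order)


def top_codes(
    events: Iterable[AttributedEvent],
    stream: Stream | str,
    phase: Phase | str,
    k: int,
) -> pd.DataFrame:
    """The ``k`` most frequent codes in one stream and phase.

    Percentages are over the total of cancer-related events of that
    stream in that phase. Ties break lexicographically by code. Events
    excluded from frequency tables are excluded here too.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    stream, phase = Stream(stream), Phase(phase)
    selected = [
        e for e in events
        if Stream(e.stream) is stream and Phase(e.phase) is phase
        and not e.excluded_from_frequency
    ]
    total = len(selected)
    counts: dict[str, int] = {}
    meta: dict[str, tuple[str, str]] = {}
    for e in selected:
        counts[e.matched_code] = counts.get(e.matched_code, 0) + 1
        meta.setdefault(e.matched_code, (e.category, e.subcategory))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return pd.DataFrame(
        [
            {
                "code": code,
                "category": meta[code][0],
                "subcategory": meta[code][1],
                "n": n,
                "pct": round_half_away(_percent(n, total), 1),
            }
            for code, n in ranked
        ]
    )


def phase_weighted_distribution(
    category_counts: Mapping[Phase, int],
    cohort_sizes: Mapping[Phase, int],
) -> dict[Phase, float]:
    """Share of a category's per-patient rate falling in each phase.

    Full-precision percents summing to 100; invariant to rescaling all
    cohort sizes by a common factor. Raises if any cohort size is
    non-positive or all counts are zero (the share is then undefined).
    """
    rates = {}
    for ph in OBSERVED_PHASES:
        n = cohort_sizes.get(ph, 0)
        if n <= 0:
            raise ValueError(f"cohort size for phase {ph.value} must be positive")
        rates[ph] = category_counts.get(ph, 0) / n
    total = sum(rates.values())
    if total == 0:
        raise ValueError("all category counts are zero; distribution undefined")
    return {ph: 100.0 * r / total for ph, r in rates.items()}


def phase_weighted_table(
    per_category_counts: Mapping[str, Mapping[Phase, int]],
    cohort_sizes: Mapping[Phase, int],
) -> pd.DataFrame:
    """Phase-weighted shares for several categories, rounded to integer
    percents (the display convention of the published figure)."""
    rows = []
    for cat, counts in per_category_counts.items():
        shares = phase_weighted_distribution(counts, cohort_sizes)
        rows.append(
            {
                "category": cat,
                **{
                    f"share_{ph.value.lower()}": round_half_away(shares[ph], 0)
                    for ph in OBSERVED_PHASES
                },
            }
        )
    return pd.DataFrame(rows)
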