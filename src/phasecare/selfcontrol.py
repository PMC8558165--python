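"""Self-control validation of the code lists (C-list derivation).

Patients diagnosed in the last accrual year carry pre-diagnostic event
history, so they can serve as their own controls: the 10 months ending
2 months before diagnosis approximate their non-cancer care, while the
10 months from diagnosis capture cancer-related care. The 2 months
immediately before diagnosis are discarded to avoid contamination by
pre-diagnostic work-up.

For every candidate code, per-patient occurrence counts in the two
windows are compared with the unequal-variance two-sample t-test, using
the Welch–Satterthwaite approximation for the degrees of freedom:

    t  = (x̄ − ȳ) / sqrt(s²x/nx + s²y/ny)
    df = (s²x/nx + s²y/ny)² / [ (s²x/nx)²/(nx−1) + (s²y/ny)²/(ny−1) ]

Codes whose post-diagnosis mean exceeds the pre-diagnosis mean with
two-sided p < 0.05 form the empirically derived C-list (the directional
requirement, a documented choice, keeps out codes *suppressed* after
diagnosis; the pure two-sided rule is available via ``directional=False``).
Agreement between the expert D-list and the C-list is summarised by the
occurrence-weighted concordance: the summed occurrence weights of codes
on both lists over the summed weights of the D-list.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._dates import add_months
from .codelists import CodeEntry, CodeList, Stream, normalize_code
from .cohort import PatientRecord


def build_pre_post_windows(
    patient: PatientRecord,
) -> tuple[tuple[dt.date, dt.date], tuple[dt.date, dt.date]]:
    """(control, case) windows around diagnosis, both 10 calendar months,
    half-open: control [diag−12m, diag−2m), case [diag, diag+10m)."""
    d = patient.diagnosis_date
    control = (add_months(d, -12), add_months(d, -2))
    case = (d, add_months(d, 10))
    return control, case


@dataclass
class CaseControlCounts:
    """Per-patient occurrence counts of one code in the two windows.

    One integer per patient per window, zeros included, so
    ``len(case) == len(control) ==`` subcohort size.
    """

    code: str
    stream: Stream
    case: np.ndarray
    control: np.ndarray


def per_code_counts(
    subcohort: Sequence[PatientRecord],
    occurrences: Iterable[tuple[str, dt.date, str, Stream]],
    code: str,
    stream: Stream | str,
) -> CaseControlCounts:
    """Count one code's occurrences per patient in the case and control
    windows (see :func:`build_pre_post_windows`)."""
    stream = Stream(stream)
    norm = normalize_code(code)
    windows = {p.pid: build_pre_post_windows(p) for p in subcohort}
    idx = {p.pid: i for i, p in enumerate(subcohort)}
    case = np.zeros(len(subcohort), dtype=int)
    control = np.zeros(len(subcohort), dtype=int)
    for pid, date, occ_code, occ_stream in occurrences:
        if pid not in idx or Stream(occ_stream) is not stream:
            continue
        if normalize_code(occ_code) != norm:
            continue
        (c0, c1), (k0, k1) = windows[pid]
        if k0 <= date < k1:
            case[idx[pid]] += 1
        elif c0 <= date < c1:
            control[idx[pid]] += 1
    return CaseControlCounts(code=code, stream=stream, case=case, control=control)


@dataclass
class TTestResult:
    """Welch t-test outcome for one code, with the inclusion decision."""

    code: str
    stream: Stream
    mean_case: float
    mean_control: float
    t_statistic: float
    df: float
    p_value: float
    included: bool
    reason: str = ""


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Unequal-variance two-sample t-test (Welch–Satterthwaite df).

    Returns ``(t, df, p)`` with a two-sided p-value. Degenerate samples:
    if both have zero variance, the t statistic is undefined and the
    decision degenerates to comparing means — p := 1.0 when equal (no
    evidence of difference) and p := 0.0 when different (deterministic
    separation), with t/df reported as nan/inf markers.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"each sample needs >= 2 observations (got {nx}, {ny})")
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return 0.0, float("nan"), 1.0
        return math.copysign(float("inf"), mx - my), float("nan"), 0.0
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, min(p, 1.0)


def derive_clist(
    subcohort: Sequence[PatientRecord],
    occurrences: Iterable[tuple[str, dt.date, str, Stream]],
    candidates: Iterable[CodeEntry],
    alpha: float = 0.05,
    directional: bool = True,
) -> tuple[CodeList, pd.DataFrame]:
    """Empirical C-list over a candidate code universe.

    A candidate enters the C-list when its per-patient case-window mean
    exceeds the control-window mean with p < ``alpha`` (two-sided Welch
    test); with ``directional=False`` significance alone decides. The
    full audit table (means, t, df, p, decision) is returned alongside
    so corrections or alternative rules can be applied downstream.
    """
    if not len(subcohort):
        raise ValueError("self-control subcohort is empty")
    pids = {p.pid for p in subcohort}
    occurrences = [o for o in occurrences if o[0] in pids]
    results: list[TTestResult] = []
    included_entries: list[CodeEntry] = []
    for entry in candidates:
        cc = per_code_counts(subcohort, occurrences, entry.code, entry.stream)
        if len(cc.case) < 2:
            results.append(
                TTestResult(entry.code, entry.stream, float("nan"), float("nan"),
                            float("nan"), float("nan"), float("nan"),
                            included=False, reason="insufficient sample")
            )
            continue
        t, df, p = welch_t_test(cc.case, cc.control)
        mean_case = float(cc.case.mean())
        mean_control = float(cc.control.mean())
        included = p < alpha and (mean_case > mean_control or not directional)
        reason = ""
        if cc.case.sum() == 0 and cc.control.sum() == 0:
            included, reason = False, "no occurrences in either window"
        results.append(
            TTestResult(entry.code, entry.stream, mean_case, mean_control,
                        t, df, p, included=included, reason=reason)
        )
        if included:
            included_entries.append(entry)
    audit = pd.DataFrame(
        [
            {
                "code": r.code, "stream": r.stream.value,
                "mean_case": r.mean_case, "mean_control": r.mean_control,
                "t": r.t_statistic, "df": r.df, "p": r.p_value,
                "included": r.included, "reason": r.reason,
            }
            for r in results
        ]
    )
    return CodeList(tuple(included_entries), label="C-list"), audit


def case_window_weights(
    subcohort: Sequence[PatientRecord],
    occurrences: Iterable[tuple[str, dt.date, str, Stream]],
    codes: Iterable[CodeEntry],
) -> dict[tuple[str, Stream], int]:
    """Occurrence weights: total case-window occurrences per code over
    the self-control subcohort (the default weighting for concordance)."""
    occurrences = list(occurrences)
    return {
        entry.key: int(
            per_code_counts(subcohort, occurrences, entry.code, entry.stream).case.sum()
        )
        for entry in codes
    }


@dataclass
class ConcordanceResult:
    """Agreement between the D-list and the derived C-list for one scope.

    ``unweighted``: |D ∩ C| / |D|. ``weighted``: occurrence-weighted
    version, dominated by frequent codes.
    """

    unweighted: float
    weighted: float
    detail: pd.DataFrame


def weighted_concordance(
    dlist: CodeList,
    clist: CodeList,
    weights: Mapping[tuple[str, Stream], float],
    stream: Stream | str | None = None,
) -> ConcordanceResult:
    """Occurrence-weighted concordance of C with D.

    ``weights`` maps (normalized code, stream) to nonnegative occurrence
    counts; D-list codes missing from the mapping weigh zero. Restrict
    to one stream with ``stream=``. Raises when the D-list's total
    weight is zero (the weighted ratio is then undefined).
    """
    stream = Stream(stream) if stream is not None else None
    d_entries = [
        e for e in dlist if stream is None or e.stream is stream
    ]
    if not d_entries:
        raise ValueError("D-list has no entries in the requested scope")
    rows = []
    w_total = w_shared = 0.0
    n_shared = 0
    for e in d_entries:
        w = float(weights.get(e.key, 0.0))
        if w < 0:
            raise ValueError(f"negative occurrence weight for {e.key}")
        in_c = e.key in clist._index
        rows.append(
            {"code": e.code, "stream": e.stream.value, "weight": w, "in_clist": in_c}
        )
        w_total += w
        if in_c:
            w_shared += w
            n_shared += 1
    if w_total == 0:
        raise ValueError("total D-list occurrence weight is zero; ratio undefined")
    return ConcordanceResult(
        unweighted=n_shared / len(d_entries),
        weighted=w_shared / w_total,
        detail=pd.DataFrame(rows),
    )
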