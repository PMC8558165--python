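"""Self-control windows, Welch test, C-list derivation, concordance."""

import datetime as dt
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from phasecare import (
    CodeEntry, CodeList, CodingSystem, Stream, build_pre_post_windows,
    derive_clist, per_code_counts, weighted_concordance, welch_t_test,
)

from conftest import make_patient


def exact_welch(x, y):
    """Independent oracle: the t and Welch–Satterthwaite df formulas
    evaluated in exact rational arithmetic (floats only at the end)."""
    x = [Fraction(int(v)) for v in x]
    y = [Fraction(int(v)) for v in y]
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = float(mx - my) / math.sqrt(float(se2))
    df = float(se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)))
    return t, df


class TestWindows:
    def test_control_and_case_windows(self):
        p = make_patient(diagnosis=dt.date(2010, 6, 15))
        control, case = build_pre_post_windows(p)
        assert control == (dt.date(2009, 6, 15), dt.date(2010, 4, 15))
        assert case == (dt.date(2010, 6, 15), dt.date(2011, 4, 15))

    def test_two_month_washout_excluded(self):
        """The two months before diagnosis belong to neither window, so a
        pre-diagnostic work-up event there is not counted at all."""
        p = make_patient(pid="S", diagnosis=dt.date(2010, 6, 15))
        occ = [("S", dt.date(2010, 5, 15), "89.7", Stream.OPS)]  # diag − 1m
        cc = per_code_counts([p], occ, "89.7", Stream.OPS)
        assert cc.case.sum() == 0 and cc.control.sum() == 0


class TestPerCodeCounts:
    def test_counts_per_patient_with_zeros(self):
        pats = [make_patient(pid=f"S{i}", diagnosis=dt.date(2010, 6, 15))
                for i in range(3)]
        occ = (
            [("S0", dt.date(2010, 7, 1), "89.7", Stream.OPS)] * 2
            + [("S2", dt.date(2010, 8, 1), "89.7", Stream.OPS)]
        )
        cc = per_code_counts(pats, occ, "89.7", Stream.OPS)
        assert list(cc.case) == [2, 0, 1]
        assert list(cc.control) == [0, 0, 0]

    def test_window_boundaries_half_open(self):
        p = make_patient(pid="S", diagnosis=dt.date(2010, 6, 15))
        occ = [
            ("S", dt.date(2010, 6, 15), "89.7", Stream.OPS),  # case start: in
            ("S", dt.date(2011, 4, 15), "89.7", Stream.OPS),  # case end: out
            ("S", dt.date(2009, 6, 15), "89.7", Stream.OPS),  # control start: in
            ("S", dt.date(2010, 4, 15), "89.7", Stream.OPS),  # control end: out
        ]
        cc = per_code_counts([p], occ, "89.7", Stream.OPS)
        assert cc.case[0] == 1 and cc.control[0] == 1

    def test_absent_code_gives_zero_vectors(self):
        p = make_patient(pid="S")
        cc = per_code_counts([p], [], "99.99", Stream.OPS)
        assert cc.case.sum() == 0 and cc.control.sum() == 0


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_textbook_vectors_match_exact_formula(self):
        x, y = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
        t, df, p = welch_t_test(x, y)
        t0, df0 = exact_welch(x, y)
        assert t == pytest.approx(t0, abs=1e-10)
        assert df == pytest.approx(df0, abs=1e-10)
        sp = stats.ttest_ind(x, y, equal_var=False)
        assert p == pytest.approx(sp.pvalue, abs=1e-10)

    def test_agrees_with_oracles_on_random_count_vectors(self):
        """t and df match exact rational arithmetic to 1e-8, and p matches
        an independent Welch implementation, over random Poisson counts."""
        rng = np.random.default_rng(12345)
        for _ in range(300):
            nx, ny = rng.integers(2, 60, size=2)
            x = rng.poisson(rng.uniform(0.1, 5.0), size=nx)
            y = rng.poisson(rng.uniform(0.1, 5.0), size=ny)
            if x.var(ddof=1) + y.var(ddof=1) == 0:
                continue
            t, df, p = welch_t_test(x, y)
            t0, df0 = exact_welch(x, y)
            assert t == pytest.approx(t0, abs=1e-8, rel=1e-8)
            assert df == pytest.approx(df0, abs=1e-8, rel=1e-8)
            sp = stats.ttest_ind(x, y, equal_var=False)
            assert p == pytest.approx(sp.pvalue, rel=1e-9, abs=1e-12)

    def test_degenerate_zero_variance_conventions(self):
        t, df, p = welch_t_test([2, 2, 2], [2, 2, 2])
        assert p == 1.0
        t, df, p = welch_t_test([3, 3, 3], [1, 1, 1])
        assert p == 0.0 and t == math.inf

    def test_insufficient_sample_raises(self):
        with pytest.raises(ValueError):
            welch_t_test([1], [1, 2])


def _entry(code, stream=Stream.OPS):
    system = {Stream.OPS: CodingSystem.OUTPATIENT_NATIONAL,
              Stream.DP: CodingSystem.ATC}[stream]
    return CodeEntry(code, system, stream, "Test")


class TestDeriveClist:
    def _subcohort(self, n):
        return [make_patient(pid=f"S{i}", diagnosis=dt.date(2010, 6, 15))
                for i in range(n)]

    def test_extreme_separation_included(self):
        pats = self._subcohort(50)
        occ = [(p.pid, dt.date(2010, 7, 1), "89.7", Stream.OPS) for p in pats]
        clist, audit = derive_clist(pats, occ, [_entry("89.7")])
        assert len(clist) == 1
        assert audit.included.all()

    def test_zero_occurrence_code_not_included(self):
        pats = self._subcohort(50)
        clist, audit = derive_clist(pats, [], [_entry("89.7")])
        assert len(clist) == 0
        assert audit.reason.iloc[0] == "no occurrences in either window"

    def test_suppressed_code_excluded_under_directional_rule(self):
        # occurs only *before* diagnosis: significant but wrong direction
        pats = self._subcohort(50)
        occ = [(p.pid, dt.date(2009, 9, 1), "89.7", Stream.OPS) for p in pats]
        directional, _ = derive_clist(pats, occ, [_entry("89.7")])
        assert len(directional) == 0
        two_sided, _ = derive_clist(pats, occ, [_entry("89.7")],
                                    directional=False)
        assert len(two_sided) == 1

    def test_null_code_inclusion_rate_is_halved_by_directionality(self):
        """Monte-Carlo: under the directional rule a null code (equal
        pre/post intensity) is included with probability ≈ α/2."""
        rng = np.random.default_rng(2024)
        pats = self._subcohort(50)
        n_reps, included = 2000, 0
        for _ in range(n_reps):
            case = rng.poisson(1.0, size=50)
            control = rng.poisson(1.0, size=50)
            t, df, p = welch_t_test(case, control)
            if p < 0.05 and case.mean() > control.mean():
                included += 1
        rate = included / n_reps
        # 99% binomial band around 0.025
        band = 2.576 * math.sqrt(0.025 * 0.975 / n_reps)
        assert abs(rate - 0.025) < band + 1e-12

    def test_planted_difference_power_at_n_100(self):
        """Codes with a post-minus-pre difference of 0.5 events/patient
        are recovered in at least 95% of replicates at n = 100."""
        rng = np.random.default_rng(7)
        reps, hits = 200, 0
        for _ in range(reps):
            case = rng.poisson(1.0, size=100)
            control = rng.poisson(0.5, size=100)
            t, df, p = welch_t_test(case, control)
            if p < 0.05 and case.mean() > control.mean():
                hits += 1
        assert hits / reps >= 0.95


class TestWeightedConcordance:
    def _lists(self):
        d = CodeList((_entry("a"), _entry("b"), _entry("c")), label="D")
        c = CodeList((_entry("a"), _entry("b")), label="C")
        return d, c

    def test_identity_gives_one(self):
        d, _ = self._lists()
        res = weighted_concordance(d, d, {e.key: 7 for e in d})
        assert res.weighted == 1.0 and res.unweighted == 1.0

    def test_forced_arithmetic(self):
        d, c = self._lists()
        weights = {("A", Stream.OPS): 10, ("B", Stream.OPS): 5,
                   ("C", Stream.OPS): 5}
        res = weighted_concordance(d, c, weights)
        assert res.weighted == pytest.approx(15 / 20)
        assert res.unweighted == pytest.approx(2 / 3)

    def test_disjoint_gives_zero(self):
        d, _ = self._lists()
        other = CodeList((_entry("z"),), label="C")
        res = weighted_concordance(d, other, {e.key: 1 for e in d})
        assert res.weighted == 0.0

    def test_monotone_in_list_intersection(self):
        """Adding a D-code to the C-list never decreases the ratio."""
        d, _ = self._lists()
        weights = {("A", Stream.OPS): 3, ("B", Stream.OPS): 2,
                   ("C", Stream.OPS): 9}
        prev = 0.0
        for codes in [(), ("a",), ("a", "b"), ("a", "b", "c")]:
            c = CodeList(tuple(_entry(x) for x in codes), label="C")
            r = weighted_concordance(d, c, weights).weighted
            assert r >= prev - 1e-12
            prev = r

    def test_zero_weight_dlist_is_undefined(self):
        d, c = self._lists()
        with pytest.raises(ValueError, match="undefined"):
            weighted_concordance(d, c, {})

    def test_unknown_codes_weigh_zero(self):
        d, c = self._lists()
        res = weighted_concordance(d, c, {("A", Stream.OPS): 4})
        assert res.weighted == 1.0  # b, c have no occurrences
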