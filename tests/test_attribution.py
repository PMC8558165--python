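"""Linkage, hospitalization flagging/classification and window selection."""

import datetime as dt
import random

import pytest

from phasecare import (
    DrugEvent, HospitalEpisode, OutpatientEvent, Phase, PhaseAssignment, Stream,
    assign_phases, classify_hospitalization, flag_hospitalization, link_events,
    select_in_window,
)
from phasecare.codelists import normalize_code

from conftest import PREVALENCE, make_patient


def episode(pid="P1", date=dt.date(2010, 7, 1), diagnoses=("401.9",),
            procedures=()):
    return HospitalEpisode(
        pid=pid, admission_date=date, discharge_date=date + dt.timedelta(days=3),
        diagnoses=diagnoses, procedures=procedures, drg="D260",
    )


class TestLinkEvents:
    def test_exact_key_grouping_conserves_counts(self):
        patients = [make_patient(pid="A"), make_patient(pid="B")]
        events = [episode(pid="A"), episode(pid="A"), episode(pid="B")]
        res = link_events(patients, events)
        assert {k: len(v) for k, v in res.groups.items()} == {"A": 2, "B": 1}
        assert not res.unmatched

    def test_unknown_pid_reported_unmatched(self):
        res = link_events([make_patient(pid="A")], [episode(pid="C")])
        assert len(res.unmatched) == 1
        assert res.n_matched == 0

    def test_empty_event_table(self):
        res = link_events([make_patient(pid="A")], [])
        assert res.n_matched == 0 and not res.unmatched


class TestFlagHospitalization:
    def test_single_main_procedure_match(self, tiny_dlist):
        related, codes = flag_hospitalization(
            episode(procedures=("85.21",)), tiny_dlist)
        assert related and codes == ["85.21"]

    def test_all_unlisted_is_not_cancer_related(self, tiny_dlist):
        related, codes = flag_hospitalization(
            episode(diagnoses=("401.9", "250.00"), procedures=("38.93",)),
            tiny_dlist)
        assert not related and codes == []

    def test_listed_code_in_last_secondary_diagnosis_slot_suffices(self, tiny_dlist):
        e = episode(diagnoses=("401.9", "250.00", "272.4", "486", "285.9", "V58.0"))
        related, codes = flag_hospitalization(e, tiny_dlist)
        assert related and codes == ["V58.0"]

    def test_procedure_slot_does_not_match_diagnosis_entry(self, tiny_dlist):
        # "174.9" is listed as a diagnosis code; in a procedure slot it
        # must not match
        e = episode(diagnoses=("401.9",), procedures=("174.9",))
        related, _ = flag_hospitalization(e, tiny_dlist)
        assert not related

    def test_flag_equals_brute_force_over_all_slots(self, tiny_dlist):
        """Property: the flag agrees with a scan over every code slot."""
        rng = random.Random(42)
        listed_procs = ["85.21", "99.25"]
        listed_diags = ["V58.0", "174.9"]
        pool_p = listed_procs + ["38.93", "93.59", "96.71"]
        pool_d = listed_diags + ["401.9", "250.00", "486"]
        for _ in range(200):
            diags = tuple(rng.choices(pool_d, k=rng.randint(1, 6)))
            procs = tuple(rng.choices(pool_p, k=rng.randint(0, 6)))
            e = episode(diagnoses=diags, procedures=procs)
            brute = any(c in listed_procs for c in procs) or any(
                c in listed_diags for c in diags)
            assert flag_hospitalization(e, tiny_dlist)[0] == brute


class TestClassifyHospitalization:
    def test_main_procedure_wins_over_secondary(self, tiny_dlist):
        e = episode(procedures=("85.21", "99.25"))
        assert classify_hospitalization(e, tiny_dlist) == ("Surgery", "Lumpectomy")

    def test_diagnosis_fallback_when_no_listed_procedure(self, tiny_dlist):
        e = episode(diagnoses=("401.9", "174.9"), procedures=("38.93",))
        assert classify_hospitalization(e, tiny_dlist) == (
            "Diagnosis and monitoring", "Diagnosis")

    def test_matches_first_match_in_slot_order_oracle(self, tiny_dlist):
        """The slot-order rule equals a brute-force first-match scan of
        procedures (main→secondary) then diagnoses (main→secondary)."""
        rng = random.Random(7)
        listed = {
            "8521": ("Surgery", "Lumpectomy"),
            "9925": ("Chemotherapy", ""),
            "V580": ("Radiotherapy", ""),
            "1749": ("Diagnosis and monitoring", "Diagnosis"),
        }
        pool_p = ["85.21", "99.25", "38.93", "96.71"]
        pool_d = ["V58.0", "174.9", "401.9", "486"]
        checked = 0
        for _ in range(300):
            diags = tuple(rng.choices(pool_d, k=rng.randint(1, 6)))
            procs = tuple(rng.choices(pool_p, k=rng.randint(0, 6)))
            proc_hits = [c for c in procs if normalize_code(c) in ("8521", "9925")]
            diag_hits = [c for c in diags if normalize_code(c) in ("V580", "1749")]
            hits = proc_hits + diag_hits
            if not hits:
                continue
            checked += 1
            expected = listed[normalize_code(hits[0])]
            e = episode(diagnoses=diags, procedures=procs)
            assert classify_hospitalization(e, tiny_dlist) == expected
        assert checked > 100

    def test_category_priority_rule(self, tiny_dlist):
        # chemotherapy main, surgery secondary: priority rule prefers Surgery
        e = episode(procedures=("99.25", "85.21"))
        assert classify_hospitalization(e, tiny_dlist)[0] == "Chemotherapy"
        assert classify_hospitalization(
            e, tiny_dlist, rule="category_priority")[0] == "Surgery"

    def test_non_cancer_related_episode_is_contract_violation(self, tiny_dlist):
        with pytest.raises(ValueError):
            classify_hospitalization(episode(), tiny_dlist)


class TestSelectInWindow:
    @pytest.fixture()
    def setting(self, tiny_dlist):
        patients = [
            make_patient(pid="INI", diagnosis=dt.date(2010, 6, 15)),
            make_patient(pid="CEN", diagnosis=dt.date(2010, 6, 15),
                         death=dt.date(2011, 8, 1), cancer_death=False),
        ]
        assignments = assign_phases(patients, PREVALENCE)
        return patients, assignments, tiny_dlist

    def test_half_open_window_boundaries(self, setting):
        patients, assignments, dlist = setting
        start, end = dt.date(2010, 6, 15), dt.date(2011, 6, 15)
        events = {
            "INI": [
                OutpatientEvent("INI", start, "89.7"),  # on start: retained
                OutpatientEvent("INI", end, "89.7"),    # on end: dropped
            ],
            "CEN": [],
        }
        attributed, stats = select_in_window(events, assignments, dlist)
        assert [e.event_date for e in attributed] == [start]
        assert stats[Stream.OPS].out_of_window == 1

    def test_censored_patient_contributes_nothing(self, setting):
        patients, assignments, dlist = setting
        events = {"CEN": [OutpatientEvent("CEN", dt.date(2010, 8, 1), "89.7")],
                  "INI": []}
        attributed, stats = select_in_window(events, assignments, dlist)
        assert attributed == []
        assert stats[Stream.OPS].no_window == 1

    def test_conservation_and_phase_labelling(self, setting):
        patients, assignments, dlist = setting
        events = {
            "INI": [
                OutpatientEvent("INI", dt.date(2010, 7, 1), "89.7"),
                OutpatientEvent("INI", dt.date(2010, 7, 2), "UNLISTED"),
                OutpatientEvent("INI", dt.date(2012, 7, 1), "89.7"),
                DrugEvent("INI", dt.date(2010, 8, 1), "L02BA01", Stream.DP),
                episode(pid="INI", date=dt.date(2010, 9, 1),
                        procedures=("85.21", "99.25")),
            ],
            "CEN": [],
        }
        attributed, stats = select_in_window(events, assignments, dlist)
        assert all(e.phase is Phase.INITIAL for e in attributed)
        # one attributed row per cancer-related hospitalization
        hd = [e for e in attributed if e.stream is Stream.HD]
        assert len(hd) == 1 and hd[0].category == "Surgery"
        for stream in (Stream.OPS, Stream.DP, Stream.HD):
            assert stats[stream].conserved()
        assert stats[Stream.OPS].retained == 1
        assert stats[Stream.OPS].not_cancer_related == 1
        assert stats[Stream.OPS].out_of_window == 1

    def test_event_order_permutation_invariance(self, setting):
        patients, assignments, dlist = setting
        events = [
            OutpatientEvent("INI", dt.date(2010, 7, 1), "89.7"),
            DrugEvent("INI", dt.date(2010, 8, 1), "L02BA01", Stream.DP),
            episode(pid="INI", date=dt.date(2010, 9, 1), procedures=("85.21",)),
            OutpatientEvent("INI", dt.date(2010, 10, 1), "90.62.2"),
        ]
        key = lambda e: (e.pid, e.stream.value, e.event_date, e.matched_code)
        base, _ = select_in_window({"INI": events}, assignments, dlist)
        for seed in range(3):
            shuffled = events[:]
            random.Random(seed).shuffle(shuffled)
            out, _ = select_in_window({"INI": shuffled}, assignments, dlist)
            assert sorted(out, key=key) == sorted(base, key=key)

    def test_hp_events_are_attributed_but_carry_their_stream(self, setting):
        patients, assignments, dlist = setting
        events = {"INI": [DrugEvent("INI", dt.date(2010, 8, 1), "L01XC03",
                                    Stream.HP)], "CEN": []}
        attributed, _ = select_in_window(events, assignments, dlist)
        assert len(attributed) == 1 and attributed[0].stream is Stream.HP
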