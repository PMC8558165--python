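"""Link events to patients, flag cancer-related ones via the D-list and
restrict them to the observation windows.

Reads results/demo/, writes results/demo/attributed.csv and prints the
per-stream conservation accounting.
"""

from pathlib import Path

from phasecare import Stream, io, link_events, load_codelist, select_in_window

BASE = Path(__file__).resolve().parents[1] / "results" / "demo"


def main() -> None:
    data = BASE / "data"
    dlist = load_codelist(data / "dlist.csv")
    patients = io.read_patients(data / "patients.csv")
    assignments = io.read_assignments(BASE / "assignments.csv")
    events = (
        io.read_hd(data / "events_hd.csv")
        + io.read_ops(data / "events_ops.csv")
        + io.read_drugs(data / "events_dp.csv", Stream.DP)
        + io.read_drugs(data / "events_hp.csv", Stream.HP)
    )
    linked = link_events(patients, events)
    attributed, stats = select_in_window(linked.groups, assignments, dlist)
    io.write_attributed(attributed, BASE / "attributed.csv")
    print(f"linked {linked.n_matched} events ({len(linked.unmatched)} unmatched)")
    for stream, st in stats.items():
        if st.total:
            print(f"  {stream.value}: {st.total} total -> {st.retained} attributed "
                  f"({st.not_cancer_related} non-cancer, {st.out_of_window} "
                  f"out of window, {st.no_window} censored); "
                  f"conserved={st.conserved()}")


if __name__ == "__main__":
    main()
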