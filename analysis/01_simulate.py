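"""Generate the demo linked dataset: a 500-patient prevalence cohort
(diagnoses 2003-2010, prevalence date 2011-01-01) with hospital,
outpatient, pharmacy and hospital-drug events, plus the illustrative
D-list and the planted ground-truth list.

Writes results/demo/data/*.csv.
"""

from pathlib import Path

from phasecare import demo_config, generate_cohort, generate_events, io
from phasecare import planted_truth, save_codelist

OUT = Path(__file__).resolve().parents[1] / "results" / "demo" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = demo_config()
    patients = generate_cohort(cfg)
    events = generate_events(cfg, patients)
    io.write_patients(patients, OUT / "patients.csv")
    io.write_hd(events.hd, OUT / "events_hd.csv")
    io.write_ops(events.ops, OUT / "events_ops.csv")
    io.write_drugs(events.dp, OUT / "events_dp.csv")
    io.write_drugs(events.hp, OUT / "events_hp.csv")
    save_codelist(cfg.dlist(), OUT / "dlist.csv")
    save_codelist(planted_truth(cfg), OUT / "planted_truth.csv")
    print(f"simulated {len(patients)} patients (seed {cfg.seed})")
    print("event records:", events.counts())
    print(f"D-list: {len(cfg.dlist())} codes, "
          f"{len(planted_truth(cfg))} with planted cancer-related excess")


if __name__ == "__main__":
    main()
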