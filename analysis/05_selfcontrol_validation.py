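"""Validate the D-list by the self-control method: derive the C-list on
the patients diagnosed in the last accrual year, then compute the
occurrence-weighted concordance against the planted truth and against
the full illustrative D-list.

Reads results/demo/data/, writes results/demo/clist.csv, clist_audit.csv
and concordance.csv.
"""

from pathlib import Path

import pandas as pd

from phasecare import (
    Stream, case_window_weights, demo_config, derive_clist,
    event_code_occurrences, io, load_codelist, planted_truth, save_codelist,
    weighted_concordance,
)
from phasecare.simulate import selfcontrol_subcohort

BASE = Path(__file__).resolve().parents[1] / "results" / "demo"


def main() -> None:
    cfg = demo_config()
    data = BASE / "data"
    patients = io.read_patients(data / "patients.csv")
    occurrences = event_code_occurrences(
        hd=io.read_hd(data / "events_hd.csv"),
        ops=io.read_ops(data / "events_ops.csv"),
        drugs=io.read_drugs(data / "events_dp.csv", Stream.DP)
        + io.read_drugs(data / "events_hp.csv", Stream.HP),
    )
    subcohort = selfcontrol_subcohort(cfg, patients)
    print(f"self-control subcohort: {len(subcohort)} patients diagnosed in "
          f"the last accrual year")

    clist, audit = derive_clist(subcohort, occurrences, cfg.candidates())
    save_codelist(clist, BASE / "clist.csv")
    audit.to_csv(BASE / "clist_audit.csv", index=False)
    print(f"C-list: {len(clist)} of {len(cfg.candidates())} candidates included")

    truth = planted_truth(cfg)
    dlist = load_codelist(data / "dlist.csv")
    rows = []
    for label, target in [("planted truth", truth), ("full D-list", dlist)]:
        weights = case_window_weights(subcohort, occurrences, target)
        res = weighted_concordance(target, clist, weights)
        rows.append({"dlist": label, "n_codes": len(target),
                     "unweighted": round(res.unweighted, 4),
                     "weighted": round(res.weighted, 4)})
        print(f"concordance vs {label}: weighted {res.weighted:.3f}, "
              f"unweighted {res.unweighted:.3f}")
    pd.DataFrame(rows).to_csv(BASE / "concordance.csv", index=False)
    recovered = {e.key for e in truth} & {e.key for e in clist}
    print(f"planted codes recovered: {len(recovered)}/{len(truth)}")
    print("(the published study reports >97% weighted concordance; the "
          "full-D-list gap here comes from listed codes simulated as never "
          "administered or as pre/post-neutral background care)")


if __name__ == "__main__":
    main()
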