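"""Reproduce the published phase-of-care results from the printed
aggregate counts: within-phase percent tables for the three streams,
the stream phase shares, and the phase-weighted (Figure-style) category
concentrations.

Writes results/published/*.csv and prints the headline numbers.
"""

from pathlib import Path

import pandas as pd

from phasecare import Phase, Stream, phase_weighted_distribution, round_half_away
from phasecare import reference as ref

OUT = Path(__file__).resolve().parents[1] / "results" / "published"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for stream in (Stream.HD, Stream.OPS, Stream.DP):
        ft = ref.published_frequency_table(stream)
        ft.table.to_csv(OUT / f"table_{stream.value.lower()}.csv", index=False)
        printed = ref.published_percents(stream)
        mismatches = sum(
            1
            for _, row in ft.table.iterrows()
            if (row.category, row.subcategory) in printed
            for ph in (Phase.INITIAL, Phase.CONTINUING, Phase.FINAL)
            if abs(row[f"pct_{ph.value.lower()}"]
                   - printed[(row.category, row.subcategory)][ph]) > 1e-9
        )
        totals = ref.STREAM_TOTALS[stream]
        shares = [round_half_away(100 * totals[ph] / sum(totals.values()), 0)
                  for ph in (Phase.INITIAL, Phase.CONTINUING, Phase.FINAL)]
        print(f"{stream.value}: {len(printed)} rows, {mismatches} percent "
              f"mismatches vs print; phase shares {shares}")

    rows = []
    for stream, cat in [(Stream.HD, "Surgery"), (Stream.HD, "Radiotherapy"),
                        (Stream.HD, "Chemotherapy"),
                        (Stream.HD, "Diagnosis and monitoring"),
                        (Stream.OPS, "Radiotherapy")]:
        shares = phase_weighted_distribution(
            ref.category_counts(stream, cat), ref.COHORT_SIZES)
        rows.append({"stream": stream.value, "category": cat,
                     **{f"share_{ph.value.lower()}": round_half_away(s, 0)
                        for ph, s in shares.items()}})
    pw = pd.DataFrame(rows)
    pw.to_csv(OUT / "phase_weighted.csv", index=False)
    print("phase-weighted concentrations (integer %):")
    print(pw.to_string(index=False))


if __name__ == "__main__":
    main()
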