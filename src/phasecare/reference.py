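"""Published aggregate results for the pooled Italian breast-cancer
patterns-of-care study (female breast cancer, eight cancer registries,
prevalence date 2011-01-01, diagnoses 2003–2010).

These are the printed phase-stratified category counts for the three
tabulated streams, the per-phase cohort sizes, and the printed percent
distributions, kept here as pre-aggregated inputs so the tabulation and
phase-weighting machinery can be validated against them. They are
*outputs* of the original study used as fixtures — nothing in the
pipeline depends on them.

Two entries of the pharmacy table are typographically damaged in the
available rendering of the source tables and were reconstructed from
the printed percents, which are mutually consistent: the continuing-
phase total (138,330 — implied independently by the hormone-therapy
67.5%, cortisone 11.2% and bisphosphonate 10.3% rows) and the
continuing-phase analgesic count (12,398, giving the printed 9.0%).
The final-phase total (17,436) is the sum of its category counts. Note
also that the hospital continuing-phase "Diagnosis and monitoring"
sub-category counts as printed sum to 4,051 while the category row
reads 4,045; both are kept as printed since every percent is consistent
with its own count and the phase total.
"""

from __future__ import annotations

from .cohort import Phase
from .codelists import Stream
from .patterns import FrequencyTable, percent_table

#: Patients per phase of care on the prevalence date.
COHORT_SIZES: dict[Phase, int] = {
    Phase.INITIAL: 7501,
    Phase.CONTINUING: 39369,
    Phase.FINAL: 2400,
}

#: Total records analysed per stream (all phases).
STREAM_TOTALS: dict[Stream, dict[Phase, int]] = {
    Stream.HD: {Phase.INITIAL: 11866, Phase.CONTINUING: 8900, Phase.FINAL: 3714},
    Stream.OPS: {Phase.INITIAL: 151305, Phase.CONTINUING: 411495, Phase.FINAL: 30593},
    Stream.DP: {Phase.INITIAL: 29855, Phase.CONTINUING: 138330, Phase.FINAL: 17436},
}

# Rows: (category, subcategory, (N_init, pct_init), (N_cont, pct_cont),
# (N_final, pct_final)); subcategory "" marks the category-level row.
HD_ROWS = [
    ("Surgery", "", (8021, 67.6), (2560, 28.8), (93, 2.5)),
    ("Surgery", "Lumpectomy", (4931, 41.6), (505, 5.7), (30, 0.8)),
    ("Surgery", "Surgery", (1826, 15.4), (260, 2.9), (31, 0.8)),
    ("Surgery", "Lymphadenectomy", (743, 6.3), (128, 1.4), (16, 0.4)),
    ("Surgery", "Plastic surgery", (433, 3.6), (1646, 18.5), (15, 0.4)),
    ("Surgery", "Radical and reconstructive surgery", (88, 0.7), (21, 0.2), (1, 0.0)),
    ("Chemotherapy", "", (2150, 18.1), (1668, 18.7), (900, 24.2)),
    ("Diagnosis and monitoring", "", (1397, 11.8), (4045, 45.4), (2195, 59.1)),
    ("Diagnosis and monitoring", "Biopsy", (356, 3.0), (342, 3.8), (49, 1.3)),
    ("Diagnosis and monitoring", "Cardiologic assessment", (340, 2.9), (1019, 11.4), (446, 12.0)),
    ("Diagnosis and monitoring", "Diagnosis", (269, 2.3), (961, 10.8), (541, 14.6)),
    ("Diagnosis and monitoring", "High diagnostic", (231, 1.9), (807, 9.1), (569, 15.3)),
    ("Diagnosis and monitoring", "Conventional radiology", (101, 0.9), (580, 6.5), (359, 9.7)),
    ("Diagnosis and monitoring", "Ultrasonography", (85, 0.7), (270, 3.0), (120, 3.2)),
    ("Diagnosis and monitoring", "Invasive procedure", (8, 0.1), (42, 0.5), (100, 2.7)),
    ("Diagnosis and monitoring", "Other diagnostic procedure", (7, 0.1), (30, 0.3), (11, 0.3)),
    ("Radiotherapy", "", (173, 1.5), (108, 1.2), (101, 2.7)),
    ("Support therapy", "", (78, 0.7), (319, 3.6), (348, 9.4)),
    ("Biologic therapy", "", (35, 0.3), (102, 1.1), (19, 0.5)),
    ("Transfusion", "", (12, 0.1), (98, 1.1), (58, 1.6)),
]

OPS_ROWS = [
    ("Diagnosis and monitoring", "", (90535, 59.8), (380107, 92.4), (22464, 73.4)),
    ("Diagnosis and monitoring", "Specialist examination", (39042, 25.8), (147315, 35.8), (10060, 32.9)),
    ("Diagnosis and monitoring", "High diagnostic", (12915, 8.5), (34454, 8.4), (4809, 15.7)),
    ("Diagnosis and monitoring", "Ultrasonography", (12371, 8.2), (68218, 16.6), (1319, 4.3)),
    ("Diagnosis and monitoring", "Conventional radiology", (9599, 6.3), (75889, 18.4), (2997, 9.8)),
    ("Diagnosis and monitoring", "Biopsy", (6798, 4.5), (10261, 2.5), (344, 1.1)),
    ("Diagnosis and monitoring", "Cardiologic assessment", (5736, 3.8), (28387, 6.9), (2126, 6.9)),
    ("Diagnosis and monitoring", "Physiatry", (1499, 1.0), (5929, 1.4), (631, 2.1)),
    ("Diagnosis and monitoring", "Genetic tests", (952, 0.6), (1427, 0.3), (115, 0.4)),
    ("Diagnosis and monitoring", "Bone Densitometry", (1623, 1.1), (8227, 2.0), (63, 0.2)),
    ("Radiotherapy", "", (41597, 27.5), (9210, 2.2), (2711, 8.9)),
    ("Chemotherapy", "", (9407, 6.2), (9323, 2.3), (3019, 9.9)),
    ("Post-surgical procedure", "", (3913, 2.6), (4503, 1.1), (546, 1.8)),
    ("Hormone therapy", "", (2580, 1.7), (2306, 0.6), (555, 1.8)),
    ("Support therapy", "", (1983, 1.3), (3591, 0.9), (942, 3.1)),
    ("Psychotherapy", "", (1018, 0.7), (1685, 0.4), (103, 0.3)),
    ("Plastic surgery", "", (268, 0.2), (672, 0.2), (5, 0.0)),
    ("Transfusion", "", (4, 0.0), (98, 0.0), (248, 0.8)),
]

DP_ROWS = [
    ("Hormone therapy", "", (18947, 63.5), (93373, 67.5), (2451, 14.1)),
    ("Cortisone", "", (4246, 14.2), (15493, 11.2), (6684, 38.3)),
    ("Antiemetic", "", (2884, 9.7), (1579, 1.1), (844, 4.8)),
    ("Analgesic", "", (1568, 5.3), (12398, 9.0), (6860, 39.3)),
    ("Myelopoietic growth factor", "", (1115, 3.7), (435, 0.3), (166, 1.0)),
    ("Bisphosphonate", "", (928, 3.1), (14247, 10.3), (288, 1.7)),
    ("Chemotherapic drug", "", (136, 0.5), (722, 0.5), (94, 0.5)),
    ("Hematopoietic growth factors", "", (31, 0.1), (83, 0.1), (49, 0.3)),
]

_ROWS = {Stream.HD: HD_ROWS, Stream.OPS: OPS_ROWS, Stream.DP: DP_ROWS}

_PHASES = (Phase.INITIAL, Phase.CONTINUING, Phase.FINAL)


def published_counts(stream: Stream) -> dict[tuple[str, str], dict[Phase, int]]:
    """Pre-aggregated (category, subcategory) → phase → N for a stream."""
    return {
        (cat, sub): {ph: cell[0] for ph, cell in zip(_PHASES, cells)}
        for cat, sub, *cells in _ROWS[Stream(stream)]
    }


def published_percents(stream: Stream) -> dict[tuple[str, str], dict[Phase, float]]:
    """The printed within-phase percent for every row of a stream."""
    return {
        (cat, sub): {ph: cell[1] for ph, cell in zip(_PHASES, cells)}
        for cat, sub, *cells in _ROWS[Stream(stream)]
    }


def published_frequency_table(stream: Stream) -> FrequencyTable:
    """Recompute the within-phase percent table from the printed counts."""
    stream = Stream(stream)
    counts = published_counts(stream)
    order = [(cat, sub) for cat, sub, *_ in _ROWS[stream]]
    return percent_table(counts, STREAM_TOTALS[stream], stream, category_order=order)


def category_counts(stream: Stream, category: str) -> dict[Phase, int]:
    """Per-phase counts of one category (category-level row)."""
    try:
        return published_counts(Stream(stream))[(category, "")]
    except KeyError:
        raise KeyError(f"category {category!r} not in stream {stream} table") from None
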