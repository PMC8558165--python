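# phasecare

Identifying cancer-related patterns of care from cancer-registry data
linked to administrative health databases, by the **direct (attribution)
method**: an expert-drawn list of cancer-related codes (the *D-list* —
ICD-9-CM procedures and diagnoses for hospital discharges, national
outpatient procedure codes, ATC drug codes) flags which events in the
claims streams are cancer-related, and events are tabulated by *phase of
care*. The package is aimed at registry epidemiologists and
health-services researchers who have individually linked registry +
claims data (or want to prototype against realistic synthetic data) and
need phase-stratified utilisation patterns without a matched non-cancer
comparison cohort.

## The method

Every patient alive on a **prevalence date** and previously diagnosed is
assigned exactly one of three mutually exclusive phases of care:

* **initial** — diagnosed within 12 months before the prevalence date
  and alive 12 months after it;
* **final** — dies of cancer within 12 months after the prevalence date,
  whatever the diagnosis date;
* **continuing** — diagnosed earlier and alive 12 months after.

Non-cancer deaths in the follow-up year are censored. Each patient
contributes one 12-month observation window: `[diagnosis, diagnosis+12m)`
(initial), `[death−12m, death)` (final), or `[prevalence−6m,
prevalence+6m)` (continuing). An event is cancer-related iff its code is
on the D-list; a hospitalization with up to 6 diagnosis and 6 procedure
codes is cancer-related if *any* code is listed, and is classified by its
first listed code in slot order. Within each phase, events are tabulated
by clinical category as counts and within-phase percents; a category's
concentration across phases is summarised by per-patient rate
normalization,

&nbsp;&nbsp;&nbsp;&nbsp;share<sub>p</sub> = (N<sub>p</sub>/n<sub>p</sub>) / Σ<sub>q</sub>(N<sub>q</sub>/n<sub>q</sub>) × 100,

where N<sub>p</sub> is the category count and n<sub>p</sub> the cohort
size in phase *p*.

The D-list is validated by a **self-control** design: patients diagnosed
in the last accrual year are their own controls — events in the 10
months ending 2 months before diagnosis (control window) versus the 10
months from diagnosis (case window). For every candidate code, the
per-patient counts are compared with the unequal-variance two-sample
t-test (Welch–Satterthwaite degrees of freedom); codes significantly
more frequent after diagnosis (p < 0.05) form the *C-list*. Agreement is
summarised by the occurrence-weighted concordance
Σ<sub>c∈D∩C</sub>w<sub>c</sub> / Σ<sub>c∈D</sub>w<sub>c</sub>.

A seeded generator produces a linked synthetic dataset (registry cohort
plus the four claims streams) with piecewise-constant Poisson event
intensities by phase and planted ground truth, so the whole pipeline is
testable end to end.

## Worked example

```bash
phasecare run --seed 20110101 --out results/demo
```

or, stage by stage, the numbered drivers under `analysis/`. On the demo
profile (500 patients, 47-code illustrative D-list of which 10 codes
carry planted cancer-related excess, 20 null background codes) the
pipeline prints:

```
phase census on 2011-01-01:   INITIAL 68 (13.7%)  CONTINUING 409 (82.5%)
                              FINAL 19 (3.8%)     CENSORED 4
HD: 1651 events -> 571 attributed (258 non-cancer, 791 out of window, 31 censored)
HD: initial phase led by Chemotherapy (39.5% of 243 events)
DP: initial phase led by Hormone therapy (71.8% of 266 events)
surgery concentrates in the initial phase (94% of the per-patient rate)
self-control subcohort: 68 patients diagnosed in the last accrual year
C-list: 11 of 67 candidates included
concordance vs planted truth: weighted 1.000, unweighted 1.000
planted codes recovered: 10/10
```

Reading this: the census splits the prevalent cohort into the three
phases (the real pooled registry cohort splits 15.2/79.9/4.9%); the
attribution step accounts for every linked event (attributed +
non-cancer + out-of-window + censored = total); the frequency tables
show hormone therapy dominating initial-phase prescriptions and surgery
concentrated in the initial phase once phase cohort sizes are removed;
and the self-control validation recovers all ten planted cancer-related
codes with weighted concordance 1.0 against the planted truth (one null
code slips in, consistent with the 5% test level).

`analysis/06_published_tables.py` reproduces the published study tables
from their printed aggregate counts (every within-phase percent to one
decimal, and the phase-concentration figures 91/62/53/76/80%).

## Layout

* `src/phasecare/` — the library: `codelists`, `cohort`, `attribution`,
  `patterns`, `selfcontrol`, `simulate`, `reference`, `io`, `cli`.
* `analysis/` — numbered narrative drivers over the library.
* `tests/` — unit, property and end-to-end validation suites.
* `docs/methods.md` — modelling assumptions, parameter choices,
  numerical conventions and limitations.
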