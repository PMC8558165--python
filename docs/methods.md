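# Methods

## Phase assignment and observation windows

The design is cross-sectional on a prevalence date: each previously
diagnosed patient alive on that date belongs to exactly one phase of
care (initial / continuing / final), and contributes exactly one
12-month observation window. Although a woman traverses several phases
over her life, the prevalence-date snapshot makes the phases mutually
exclusive; no longitudinal person-time decomposition is attempted.

Conventions the source design leaves open, fixed here:

* **Half-open intervals everywhere.** "Diagnosed within 12 months
  before" means `prevalence−12m ≤ diagnosis < prevalence`; "dies within
  12 months after" means `prevalence ≤ death < prevalence+12m`; windows
  are `[start, end)`. This avoids double counting at boundaries.
* **Calendar-month arithmetic** (2010-06-15 + 12m = 2011-06-15, with
  month-end clamping), matching the "initial year"/"last year of life"
  phrasing rather than fixed 365-day offsets.
* **Censoring.** Non-cancer deaths in the follow-up year are censored
  and excluded from all tabulations: they belong to no phase and carry
  no window. The census reports them separately; phase shares are
  computed over the non-censored cohort. The pooled-study counts
  (7501/39,369/2400 of 49,270) give shares 15.2/79.9/4.9%, which the
  package reports exactly rather than any rounded published summary.
* **Incomplete dates.** Month-only registry dates are imputed to day 15
  deterministically.
* A patient dead before, or diagnosed on/after, the prevalence date is
  a contract violation (`NotPrevalentError`), not a silent drop —
  cohort construction is the caller's responsibility.

## Attribution

Codes are matched exactly after normalization (strip, uppercase, dots
removed from ICD-9-CM-style codes; ATC verbatim uppercase). Prefix
matching is off by default — the lists enumerate explicit codes, and
prefix semantics would silently widen them; an opt-in ATC prefix mode
exists for sensitivity analyses.

A hospital discharge is cancer-related if any of its ≤12 codes is
listed. For tabulation each discharge contributes **one** row (tables
count discharges, not codes) with the category of its first listed code
in slot order: procedures main→secondary, then diagnoses
main→secondary. Slot 0 is "main" in discharge-abstract semantics;
falling back to diagnosis codes when no procedure matches is the
package's documented choice, and a category-priority alternative
(Surgery > Chemotherapy > Radiotherapy > …) is available behind a
switch for sensitivity checks. Episodes are anchored to their admission
date for window membership. Outpatient and drug records are single-code
events contributing one row each. Hospital-pharmacy (HP) events are
flagged and exported but never tabulated — that stream's capture is
treated as qualitative only.

Attribution is conservative by construction: per stream,
`retained + non-cancer-related + out-of-window + censored = total`, and
the selection is invariant to event order.

## Patterns

Within-phase percents are computed at full precision over the phase
total (sub-categories too) and rounded **half away from zero** to one
decimal, the convention of the published tables; phase-concentration
shares are rounded to integers. Top-code rankings break ties
lexicographically, with percents over the cancer-related events of that
stream and phase. The outpatient blood-test and genetic-marker codes
stay on the list for attribution but are dropped from frequency tables
(`excluded_from_frequency`), where their one-record-per-test volume
would swamp the distribution.

The phase-weighted category distribution divides each phase's category
count by that phase's cohort size and normalizes the three rates to
100%. Among the readings admitted by the phrase "weighted by the
percent distribution of patients", this per-patient-rate normalization
is adopted because it reproduces all five published concentration
figures (surgery 91% initial; hospital radiotherapy 62%, chemotherapy
53% and diagnostics 76% final; outpatient radiotherapy 80% initial)
from the published counts and cohort sizes — the acceptance suite pins
this down.

## Self-control validation

Control window `[diagnosis−12m, diagnosis−2m)`, case window
`[diagnosis, diagnosis+10m)`: both 10 calendar months, with the 2
months before diagnosis discarded as pre-diagnostic work-up. Per-patient
counts (zeros included) are compared with the unequal-variance t-test;
the Welch–Satterthwaite degrees of freedom follow the standard formula
and two-sided p-values come from the t distribution. The counts are
treated as independent samples, mirroring the original analysis, even
though they are paired self-controls; a paired or count-model (Poisson)
variant is deliberately out of scope. No multiple-testing correction is
applied (inclusion is raw p < 0.05); the audit table carries all
p-values so corrections can be applied downstream.

Decisions on points the source leaves open (both config-exposed):

* **Directionality.** Inclusion additionally requires
  `mean_case > mean_control`, so codes *suppressed* after diagnosis are
  not admitted; under this rule a null code is included with
  probability ≈ α/2. The pure two-sided rule is available
  (`directional=False`).
* **Degenerate samples.** If both samples are constant the t statistic
  is undefined; p := 1 when the means are equal, p := 0 when they
  differ (deterministic separation). Samples of size < 2 yield an
  excluded-with-reason audit row.
* **Concordance weights** are case-window occurrence counts within the
  self-control subcohort (keeping the metric inside the validation
  design); whole-cohort weights can be supplied instead. D-list codes
  with zero occurrences carry zero weight, so they depress the
  unweighted but not the weighted ratio.

## Synthetic data

The generator emulates what the analysis assumes and nothing finer:
diagnosis dates uniform over an 8-year accrual window (2003–2010,
prevalence 2011-01-01), exponential post-diagnosis survival (mean 20
years, giving a realistic ≈4–5% final-phase share; deaths beyond
registry follow-up are recorded as alive), 20% of follow-up-year deaths
from non-cancer causes, and age at diagnosis ≈ N(62, 12²) truncated to
25–95. Events per patient and code follow a piecewise-constant Poisson
process: background intensity λ0 throughout the 2009–2011 data window
(non-cancer care, present pre-diagnosis) plus a phase-specific excess
after diagnosis — initial over the first 12 months, final over the last
12 months of life (taking precedence), continuing in between. Phase
boundaries finer than the 12-month windows would be unidentifiable to
the analysis, so smooth hazard shapes are deliberately not modelled.
Hospital events are packaged into episodes with the generating code in
a random slot of the appropriate kind and never-listed filler codes in
the others, so multi-code flagging is exercised non-trivially.

The demo profile has 500 patients and a 47-code illustrative D-list
spanning the clinical categories of the published tables (it is **not**
the original 202/250/60-code expert list). Ten codes carry planted
excess — each with initial-phase excess ≥ 0.5 events/patient-year, the
regime the validation properties are stated for — with phase profiles
qualitatively matching clinical expectation (surgery initial-dominant,
analgesics and cortisone final-dominant, hormone therapy
initial/continuing). Twenty null codes have identical pre/post
intensity, and several listed codes are simulated as never administered
or as background-only generic care, reproducing the known failure modes
of list validation. Absolute event volumes were chosen for statistical
recoverability at the demo sample size, not to mimic the published
tables' proportions. What passing tests show is therefore that the
*machinery* is correct under the assumed data-generating process;
real claims data add coding dialects, incomplete capture, comorbidity
confounding and non-Poisson clustering that the generator does not
emulate.

## Problem sizes and numerics

The test suite validates the Welch implementation against exact
rational arithmetic (1000 random count-vector pairs, agreement to
1e-8 in t and df) and against an independent Welch implementation for
p-values; type-I error is checked with 2000 null replicates at n = 50
(99% binomial band around 0.05); planted-code recovery runs on the full
500-patient demo profile. Percent computations round half away from
zero only at display time. All randomness flows from a single seed;
identical config + seed gives byte-identical output files.

## Known limitations

* Cost valuation (tariffs, euros) is out of scope — the package stops
  at patterns of occurrence.
* One code list serves all phases; age- or stage-differentiated lists
  are not supported.
* The published outpatient phase shares contain an internal
  inconsistency (the continuing share computes to 69.3% from the
  printed totals but is published as 70%); the package reports the
  exact arithmetic and the corresponding check documents the
  discrepancy rather than matching it.
* Probabilistic record linkage is not implemented; pseudonymous ids are
  exact-match keys.
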