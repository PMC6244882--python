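# Methods

## Scope and data model

The package analyses treatment pathways over a six-table subset of the OMOP
CDM v5: PERSON, OBSERVATION_PERIOD, CONDITION_OCCURRENCE, DRUG_EXPOSURE,
CONCEPT and a flat product→ingredient map (the only slice of the standardized
vocabulary hierarchy the analysis needs). Concept identifiers are treated as
opaque integers; no terminology mapping is performed. Simplifications relative
to full OMOP: one observation period per person (the eligibility logic never
needs more), and no visit, dose or quantity fields.

Dates are ISO-8601 calendar dates, durations are whole days, and intervals
are half-open `[start, end)` unless stated. These conventions make every
boundary testable to the day.

## Cohort eligibility

A patient enters a disease cohort when all of the following hold, evaluated
in this order (the attrition count of each stage is logged):

1. **Diagnosis** — at least one condition occurrence in the disease's
   diagnosis concept set, at any date in the record.
2. **Exclusion** — no condition occurrence in the exclusion set, *at any
   date*, pre- or post-index. Any-time exclusion is the stricter and more
   reproducible reading of "patients meeting exclusion criteria were
   removed"; a pre-index-only variant would require choosing an undefined
   window.
3. **Index date** — the earliest exposure to a *disease-targeted* drug, with
   compound products decomposed first (so a combination pill containing a
   target ingredient can set the index). Requiring a target drug rather than
   any drug follows the intent of "continuous treatment with some medication
   targeted to the disease"; both readings are representable by widening the
   target set.
4. **Prior history (washout)** — the observation period starts at least
   `min_history_days` (default 183 ≙ 6 months) before the index date,
   inclusive: exactly 183 days qualifies.
5. **Continuous treatment** — target-drug exposures are merged into *drug
   eras*, bridging gaps of at most `max_gap_days` (default 120, the OHDSI
   persistence-window convention; "continuous" is otherwise undefined), and
   the era containing the index date must extend at least
   `min_treatment_days` (default 365 ≙ 1 year) past it.

All three thresholds are plain integer-day parameters
(`EligibilityParams`), overridable from the CLI.

## Pathway extraction

Exposures are decomposed to ingredient level (duplicate person/ingredient/date
rows collapsed), restricted to the disease's target drugs, and clipped to
on-or-after the index date. Each ingredient is placed at its *first* exposure
date; dates are sorted and ties grouped into combination rounds. Dose changes
and repeat prescriptions of an already-seen ingredient never open a new round
— pathway identity is ingredient-level only. The observation window runs to
the end of the record rather than stopping at one year, matching the "until no
new drug appears" rule.

Extraction stops at a cap of 20 distinct medications. If a combination round
would cross the cap, the round is truncated keeping its lowest concept ids,
then extraction stops; this is the deterministic tie-break that guarantees no
pathway ever exceeds the cap while leaving sub-cap pathways untouched by any
cap increase.

Canonical notation: rounds joined by `>`, within-round ingredients sorted by
concept id and joined by `+` (`"1+2>3"`). Aggregation counts patients per
canonical pathway, sorted by count descending then key ascending, so outputs
are diffable. The *uniqueness proportion* is the fraction of patients whose
pathway has count 1.

## Consistency indexes and trends

For the most common first drug `d*` (argmax over first-round membership
counts, ties to the smaller concept id):

- **Monotherapy**: pathways of exactly one round with one ingredient. A
  day-one combination is not monotherapy.
- **Common monotherapy**: pathway exactly `[[d*]]`. Two denominators exist:
  the whole cohort and the monotherapy patients. The static index defaults to
  the whole cohort (the written definition); the yearly trend defaults to
  that year's monotherapy patients — the only denominator under which a
  cohort-wide monotherapy share and a much larger most-common-monotherapy
  share are mutually consistent. Every output row carries a
  `common_mono_denominator` flag; nothing is guessed silently.
- **First line**: `d*` is a member of the first round (sole occupancy not
  required, matching the sunburst's inner-ring semantics).

For trends, patients are grouped by index year, `d*` is computed once from
the whole cohort and held fixed across years, and empty years are omitted.
The patient-weighted mean of the yearly monotherapy proportions equals the
static proportion by construction (asserted to 1e-12 in tests).

## Synthetic data generator

The generator emulates the population a single-hospital pathway study draws
on: per-patient diagnosis records, drug exposures realizing configured
pathway templates, observation histories, and planted eligibility violations.
Study conditions are set by `GeneratorConfig`; the defaults are index years
2005–2015 (an eleven-year window typical of such studies) and history lengths
uniform on 183–1460 days. Timing distributions are uniform because nothing
about real visit timing is being modelled — uniform is the least-assumptive
choice that still exercises every window boundary.

Per template, round *r* starts `inter_round_gap_days` (default 90) after
round *r−1* and each exposure spans `exposure_span_days` (default 60); the
final round is stretched to a uniform 366–499 days past index so
template-labelled patients always satisfy treatment continuity. A config
whose round gaps exceed the persistence window is rejected as infeasible
rather than silently producing ineligible "eligible" patients. Multi-
ingredient rounds are optionally emitted as a single compound-product
exposure (probability `compound_product_prob`) whose map entry expands to the
round's ingredient set, exercising the decomposition rule end to end.

Noise classes each break exactly one predicate: `short_history` draws a
0–182-day history; `early_dropout` truncates exposures at a uniform 30–300
days post index (violating the 365-day rule deterministically, since
300 < 365); `excluded_dx` adds an exclusion-concept condition to an otherwise
eligible patient. Labels partition the population; the ground-truth table
(person, label, intended index date, intended pathway) is the answer key the
test suite checks cohort construction and extraction against.

Randomness is one splittable stream: each person's draws come from a
generator seeded with `(seed, person_id)`, so output is byte-identical for a
given config and seed and independent of generation order.

### What passing tests do and do not show

The generator plants discrete template mixes, so recovery tests demonstrate
correctness of the *machinery* (eligibility logic, decomposition, round
building, counting), not realism of the data. In particular, real pathway
data has a long tail of patient-specific sequences that makes the uniqueness
statistic large; under a finite template mix uniqueness is bounded by the
share of templates realized exactly once and is typically ~0 at realistic
cohort sizes (the acceptance script reports it as computed). Comorbidity,
dosing, visit structure and mid-era switching variability are not modelled.

## Numerical and degenerate-input choices

- Empty summaries are errors for every ratio (no silent NaN); an empty
  monotherapy denominator yields 0 for the common-monotherapy trend value.
- All ties are broken deterministically: smaller concept id for the
  most-common drug, key-ascending for equal pathway counts, name-ascending
  for equal sunburst wedge sizes.
- Validation reports violations as data (table, row, rule), one per offending
  row, rather than raising on the first defect.
- The sunburst adds no placeholder nodes for patients whose pathway ends
  before the display depth (default 3 rings); conservation — leaf sizes
  summing to the cohort size at every depth — therefore holds exactly.

## Problem sizes

The bundled checks run the full pipeline at cohort sizes up to 5000 patients
(distribution recovery at 3 binomial standard errors), 1000 patients with
30% planted noise (exact answer-key equality), 200 randomized mini-patients
against a brute-force reference, and 100 randomized small configurations for
the conservation properties — sizes at which every statistical tolerance is
meaningful while the whole suite stays interactive.

## Known limitations

- One observation period per person; multi-period records must be merged
  upstream.
- No death or disenrollment censoring: a patient who dies mid-year simply
  fails the continuity filter, as in the underlying protocol.
- Exclusion timing and index-drug scope are config choices, not inferred
  from data.
- The era-based "combination" concept is tie-by-first-date only; overlapping
  eras started on different days are sequential rounds, not combinations.
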