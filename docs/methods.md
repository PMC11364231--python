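# Methods

This note documents the models, conventions and design choices behind the
package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Out-of-pocket costing

Each encounter's OOP expense is the sum of six components — consultations,
procedures, imaging, stay, consumables, death expenses — resolved against
an itemized fee schedule (`code,category,unit_cost_tzs,modality,variant,ward`).
Conventions:

* Every encounter is charged exactly one emergency-physician consultation
  (`consult_em`), whether or not it appears in the service list; further
  consults are billed per recorded visit (the alternative — billing
  same-day repeat consults once — is not modeled, as registries rarely
  distinguish them).
* A surgical procedure is one procedural fee per recorded operation;
  anesthesia and theatre consumables are not itemized separately.
* Imaging substitution: an MRI or ultrasound of unknown subtype is charged
  the arithmetic mean over all schedule items of that modality; a scan of
  unknown laterality the mean of the unilateral and bilateral prices. A
  substituted price therefore always lies within the [min, max] of the
  candidates it averages. `unknown` is an explicit marker in the service
  file, distinct from an empty (not-applicable) field.
* Stay is costed as `days_general × basic shared-ward rate +
  days_icu × ICU rate`; when a ward lists several rates the cheapest is
  taken as the basic accommodation.
* In-hospital deaths add the death certificate, morgue transport and body
  bag.
* All amounts are citizen rates, pre-insurance-reimbursement (registries
  typically lack the job-classification fields that determine NHIF
  reimbursement tiers), kept as exact TZS; USD conversion (default 2,339
  TZS/USD) happens only at report time, rounded to the nearest dollar for
  headline figures and 2 decimals elsewhere.

The bundled `data/default_fee_schedule.csv` contains **synthetic**
placeholder prices so the package is runnable and testable self-contained;
real analyses must supply the hospital's actual price list.

## CHE and IMP classification

* **Comparison operator.** Flags use `OOP >= x·Y` (a strict `>` is
  available via configuration). The boundary case therefore counts as
  catastrophic.
* **Subsistence expenditure.** Households are ranked by annual total
  expenditure (stable sort, ties in input order); the percentile rank of
  the i-th of n is `100·(i − 0.5)/n` and the closed window [45, 55]
  selects the middle-consumption households, whose mean annual food
  spending is SE. If the window is empty (tiny cohorts) the household
  nearest the median is used, so SE is defined for any non-empty cohort.
  SE is a per-household amount by default; a per-adult-equivalent option
  exists but is off. Ranking uses household TE, not per-capita TE.
* **Zero capacity to pay.** When `SE > TE`, NSE floors at 0; the 40%-of-NSE
  rule then flags any positive OOP but never a zero-cost patient.
* **Time normalization.** Income is annual; the monthly national line is
  ×12 and the daily international lines ×365 (and × the TZS/USD rate)
  before comparison.
* **IMP definition.** A patient is impoverished whenever post-OOP
  per-adult-equivalent income is below a line, regardless of pre-OOP
  status; a `newly_poor` mode (pre-OOP at or above the line, post-OOP
  below) is available but off by default.
* **Equivalence scale.** OECD-modified weights 1 / 0.5 / 0.3, child = under
  14.
* **Missing income.** Patients without income data get null IMP flags: they
  are excluded from IMP strata in tables but retained in the cohort, and
  the metrics file reports the any-IMP prevalence under both the full and
  the eligible denominator.

## Synthetic cohort generator

The generator emulates the reference sample's published marginals; it is a
test harness for the pipeline, not a fitted model of the registry.

* **Income**: monthly per-adult-equivalent income is lognormal with median
  98,387 TZS; the dispersion is solved in closed form from the published
  IQR of 136,842 TZS via `IQR/median = 2·sinh(z₇₅·σ)` (σ ≈ 0.96). Annual
  household income = monthly per-AE income × 12 × H_a. About 2.6% of
  respondents decline to report income.
* **Expenditure**: TE = annual income × a lognormal factor (log-median
  0.85, σ = 0.30 — expenditure tracks income in a cash-constrained
  setting); the food share of TE is Beta(9, 11) (mean 0.45, a plausible
  Engel share for the setting; the source reports no food-share data).
* **Composition**: the dependents bracket (0–2 / 3–5 / 6+ at
  47.4/37.2/15.4%) fixes the dependent count; 60% of dependents are
  children (<14), the rest dependent adults; a spouse is present with
  probability 0.6. Only the brackets are calibrated — the full
  household-size joint distribution is unreported.
* **Encounters and services**: hospitalization (80.8%), surgery (48.7%)
  and death (2.6%) are drawn at the published rates; stay lengths, imaging
  and consumable counts rise with hospitalization and surgery, which also
  drags facility-transfer counts upward — inducing the observed
  surgery–financial-toxicity association. Its magnitude is a free
  generator parameter, not an empirical claim. Service intensities and the
  bundled schedule's prices were calibrated once so the default-condition
  median itemized OOP sits near the published 476,793 TZS (observed within
  roughly ±7% across seeds at n = 2,000).
* **Probability simplexes** built from published rounded percentages (e.g.
  66.7/16.7/10.3/6.4 sums to 100.1) are accepted within 5·10⁻³ and
  renormalized exactly at draw time.
* **Target construction** (`target_any_che`): after costing, every
  patient's minimal CHE trigger `min(0.10·TE, 0.25·TE, 0.40·NSE)` is
  computed; the `round(target·n)` patients closest to (or past) their
  trigger are made positive by scaling all six cost components by one
  factor up to the trigger (with a 10⁻⁹ relative margin against float
  rounding), and the rest negative by scaling down to 90% of it. Scaling
  every component equally preserves additivity exactly. In this mode the
  rescaled costs table is the canonical OOP input and the emitted labels
  are the classifier's own output on it; the unscaled service list no
  longer re-costs to the same totals, so the flat-enumeration equivalence
  applies to the default mode only.

What passing tests on these cohorts do **not** show: fidelity to the real
registry's joint distributions (income–mechanism, age–surgery, ...), to the
real fee schedule, or to real reporting behavior (item-level missingness is
limited to imaging variants and a fixed income-refusal rate).

## Descriptive analysis

* Tables report `% (n)` with the full stratum size (unknown responses
  included) as denominator, and median [IQR] (linear-interpolation
  quantiles) for continuous rows; percentages 1 dp, ratios 2 dp.
* Strata overlap by construction: each per-threshold CHE stratum is a
  subset of "any CHE"; p-values are computed only for the any-vs-none
  split, which is the only independent comparison.
* Continuous rows are compared with Welch's t-test (one-way ANOVA for
  k > 2 groups); categorical rows with a chi-square test of independence
  rather than a t-test, which is not defined for them — the method used is
  recorded per row. No multiple-testing correction is applied.
* The Three-Delays summary reports, per stratum: facility-transfer counts
  (Delay 2), the partial set of decision-to-seek-care factors available in
  the registry fields (cost concern, low perceived severity, lack of
  agency — Delay 1), the time-to-care distribution over the ordinals
  minutes / hours / longer (Delay 3), and the median-OOP ratio between
  toxic and non-toxic strata. Empty strata render with n = 0.

## Numerical conventions and degenerate inputs

* TZS amounts are floats summed exactly; component additivity is asserted
  to 10⁻⁶ TZS.
* Duplicate fee codes, negative costs, missing schedule columns, negative
  stay days and mismatched patient identifiers raise typed errors
  (`SchemaError`, `ValidationError`, `UnresolvableItemError`, `JoinError`)
  naming the offending record; the CLI maps validation errors to exit
  code 1 and other failures to 2.
* A single-household cohort yields SE = its own food spending; an empty
  cohort is a validation error.
* `metrics.json` is written with sorted keys, so identical inputs and seed
  give a byte-identical file.

## Problem sizes

The test suite and acceptance script use cohorts of 50–400 patients for
unit and property checks and 2,000 for marginal-fidelity and
prevalence-recovery checks, with 1,000 replicates for the Welch
nominal-rate check — sizes at which binomial 3·SE bounds are tight enough
to detect real generator miscalibration.
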