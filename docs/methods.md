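# Methods

## Exposure model

The package quantifies antipsychotic drug exposure from dispensing claims as
a total chlorpromazine-equivalent daily dose (mg CPZ/day). For a claim with
strength `s` (mg per dispensed unit), quantity `q` (units) and day's supply
`d` (days), the daily dose is `s*q/d`: the dispensed drug mass spread evenly
over the supply period. This is the standard claims construction and is the
package's own choice — it is applied uniformly to oral, short-acting and
long-acting injectable claims, which makes depot doses commensurable with
daily oral dosing. The daily dose is multiplied by a potency-based
conversion factor `cpz_factor(drug, formulation)` — mg of chlorpromazine
pharmacologically comparable to 1 mg of the drug — and the equivalents of
all eligible claims at a timepoint are summed regardless of drug or route.

Adherence is deliberately not modelled: the measure is dispensed, not
consumed, drug. Equivalence factors capture a single mechanism (dopamine
antagonism); no adjustment is made for other receptor activity.

### Equivalence and interval tables

The bundled tables are **reconstructions** from the potency-equivalence
literature (minimum-effective-dose studies for the older agents, consensus
values for the rest): e.g. 2 mg risperidone ~ 100 mg chlorpromazine gives
`cpz_factor = 50`. Long-acting factors are scaled so typical depot regimens
land in a plausible 100–150 mg CPZ/day range. Both tables are plain CSV and
fully user-replaceable (`read_equivalence_table`, `read_intervals_table`);
the only hard requirement is the identity entry (chlorpromazine, immediate)
= 1.0. Users with jurisdiction-specific validated tables should substitute
them.

## Cleaning rules

Cleaning writes only the `cleaned_quantity` / `cleaned_days_supply` fields;
raw fields are immutable, and a modified flag is set exactly when the
cleaned value differs from the raw value. This makes `clean_all` idempotent
(a second run reports zero modifications), which the test suite asserts.

* **Oral/rectal**: if the next fill of the same drug (canonical lower-case
  token, same formulation, any strength) is dispensed within
  `next_fill_window_days` (default 100, *inclusive*), the recorded day's
  supply is kept; otherwise it is replaced by
  `round_half_up(quantity / oral_fallback_divisor)` floored at 1 day
  (divisor default 5). "Next" means a strictly later dispense date;
  same-day duplicates are concurrent prescriptions, not refills.
* **Long-acting injectable**: with minimum interval `m` and gap `g` to the
  next long-acting claim of *any* depot drug — keep when `days_supply > m`;
  set to `m` when there is no subsequent depot claim; set to `g` when
  `g < m`; and set to `m` in the remaining case (`days_supply <= m`,
  `g >= m`), which the three-branch rule wording leaves open and which we
  fill with the minimum-interval semantics.
* **Short-acting injectable**: when both unit cost (per mL) and total
  billed cost are present and `|q*unit - total|/total` exceeds
  `cost_mismatch_tolerance` (default 5%, so consistent rows are not churned
  by rounding noise), the quantity is repaired to `total/unit` rounded to 2
  decimals; the oral day's-supply rule then runs on the repaired quantity.
  Missing costs leave the quantity untouched.

Degenerate inputs: the fallback never produces a day's supply below 1; the
repair never fires on zero or missing costs; unsorted per-patient input is a
contract error rather than a silent misanswer.

## Cohort

Entry is the patient's **first-ever** antipsychotic claim, required to fall
inside the accrual window (defaults 2009-01-01..2012-12-31). A patient whose
first claim precedes the window is not a new user within it and is logged as
`prior_use`; the explicit washout check (no dispensing in the
`washout_days=365` before entry) is also applied. Exclusions are evaluated
in a fixed order — `no_dementia`, `under_age`, `prior_use`,
`no_subsequent_rx` — so each excluded candidate carries exactly one reason;
the order affects only the log, never membership. Age is completed years at
entry (minimum 66, which in the motivating setting guarantees a year of
observable drug history). Follow-up ends at death or `followup_days=365`,
whichever comes first. The dementia indicator is consumed as a boolean input
flag; the diagnostic case definition that produces it is out of scope.

A patient "remains on therapy" at a timepoint when follow-up reaches it and
at least one eligible claim covers it — a coverage definition, not a
grace-period persistence definition; the distinction matters only for how
the active-at-timepoint counts are read.

## Timepoints and eligibility

Assessments default to days 0, 182 and 365 (initiation, month 6, month 12;
month lengths are never used — all arithmetic is in exact days). At
initiation only claims dispensed on the entry date contribute (a new user
has no earlier supply that could cover day 0). At later timepoints `t` a
claim contributes iff it was dispensed in the half-open lookback window
`(t-100, t]` *and* covers `t` under the half-open supply interval
`[dispense, dispense+ds)`: a claim dispensed on day `t` with one day of
supply covers it; a claim whose supply ends exactly at `t` does not. The
half-open conventions avoid double counting at boundaries and are
configurable interpretation points, stated here because the underlying rule
wording does not fix them.

Totals are computed twice — raw fields and cleaned fields, with eligibility
re-derived under each — and a patient-timepoint counts as "modified by
cleaning" when the totals differ by more than `dose_change_tolerance_mg`
(1e-9 mg): field changes that cancel in the total do not count. Route
strata are oral (rectal folds in), regular injectable, long-acting
injectable, and multiple when the cleaned eligible claims span more than one
category.

## Summaries

Quartiles use type-7 linear interpolation (the numpy default) everywhere.
Box-plot data report Q1/median/Q3 with whiskers at the most extreme
observations within 1.5 x IQR of the quartiles and everything beyond listed
as outliers, for raw and cleaned totals side by side. Concurrency counts
**distinct drugs** (not distinct claims) among a patient's contributing
claims at a timepoint. Empty strata are absent, never zero. Percentages are
rounded to one decimal only in written files.

## Synthetic generator

`generate(GeneratorConfig(...))` draws, per patient: an administration-route
class (published shares 97 / 2 / 1 / 0.5% for oral / regular injectable /
multiple / long-acting, normalised internally because the rounded shares sum
to 100.5%), an atypical-vs-typical initial drug (81% atypical), death under
a constant hazard calibrated to 20% one-year mortality, a uniformly drawn
entry date, and flags exercising each cohort exclusion (5% under 66, 8%
without dementia, 5% with pre-window dispensing, 3% single-fill).
Refills follow the true day's supply with small jitter and a geometric
per-refill discontinuation probability of 0.06 (about 48% of oral patients
still on therapy at month 12, with mortality on top); 5% of oral gaps
exceed the 100-day window so both branches of the refill rule occur in
truthful data. Concurrency (total probability 0.14 of >= 2 drugs at
initiation) is implemented as a second, different drug dispensed once on the
entry date; multiple-route patients are concurrent by construction, so
single-route patients draw a correspondingly rescaled probability. Second
drugs do not refill, which keeps cohort retention identical for concurrent
and non-concurrent patients.

Errors are injected at the patient level with the published per-route
shares (3 / 16 / 36 / 42%), one archetype-appropriate claim on the entry
date: depot claims get `ds_one_day_injection` (day's supply 1), short-acting
injectables get `quantity_cost_mismatch` (quantity 1 with truthful costs),
oral claims get `ds_too_short` (1–7 days against a true 30/90), with the
next same-drug refill scheduled beyond 100 days so the fallback rule can
act — the keep branch cannot repair a day's-supply error. Ground truth
records every true value and every flip.

**Idealisations, and what passing tests do and do not show.** Truthful
regimens are constructed to be fixed points of the cleaning rules: oral and
short-acting claims dispense exactly 5 units per supply day, so the
conservative `quantity/5` fallback reproduces the true day's supply, and
depot regimens use the minimum dosing interval as the true supply with
injection gaps at or above it. This makes recovery exact — cleaned doses
equal ground truth for 100% of injected injectable errors — and makes the
zero-error limit report zero modifications, so every flagged modification is
attributable to an injected error. Real data are messier: true regimens
need not satisfy the cleaner's assumptions, so the fallback can *introduce*
error in claims whose supply is genuinely longer than quantity/5, costs can
be missing or wrong, and error modes beyond the three archetypes (which
extrapolate from one documented depot-billing anecdote) exist. Passing
tests therefore demonstrate that the rules are implemented exactly as
specified and recover the error modes they were designed for — not that
they are unbiased on any particular real population. The generator also
makes no attempt to reproduce real-cohort magnitudes (cohort size, exact
medians, Ontario costs or prevalence).

## Problem sizes and numerics

The test suite and acceptance script use synthetic cohorts of 50–5,000
patients (about 13,000 claims at n=2,000); these sizes give 3-standard-error
binomial bands of a few tenths of a percent on the oral shares while the
whole suite runs in seconds. Dose comparisons use an absolute tolerance of
1e-9 mg; monetary repair is rounded to cents; day's-supply rounding is
half-up. All randomness flows from a single integer seed through
`numpy.random.default_rng`; two runs with the same seed produce
byte-identical CSV outputs, which the determinism test asserts via SHA-256
digests.

## Known limitations

* Single-ingredient products only; combination strengths are out of scope.
* No imputation of missing strength; unmapped drugs raise an error listing
  every offender rather than silently dropping exposure.
* The bundled equivalence values are reconstructions, not a validated
  jurisdictional table.
* The coverage-based persistence definition, the half-open boundary
  conventions and the initiation same-day rule are documented
  interpretation choices; all are configurable or clearly isolated.
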