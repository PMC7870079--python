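# Methods

This note documents the data model, the derivation and selection rules,
the statistical stages, the synthetic-data generator, and the numerical
conventions — including the places where a design choice was genuinely
open and what we chose.

## Claims data model

A bundle is six delimited tables: patients (sex, birth year, hospital,
per-patient `data_end`), hospitals (bed-size class, designated cancer
hospital), confirmed-diagnosis events (ICD-10), prescription events
(drug, date, optional dose and days supplied, route), procedure events
(colorectal resection, qualitative/quantitative proteinuria tests), and
assessments (BMI; the 10-item Barthel ADL index stored as a
semicolon-separated item vector, total 0–100). Dates are ISO-8601
calendar dates and all interval arithmetic is in integer days, because
every rule below is a day-count rule. `data_end` is stored per patient
rather than inferred from the last claim: the 60-day completion rule
needs the hospital's data-availability horizon, not the last event.
Diagnoses flagged unconfirmed are kept on disk but ignored by all
selection logic. Validation is total — malformed rows (bad ICD-10
pattern, non-positive dose, out-of-range BMI or Barthel items, foreign-key
violations, events after `data_end`) are rejected with specific errors;
only rows with unparseable dates are dropped, and then counted.

## Drug vocabulary and regimen naming

The vocabulary covers the drugs recommended for systemic CRC therapy in
the Japanese guidelines — oral and intravenous fluoropyrimidines
(capecitabine, 5-FU, S-1, UFT), oxaliplatin, irinotecan, FTD/TPI, the
three antiangiogenic antibodies, the two anti-EGFR antibodies,
pembrolizumab and regorafenib — plus leucovorin and the concomitant
classes the covariate stage needs. Exactly the five monoclonal antibodies
are `is_biologic`; pembrolizumab and regorafenib are antitumor but do not
participate in the biologic-addition rule. Leucovorin is a modulator:
displayed inside regimen names, never a trigger for line starts or ends,
and never a contributor to the exposure clock.

Backbones are determined solely by the set of non-biologic antitumor
drugs ({5-FU, oxaliplatin} → FOLFOX, {capecitabine, oxaliplatin} → CAPOX,
{5-FU, irinotecan} → FOLFIRI, {5-FU, oxaliplatin, irinotecan} →
FOLFOXIRI, {S-1, oxaliplatin} → SOX, {S-1, irinotecan} → IRIS, named
monotherapies, otherwise OTHER with the raw set retained). Leucovorin
presence is therefore not required for the FOLF- names; in practice
infusional 5-FU always travels with it. Multiple biologics in one window
are retained and flagged (`multi_biologic`), not rejected — claims noise
exists and downstream rules need a deterministic treatment of it.

Default cycle lengths (used for expected final dose dates when
`days_supplied` is absent): 14 days for the infusional/antibody backbone
(5-FU, leucovorin, oxaliplatin, irinotecan, and all five antibodies),
21 days for S-1 and FTD/TPI cycles, 28 days as the generic oral fallback
(capecitabine, UFT, regorafenib). The 14-day default encodes the
expected biweekly antiangiogenic schedule that the ≥21-day-gap metric is
defined against.

## Line derivation

Within one patient, prescriptions of antitumor drugs (plus leucovorin)
on or after the anchor date are grouped by calendar date and scanned
once:

* the regimen is assembled from the closed window
  `[start, start + 27]`;
* the *exposure clock* is the running maximum expected-final-dose date
  over the line's antitumor prescriptions. The 180-day gap is measured
  from this covered end, not from the last prescription date — a choice
  we document rather than inherit, since "discontinuation" concerns
  exposure and oral supplies outlast their prescription date. A line cut
  by the gap rule ends at the covered end (`gap_180`);
* a date group containing an antitumor drug outside the current regimen
  ends the line at that date (`new_drug`, half-open interval — the
  boundary prescription opens the next line, so lines partition the
  prescriptions and durations are `end − start` days);
* the biologic-addition exception is deliberately narrow: it applies
  only to lines ≥2, only when every new drug in the group is a biologic,
  and only when the current regimen contains none. A biologic arriving
  together with new chemotherapy, or into a regimen that already has a
  biologic (including an earlier addition), starts a new line;
* if neither rule fires the line ends at
  `min(running covered end, data_end)` (`data_end`). We use the running
  maximum covered end here as well, for consistency with the gap clock,
  rather than the literal last prescription's cover; the two differ only
  when an early long oral supply outlasts the final prescription.

A restart of the identical drug set after a ≥180-day gap is a new line:
the gap rule is stated unconditionally, and the derived line records let
a sensitivity analysis re-merge such pairs if desired.

Line numbering is 1, 2, 3, … for the first-line population and
adjuvant (0), 2, 3, … for the early recurrence population, whose first
post-adjuvant line is second-line therapy by construction.

Completion/evaluability: `evaluable_for_transition` = a next line exists
or strictly more than 60 days of data follow the line's end;
`completed` = at least 60 days separate the expected final dose date from
`data_end`. The asymmetry ("more than" vs "or greater") is intentional
and boundary-tested.

## Cohort selection

Shared first step: earliest confirmed C18–C20 diagnosis in the diagnosis
window (defaults: 2014-05-01..2019-07-31). All windows are closed
intervals in days (91 days ≈ 3 months, 183 ≈ 6 months, 365 ≈ 1 year);
month-based statements are frozen to these day counts so that boundaries
are testable. Age is computed from birth year with July 1 as the assumed
birthday — claims carry only birth year, and a fixed convention keeps the
age-20/age-70 boundaries deterministic.

Early recurrence eligibility is evaluated first (resection after
diagnosis; adjuvant drug ≤91 days after surgery; no antibody before the
resection or within 91 days of chemotherapy start; a derived second line
starting ≤183 days after the adjuvant covered end), because the
first-line population excludes anyone eligible for it. The 183-day
switch window is measured from the adjuvant line's expected final dose
date: in a prescription database the "last dose" is best proxied by the
covered end, consistent with the censoring rule. The first-line
population then requires the antibody anchor, age ≥20 at it, the 365-day
washout (days −365..−1), no prescription of antitumor drugs outside the
configured guideline list, and therapy start on/after the enrollment
start (2016-05-01). Every criterion's survivor count is recorded in a
monotone selection log. Antibody monotherapy anchors are allowed.

Presumed RAS status: wild type iff any anti-EGFR prescription falls in
the analysis window — a prescription proxy, with the misclassification
caveat that implies. The FOLFIRI + antiangiogenic subpopulation requires
the second line's initial 28-day regimen to have a FOLFIRI backbone and
at least one antiangiogenic drug in that window; the attributed drug is
the earliest-prescribed one, with same-day ties broken by the fixed order
bevacizumab < ramucirumab < aflibercept beta, and multi-antiangiogenic
windows flagged.

## Metrics

Percentages are rounded half-up to one decimal (decimal arithmetic, not
binary `round`), matching the reporting convention of the tables this
package reproduces; a rate with zero evaluable patients is reported as
absent, never 0. Transition rates stratify by population × presumed RAS
and omit the adjuvant→second step for the early recurrence population
(100% by construction). Sequence tables count regimen labels per line;
flow tables aggregate from→to regimen groups (oxaliplatin-based,
irinotecan-based, a combined group for regimens containing both,
fluoropyrimidine monotherapy, other).

Second-line antiangiogenic metrics, computed over the evaluable subset:
prescription counts (median, IQR), any ≥21-day gap between consecutive
antiangiogenic prescription dates (prescription dates, not covered ends —
the gap is defined against the biweekly schedule), dose reduction = any
prescription dosed strictly below the immediately preceding prescription
of the same drug (claims carry no planned dose, so consecutive
comparison is the only available definition), and single use = exactly
one antiangiogenic prescription in the line. Duration records run from
the first second-line prescription to the last antiangiogenic expected
final dose date, with the 60-day rule deciding event vs censoring.
Months are days / 30.4375.

## Statistical stages

* **Kaplan–Meier**: lifelines' product-limit estimator; median CI by the
  log-log transform (lifelines' default); restricted mean computed as the
  area under the step function up to the largest observation with the
  standard risk-set variance, flagged as underestimated when the largest
  observation is censored.
* **Logistic** (single prescription vs ≥2, coded so OR > 1 means higher
  odds of stopping after one): statsmodels maximum likelihood, Wald 95%
  CIs. Separation or non-convergence raises a `ModelError` — never a
  silent fit.
* **Cox** (overall duration from second-line start to the end of all
  antitumor therapy): lifelines `CoxPHFitter` with Efron tie handling —
  day-granularity data is heavily tied and Efron is the less-biased
  standard choice. Wald intervals for both models; no multiple-testing
  adjustment, matching the exploratory framing of the analysis.

Baseline covariates derive only from events in `[index − 365, index]`
(index = second-line start); concomitant covariates only from events in
the second line's half-open interval. Sidedness comes from any confirmed
diagnosis code (right: C18.0–C18.4; left: C18.5–C18.7, C19, C20; both may
be true, neither for C18.8/C18.9); ADL independent means a Barthel total
of exactly 100; BMI ≤18.5 uses the latest baseline assessment. Rows with
missing BMI or ADL are excluded complete-case with the exclusion count
reported, never imputed.

## Synthetic claims generator

The generator emulates the statistical structure the analyses assume and
emits only what a real extract would contain: dated claims. The line
structure is latent bookkeeping, which makes the derivation algorithm the
thing under test. Defaults follow the study conditions: enrollment
2016-05..2019-07, ~9% early recurrence, ~27% presumed RAS wild type, an
antiangiogenic mix of roughly 53/35/12 (bevacizumab/ramucirumab/
aflibercept beta), first-line menus dominated by FOLFOX/CAPOX plus an
antibody, second lines dominated by FOLFIRI, per-line transition
probabilities around 0.45–0.63, a gamma first-line duration with median
near half a year, ~12% dose-reduction and ~10–12% single-prescription
rates, ~10% missingness for BMI and ADL, and hazard effects shaped like
the published hazard ratios (e.g. 1.31 for BMI ≤18.5, 0.64 for presumed
wild type).

Mechanics worth knowing:

* all of a regimen's drugs are prescribed together on the line's cycle
  grid (cycle = the regimen's longest drug cycle); oral drugs carry
  `days_supplied` equal to that cycle. Optional noise adds ±2-day jitter
  and occasional 7–14-day cycle delays (which create the ≥21-day gaps);
  the ground truth is bookkept from the *emitted* dates, so recovery is
  exact even under noise;
* overall duration from second-line start is drawn from an exponential
  proportional-hazards model with configurable per-covariate log hazard
  ratios, then partitioned into line spans and between-line gaps inside
  that total, so the hazard structure survives the discretisation;
* the single-prescription outcome is drawn from a logistic model with
  configurable effects; multi-prescription users are guaranteed at least
  two cycles so the observed outcome equals the latent one;
* `data_end` is the last event plus an exponential lag (mean 300 days),
  which produces realistic censoring and evaluability mixes;
* a configurable share of patients are decoys violating exactly one
  selection criterion (washout, age, non-guideline drug, enrollment
  date, diagnosis code, unconfirmed diagnosis, adjuvant without
  recurrence, therapy without biologics), so selection is tested against
  patients that *should not* be found;
* a fixed rounded share of hospitals is designated-cancer (74%), keeping
  that covariate non-degenerate at any scale;
* everything is driven by one seeded generator in fixed order: identical
  config + seed ⇒ byte-identical bundles.

What the generator does not emulate: real Japanese billing-code
distributions, costs, hospital case-mix realism, multi-hospital patient
fragmentation, or diagnosis noise beyond the decoy mechanism. Passing
recovery tests therefore shows the rules are implemented exactly as
stated, not that the rules correctly segment real-world prescribing.

## Validation experiments and problem sizes

The test suite and the acceptance script share the same experiment code:
exact recovery of populations, full line sequences and subpopulation
attribution on 200-patient bundles (noise-free, and with schedule noise);
Kaplan–Meier agreement with a brute-force product-limit oracle on ≤50
record fixtures; Cox effect recovery (true log HR ln 1.5 on BMI ≤18.5,
20 replicates at 2,000 patients, coverage of ±0.15 on the log scale);
logistic effect recovery (true OR 2.0 on age ≥70, 20 replicates at 2,200
patients so the evaluable model n is ≈2,000, coverage of [1.6, 2.5]);
null calibration (40 replicates at 500 patients, pooled share of
covariate p-values below 0.05 compared against 10%); and byte-level
determinism of the whole pipeline. Replicate counts and cohort sizes are
the experiment's design; recovery configurations route every patient to
a FOLFIRI + antiangiogenic second line and switch missingness off so the
estimation error of the effect itself is isolated. At ~2,000 evaluable
patients and a ~12% single-use rate the logistic log-OR has a Wald SE
near 0.13, so individual replicates land outside [1.6, 2.5] roughly one
time in ten even under a correct implementation — the logistic coverage
check is the least powered of the suite and its seed-to-seed variability
is expected, not a defect signal.

## Known limitations

* The rule set is one defensible reading of day-count rules whose
  boundary conventions (closed windows, covered-end gap clock,
  same-drug restart) are documented choices, not ground truth.
* Presumed RAS status misclassifies wild-type patients who never receive
  an anti-EGFR antibody.
* Dose reduction compares consecutive prescriptions and cannot see
  reductions applied at the first prescription.
* The Cox stage assumes proportional hazards on a duration that mixes
  on-treatment spans and between-line gaps; the generator satisfies this
  by construction, real data need not.
* Real-data regression estimates, KM medians and baseline tables from
  the proprietary source database are not reproducible here; the
  pipeline reproduces their *arithmetic* and validates the machinery on
  synthetic data.
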