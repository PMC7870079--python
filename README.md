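# crclot

Line-of-therapy analytics for advanced colorectal cancer (CRC) in
hospital administrative claims: rule-based cohort selection, derivation of
treatment lines from raw prescriptions, treatment-sequence and
second-line antiangiogenic metrics, and the survival/regression stages
built on top of them — plus a synthetic claims generator with known
ground truth for end-to-end validation.

## Who it is for

Pharmacoepidemiologists and biostatisticians who study systemic therapy
patterns in claims databases. Claims carry dated drug prescriptions but no
notion of "regimen" or "line of therapy"; every analysis of treatment
sequences therefore rests on a derivation algorithm whose window and gap
rules must be explicit, tested, and reproducible. `crclot` implements one
complete rule set for advanced CRC and pairs it with a generator that
knows the truth, so the rules can be validated instead of trusted.

## The rule set

**Regimen.** A line's regimen is the combination of all antitumor drugs
(plus leucovorin) prescribed within the initial 28-day window of the
line's first prescription, named by exact-set match (FOLFOX, CAPOX,
FOLFIRI, FOLFOXIRI, SOX, IRIS, monotherapies, otherwise OTHER) with
biologics as an ordered suffix (BEV, RAM, AFL, CET, PANI).

**Line ends** at whichever comes first:

1. *gap rule* — ≥180 days between the running expected-final-dose date
   (prescription date + days supplied, or the drug's default cycle
   length) and the next antitumor prescription; the line ends at the
   expected final dose date;
2. *new-drug rule* — a prescription containing an antitumor drug not in
   the current regimen; the line ends, and the next line starts, at that
   prescription's date. Exception, for second and later lines only: a
   biologic prescribed into a chemotherapy-only regimen is an **addition**
   to the regimen, not a new line.

Otherwise the last line ends at `min(expected final dose date, data end)`.

**Completion and evaluability.** A patient completed all therapy when ≥60
days separate the final expected dose date from the hospital's data end
(otherwise the duration is censored there); a line counts toward a
transition-rate denominator when a next line exists or >60 days of data
remain after its end, so that non-transition is observable.

**Populations.** A *first-line* population (confirmed CRC diagnosis,
ICD-10 C18–C20; first bevacizumab/cetuximab/panitumumab prescription after
it; age ≥20; no such antibody in the prior 365 days; therapy start in the
enrollment window) and an *early recurrence* population (resection, an
adjuvant fluoropyrimidine/oxaliplatin within 91 days of surgery, and a
switch to a new line within 183 days of the adjuvant covered end). RAS
status is presumed from prescriptions: any anti-EGFR antibody in the
analysis window ⇒ wild type. Members whose second line is FOLFIRI plus an
antiangiogenic drug (bevacizumab, ramucirumab, aflibercept beta) form the
subpopulation for the statistical stages:

* Kaplan–Meier estimate of second-line antiangiogenic duration
  (median, log-log 95% CI, restricted mean);
* multivariate logistic model for a single antiangiogenic prescription vs
  ≥2 (odds ratios, Wald CIs);
* multivariate Cox model (Efron ties) for overall treatment duration from
  second-line start to the end of all antitumor therapy, with the 60-day
  completion rule as the event indicator.

## Worked example

```python
from crclot import DrugVocabulary, SimulationConfig, build_cohorts, simulate_bundle
from crclot.metrics import second_line_aa_report
from crclot.simulate import analysis_config_for_simulation

config = SimulationConfig(n_patients=1200, seed=3,
                          line_transition_probs=[1.0, 0.57, 0.52, 0.45],
                          p_aa_second_line=1.0,
                          second_line_backbones={"FOLFIRI": 1.0})
bundle, truth = simulate_bundle(config)
vocab = DrugVocabulary.default()
res = build_cohorts(bundle, vocab, analysis_config_for_simulation(config))
report = second_line_aa_report(bundle, res.members, res.lines, vocab)
```

Running `python examples/04_second_line_models.py` (which continues this
script through the three model stages) prints:

```
subpopulation n=1145, evaluable n=1042
  transitioned to 3rd line: 676 (64.9%)
  single antiangiogenic prescription: 125 (12.0%)

KM second-line antiangiogenic duration: median 5.9 months (95% CI 5.1-6.7)
```

1,145 of 1,200 simulated patients reached a FOLFIRI + antiangiogenic
second line; 1,042 are evaluable (their non-transition would have been
observable), of whom 64.9% started a third line and 12.0% stopped the
antiangiogenic drug after a single prescription. The fitted odds and
hazard ratios (printed next by the example) recover the generator's
configured effects — e.g. hazard ratio 1.29 for BMI ≤18.5 against a
configured 1.31, and 0.59 for presumed RAS-wild type against a configured
0.64.

The other examples show the generator (`01`), the derivation rules on a
hand-written history (`02`), and cohort attrition plus sequence tables
(`03`). The same stages are scriptable via the `crclot` command
(`simulate`, `build-cohorts`, `derive-lines`, `transition-rates`,
`sequence-table`, `second-line-report`, `run-all`, `render-tables`).

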