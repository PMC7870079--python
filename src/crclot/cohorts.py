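"""Patient-selection algorithms for the analysis populations.

Two mutually exclusive populations are selected from a validated bundle:

* **first-line population** -- presumed advanced/metastatic disease:
  confirmed CRC diagnosis (ICD-10 C18-C20) in the diagnosis window, a first
  prescription of bevacizumab, cetuximab or panitumumab after that
  diagnosis, age >= 20 at that prescription, no such antibody in the 365
  days before it, not eligible for the early recurrence population, no
  prescription of antitumor drugs outside the guideline list, and therapy
  start on/after the enrollment start;
* **early recurrence population** -- adjuvant therapy followed by early
  relapse: colorectal resection after the first CRC diagnosis, an adjuvant
  drug (capecitabine, 5-FU, S-1, UFT or oxaliplatin) started within 91
  days of surgery, a switch to a subsequent line within 183 days of the
  adjuvant line's expected final dose date, no antibody before the first
  resection and none within 91 days of chemotherapy start.

Presumed RAS status is a prescription proxy: any anti-EGFR antibody in the
whole analysis window implies wild type, otherwise mutant.

The FOLFIRI + antiangiogenic subpopulation flags members whose second
line's initial 28-day regimen is a FOLFIRI backbone plus at least one
antiangiogenic drug; the attributed drug is the earliest-prescribed
antiangiogenic in that window (date ties broken bevacizumab < ramucirumab
< aflibercept beta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional

import pandas as pd
from pydantic import BaseModel

from .events import PatientEvents, collect_events
from .io import ClaimsBundle
from .lines import LineConfig, TherapyLine, annotate_lines, derive_lines
from .vocab import (
    ANTI_EGFR_DRUGS,
    ANTIANGIOGENIC_DRUGS,
    FIRST_LINE_MAB_DRUGS,
    DrugVocabulary,
    name_regimen,
)

CRC_ICD10_PREFIXES = ("C18", "C19", "C20")

#: fixed tie order for attributing the second-line antiangiogenic drug
AA_TIE_ORDER = {d: i for i, d in enumerate(ANTIANGIOGENIC_DRUGS)}

DEFAULT_JSCCR_DRUGS = frozenset(
    {
        "fluorouracil", "capecitabine", "s1", "uft", "oxaliplatin", "irinotecan",
        "trifluridine_tipiracil", "bevacizumab", "ramucirumab", "aflibercept_beta",
        "cetuximab", "panitumumab", "pembrolizumab", "regorafenib",
    }
)

DEFAULT_ADJUVANT_DRUGS = frozenset(
    {"capecitabine", "fluorouracil", "s1", "uft", "oxaliplatin"}
)


class AnalysisConfig(BaseModel):
    """Calendar windows and drug sets driving cohort selection.

    Defaults reproduce the study design: diagnoses accepted May 2014 -
    July 2019, therapy starts from May 2016, analysis period through
    September 2019.  All day-count windows are closed intervals.
    """

    diagnosis_start: date = date(2014, 5, 1)
    diagnosis_end: date = date(2019, 7, 31)
    enrollment_start: date = date(2016, 5, 1)
    analysis_start: date = date(2014, 5, 1)
    analysis_end: date = date(2019, 9, 30)
    min_age: int = 20
    washout_days: int = 365
    adjuvant_window_days: int = 91
    recurrence_window_days: int = 183
    baseline_window_days: int = 365
    jsccr_drugs: frozenset[str] = DEFAULT_JSCCR_DRUGS
    adjuvant_drugs: frozenset[str] = DEFAULT_ADJUVANT_DRUGS
    line: LineConfig = None  # type: ignore[assignment]

    model_config = {"arbitrary_types_allowed": True}

    def model_post_init(self, __context) -> None:
        if self.line is None:
            object.__setattr__(self, "line", LineConfig())


@dataclass
class CohortMember:
    patient_id: str
    population: str  # 'first_line' | 'early_recurrence'
    anchor_date: date  # first qualifying antibody rx, or first resection
    therapy_start_date: date  # first-line start or adjuvant start
    index_date: Optional[date]  # start of second-line therapy, if any
    presumed_ras: str  # 'wild_type' | 'mutant'
    in_folfiri_aa_subpop: bool = False
    second_line_aa_drug: Optional[str] = None
    multi_aa: bool = False


@dataclass
class SelectionLog:
    steps: list[tuple[str, int]] = field(default_factory=list)

    def record(self, label: str, n: int) -> None:
        if self.steps and n > self.steps[-1][1]:
            raise ValueError("selection-log attrition must be non-increasing")
        self.steps.append((label, n))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["criterion", "n_remaining"])


@dataclass
class CohortResult:
    members: list[CohortMember]
    logs: dict[str, SelectionLog]
    lines: dict[str, list[TherapyLine]]

    def member(self, patient_id: str) -> CohortMember:
        for m in self.members:
            if m.patient_id == patient_id:
                return m
        raise KeyError(patient_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": m.patient_id,
                    "population": m.population,
                    "anchor_date": m.anchor_date,
                    "therapy_start_date": m.therapy_start_date,
                    "index_date": m.index_date,
                    "presumed_ras": m.presumed_ras,
                    "in_folfiri_aa_subpop": m.in_folfiri_aa_subpop,
                    "second_line_aa_drug": m.second_line_aa_drug,
                    "multi_aa": m.multi_aa,
                }
                for m in sorted(self.members, key=lambda m: m.patient_id)
            ],
            columns=["patient_id", "population", "anchor_date", "therapy_start_date",
                     "index_date", "presumed_ras", "in_folfiri_aa_subpop",
                     "second_line_aa_drug", "multi_aa"],
        )


def age_on(birth_year: int, on_date: date) -> int:
    """Age from a birth year with July 1 as the assumed birthday."""
    age = on_date.year - int(birth_year)
    if on_date < date(on_date.year, 7, 1):
        age -= 1
    return age


def first_crc_diagnosis(bundle: ClaimsBundle, patient_id: str,
                        config: AnalysisConfig | None = None) -> Optional[date]:
    """Earliest confirmed C18-C20 diagnosis inside the diagnosis window."""
    config = config or AnalysisConfig()
    dx = bundle.diagnoses
    sub = dx[
        (dx["patient_id"] == patient_id)
        & dx["confirmed"]
        & dx["icd10"].astype(str).str.startswith(CRC_ICD10_PREFIXES)
        & (dx["date"] >= config.diagnosis_start)
        & (dx["date"] <= config.diagnosis_end)
    ]
    return None if sub.empty else sub["date"].min()


def presume_ras_status(prescriptions: pd.DataFrame, patient_id: str,
                       window: tuple[date, date]) -> str:
    """'wild_type' iff any anti-EGFR antibody prescription falls in ``window``."""
    rx = prescriptions
    hit = rx[
        (rx["patient_id"] == patient_id)
        & rx["drug_id"].isin(ANTI_EGFR_DRUGS)
        & (rx["date"] >= window[0])
        & (rx["date"] <= window[1])
    ]
    return "wild_type" if len(hit) else "mutant"


def _grouped(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    if df.empty:
        return {}
    return {pid: g for pid, g in df.groupby("patient_id", sort=True)}


@dataclass
class _EarlyRecurrenceCandidate:
    resection_date: date
    adjuvant_start: date
    lines: list[TherapyLine]


def _early_recurrence_eligibility(
    pid: str, dx_date: date, ev: PatientEvents, birth_year: int, data_end: date,
    vocab: DrugVocabulary, config: AnalysisConfig,
) -> tuple[Optional[_EarlyRecurrenceCandidate], str]:
    """Early-recurrence inclusion/exclusion for one patient, before the
    enrollment-date filter.  Returns (candidate, failed-criterion-label)."""
    resections = [d for d, kind in ev.proc
                  if kind == "colorectal_resection"
                  and dx_date <= d <= config.diagnosis_end]
    if not resections:
        return None, "resection_after_diagnosis"
    resection = min(resections)
    if age_on(birth_year, resection) < config.min_age:
        return None, "age_ge_20"
    adj_limit = resection + timedelta(days=config.adjuvant_window_days)
    adj_dates = [d for d, drug, _, _ in ev.rx
                 if drug in config.adjuvant_drugs and resection <= d <= adj_limit]
    if not adj_dates:
        return None, "adjuvant_within_91d_of_surgery"
    adj_start = min(adj_dates)
    mab_dates = [d for d, drug, _, _ in ev.rx if drug in FIRST_LINE_MAB_DRUGS]
    if any(d < resection for d in mab_dates):
        return None, "no_biologic_before_resection"
    mab_limit = adj_start + timedelta(days=config.adjuvant_window_days)
    if any(adj_start <= d <= mab_limit for d in mab_dates):
        return None, "no_biologic_within_91d_of_chemo_start"
    lines = derive_lines(ev.rx, adj_start, data_end, vocab, first_line_number=0,
                         config=config.line, patient_id=pid)
    if len(lines) < 2:
        return None, "switch_to_second_line_within_183d"
    gap = (lines[1].start_date - lines[0].expected_final_dose_date).days
    if gap > config.recurrence_window_days:
        return None, "switch_to_second_line_within_183d"
    return _EarlyRecurrenceCandidate(resection, adj_start, lines), ""


def build_cohorts(bundle: ClaimsBundle, vocab: DrugVocabulary,
                  config: AnalysisConfig | None = None) -> CohortResult:
    """Run the full selection: both populations, RAS presumption, line
    derivation, and the FOLFIRI + antiangiogenic subpopulation flags."""
    config = config or AnalysisConfig()
    events = collect_events(bundle)
    non_jsccr_antitumor = vocab.antitumor_ids() - config.jsccr_drugs

    patients = bundle.patients
    all_ids = list(patients["patient_id"])
    birth_year = dict(zip(patients["patient_id"], patients["birth_year"]))
    data_end = dict(zip(patients["patient_id"], patients["data_end"]))

    er_log = SelectionLog()
    fl_log = SelectionLog()
    er_log.record("patients_in_bundle", len(all_ids))
    fl_log.record("patients_in_bundle", len(all_ids))

    # --- first CRC diagnosis (shared first criterion) ------------------
    dx = bundle.diagnoses
    crc = dx[
        dx["confirmed"]
        & dx["icd10"].astype(str).str.startswith(CRC_ICD10_PREFIXES)
        & (dx["date"] >= config.diagnosis_start)
        & (dx["date"] <= config.diagnosis_end)
    ] if len(dx) else dx
    dx_date: dict[str, date] = (
        crc.groupby("patient_id")["date"].min().to_dict() if len(crc) else {}
    )
    er_log.record("confirmed_crc_diagnosis_in_window", len(dx_date))
    fl_log.record("confirmed_crc_diagnosis_in_window", len(dx_date))

    # --- early recurrence eligibility (pre-enrollment filter) ----------
    er_candidates: dict[str, _EarlyRecurrenceCandidate] = {}
    er_order = [
        "resection_after_diagnosis", "age_ge_20", "adjuvant_within_91d_of_surgery",
        "no_biologic_before_resection", "no_biologic_within_91d_of_chemo_start",
        "switch_to_second_line_within_183d",
    ]
    survivors = dict.fromkeys(er_order, 0)
    for pid in sorted(dx_date):
        cand, failed = _early_recurrence_eligibility(
            pid, dx_date[pid], events[pid], birth_year[pid], data_end[pid],
            vocab, config,
        )
        if cand is not None:
            er_candidates[pid] = cand
            for k in er_order:
                survivors[k] += 1
        else:
            for k in er_order:
                if k == failed:
                    break
                survivors[k] += 1
    for k in er_order:
        er_log.record(k, survivors[k])

    # non-guideline antitumor drug exclusion, then enrollment-date filter
    def uses_non_jsccr(pid: str) -> bool:
        return any(drug in non_jsccr_antitumor for _, drug, _, _ in events[pid].rx)

    er_eligible = {pid: cand for pid, cand in er_candidates.items()
                   if not uses_non_jsccr(pid)}
    er_log.record("no_non_jsccr_antitumor_drug", len(er_eligible))
    er_members: dict[str, _EarlyRecurrenceCandidate] = {
        pid: cand for pid, cand in er_eligible.items()
        if cand.adjuvant_start >= config.enrollment_start
    }
    er_log.record("therapy_start_on_after_enrollment_start", len(er_members))

    # --- first-line population ------------------------------------------
    fl_anchor: dict[str, date] = {}
    for pid in sorted(dx_date):
        d = dx_date[pid]
        mab_dates = [
            rd for rd, drug, _, _ in events[pid].rx
            if drug in FIRST_LINE_MAB_DRUGS and d <= rd <= config.diagnosis_end
        ]
        if mab_dates:
            fl_anchor[pid] = min(mab_dates)
    fl_log.record("first_line_antibody_after_diagnosis", len(fl_anchor))

    fl_anchor = {
        pid: a for pid, a in fl_anchor.items()
        if age_on(birth_year[pid], a) >= config.min_age
    }
    fl_log.record("age_ge_20_at_first_antibody", len(fl_anchor))

    def washout_ok(pid: str, anchor: date) -> bool:
        lo = anchor - timedelta(days=config.washout_days)
        return not any(
            lo <= rd < anchor
            for rd, drug, _, _ in events[pid].rx
            if drug in FIRST_LINE_MAB_DRUGS
        )

    fl_anchor = {pid: a for pid, a in fl_anchor.items() if washout_ok(pid, a)}
    fl_log.record("no_prior_antibody_within_365d", len(fl_anchor))

    fl_anchor = {pid: a for pid, a in fl_anchor.items() if pid not in er_candidates}
    fl_log.record("not_eligible_for_early_recurrence", len(fl_anchor))

    fl_anchor = {pid: a for pid, a in fl_anchor.items() if not uses_non_jsccr(pid)}
    fl_log.record("no_non_jsccr_antitumor_drug", len(fl_anchor))

    fl_anchor = {pid: a for pid, a in fl_anchor.items() if a >= config.enrollment_start}
    fl_log.record("therapy_start_on_after_enrollment_start", len(fl_anchor))

    # --- assemble members: derived lines and RAS presumption -----------
    members: list[CohortMember] = []
    lines_by_pid: dict[str, list[TherapyLine]] = {}
    wild_pids = {
        pid for pid, ev in events.items()
        if any(drug in ANTI_EGFR_DRUGS
               and config.analysis_start <= rd <= config.analysis_end
               for rd, drug, _, _ in ev.rx)
    }

    def ras_of(pid: str) -> str:
        return "wild_type" if pid in wild_pids else "mutant"

    for pid, cand in sorted(er_members.items()):
        lines = annotate_lines(cand.lines, data_end[pid], config.line)
        lines_by_pid[pid] = lines
        members.append(
            CohortMember(
                patient_id=pid,
                population="early_recurrence",
                anchor_date=cand.resection_date,
                therapy_start_date=cand.adjuvant_start,
                index_date=lines[1].start_date if len(lines) > 1 else None,
                presumed_ras=ras_of(pid),
            )
        )
    for pid, anchor in sorted(fl_anchor.items()):
        lines = derive_lines(events[pid].rx, anchor, data_end[pid], vocab,
                             first_line_number=1, config=config.line, patient_id=pid)
        lines = annotate_lines(lines, data_end[pid], config.line)
        lines_by_pid[pid] = lines
        members.append(
            CohortMember(
                patient_id=pid,
                population="first_line",
                anchor_date=anchor,
                therapy_start_date=anchor,
                index_date=lines[1].start_date if len(lines) > 1 else None,
                presumed_ras=ras_of(pid),
            )
        )

    select_folfiri_aa_subpopulation(members, lines_by_pid, bundle, vocab, config,
                                    _events=events)
    return CohortResult(members=members,
                        logs={"first_line": fl_log, "early_recurrence": er_log},
                        lines=lines_by_pid)


def second_line(lines: list[TherapyLine]) -> Optional[TherapyLine]:
    for line in lines:
        if line.line_number == 2:
            return line
    return None


def select_folfiri_aa_subpopulation(
    members: list[CohortMember],
    lines_by_pid: dict[str, list[TherapyLine]],
    bundle: ClaimsBundle,
    vocab: DrugVocabulary,
    config: AnalysisConfig | None = None,
    _events: dict[str, PatientEvents] | None = None,
) -> list[CohortMember]:
    """Flag members whose second-line initial regimen is FOLFIRI plus at
    least one antiangiogenic drug, and attribute the antiangiogenic drug."""
    config = config or AnalysisConfig()
    events = _events or collect_events(bundle)
    aa_set = set(ANTIANGIOGENIC_DRUGS)
    for m in members:
        m.in_folfiri_aa_subpop = False
        m.second_line_aa_drug = None
        m.multi_aa = False
        line2 = second_line(lines_by_pid.get(m.patient_id, []))
        if line2 is None:
            continue
        label = name_regimen(line2.regimen.base_drugs, vocab)
        if label.backbone != "FOLFIRI" or not (set(line2.regimen.base_drugs) & aa_set):
            continue
        window_end = line2.start_date + timedelta(days=config.line.regimen_window_days - 1)
        in_window = [
            (rd, drug) for rd, drug, _, _ in events[m.patient_id].rx
            if drug in aa_set and line2.start_date <= rd <= window_end
        ]
        first = min(in_window, key=lambda t: (t[0], AA_TIE_ORDER[t[1]]))
        m.in_folfiri_aa_subpop = True
        m.second_line_aa_drug = first[1]
        m.multi_aa = len({drug for _, drug in in_window}) > 1
    return members
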