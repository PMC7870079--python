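"""Synthetic claims generator with known ground truth.

The generator emits *prescriptions*, not lines: the true line structure is
latent bookkeeping, and recovering it is exactly what the derivation
algorithm is tested against.  Each simulated patient gets

* a confirmed C18-C20 diagnosis, demographics and a hospital;
* for the early recurrence arm, a resection, adjuvant chemotherapy within
  91 days of surgery and a switch to second-line therapy within 183 days
  of the adjuvant expected final dose date; for the first-line arm, a
  biologic-containing first regimen;
* subsequent lines drawn from per-line transition probabilities and
  regimen menus, with every line's drugs prescribed on the regimen's
  cycle grid (plus optional jitter and delay noise) until the line's
  simulated end;
* an overall treatment duration from second-line start drawn from an
  exponential proportional-hazards model with configurable per-covariate
  log hazard ratios, and a single-prescription antiangiogenic outcome
  drawn from a logistic model with configurable effects;
* a per-patient ``data_end`` lag, BMI/Barthel assessments with
  configurable missingness, and concomitant drugs/procedures during the
  second line.

A configurable fraction of patients are "decoys" that violate one
selection criterion (prior antibody in the washout window, age < 20, a
non-guideline antitumor drug, pre-enrollment start, a non-CRC or
unconfirmed diagnosis, adjuvant therapy without recurrence, or systemic
therapy without biologics); their true population label is None.

Under a fixed seed the generator is deterministic, and on a noise-free
configuration (no jitter, no cycle delays) the derivation recovers the
truth lines exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .cohorts import AnalysisConfig
from .io import BARTHEL_ITEM_MAX, ClaimsBundle, make_bundle
from .vocab import DrugVocabulary

#: drugs of each named backbone as the generator prescribes them
BACKBONE_DRUGS: dict[str, tuple[str, ...]] = {
    "FOLFOX": ("fluorouracil", "leucovorin", "oxaliplatin"),
    "CAPOX": ("capecitabine", "oxaliplatin"),
    "FOLFIRI": ("fluorouracil", "leucovorin", "irinotecan"),
    "FOLFOXIRI": ("fluorouracil", "leucovorin", "oxaliplatin", "irinotecan"),
    "SOX": ("s1", "oxaliplatin"),
    "IRIS": ("s1", "irinotecan"),
    "CAPE": ("capecitabine",),
    "S-1": ("s1",),
    "5-FU": ("fluorouracil", "leucovorin"),
    "UFT": ("uft",),
    "FTD/TPI": ("trifluridine_tipiracil",),
    "IRI": ("irinotecan",),
    "REG": ("regorafenib",),
    "PEMBRO": ("pembrolizumab",),
}

_IV_DOSES = {"fluorouracil": 2400.0, "oxaliplatin": 130.0, "irinotecan": 150.0,
             "leucovorin": 200.0}
_AA_DOSES = {"bevacizumab": 300.0, "ramucirumab": 500.0, "aflibercept_beta": 250.0}
_MAB_DOSES = {"cetuximab": 400.0, "panitumumab": 360.0, **_AA_DOSES}

_ORAL_DRUGS = {"capecitabine", "s1", "uft", "trifluridine_tipiracil", "regorafenib",
               "sorafenib", "amlodipine", "candesartan", "butylscopolamine",
               "warfarin", "edoxaban", "acetaminophen"}

_RIGHT_CODES = ("C18.0", "C18.1", "C18.2", "C18.3", "C18.4")
_LEFT_CODES = ("C18.5", "C18.6", "C18.7", "C19", "C20")

DECOY_KINDS = ("prior_antibody", "under_age", "non_jsccr", "pre_enrollment",
               "wrong_icd", "unconfirmed", "adjuvant_only", "no_biologic")

#: covariates of the discontinuation models, matching stats.COX_COVARIATES
_COX_COVS = [
    "designated_cancer_hospital", "age_ge70_at_2l", "male", "left_sided",
    "presumed_ras_wild", "bmi_le_18_5", "adl_not_independent",
    "oral_fp_prev_line", "irinotecan_prev_line", "prev_line_ge180d",
    "early_recurrence", "qual_proteinuria_2l", "quant_proteinuria_2l",
    "antihypertensive_2l", "anticholinergic_2l", "anticoagulant_2l",
]
_LOGISTIC_COVS = _COX_COVS[:11]


class ConfigError(RuntimeError):
    """Infeasible simulation configuration."""


class SimulationConfig(BaseModel):
    """Study-shaped defaults for the synthetic cohort.

    Calendar windows, population mix, regimen menus, transition
    probabilities and outcome-model defaults follow the study conditions:
    therapy starts May 2016 - July 2019, ~9% early recurrence, ~27%
    presumed RAS wild type, antiangiogenic drug mix roughly 53/35/12,
    ~11-12% marginal single-prescription rate, and Cox effects shaped like
    the reported hazard ratios.
    """

    n_patients: int = 500
    seed: int = 0
    enrollment_start: date = date(2016, 5, 1)
    enrollment_end: date = date(2019, 7, 31)
    n_hospitals: int = 10
    p_designated_cancer: float = 0.74
    p_early_recurrence: float = 0.09
    p_ras_wildtype: float = 0.27
    p_decoy: float = 0.06
    p_male: float = 0.58
    age_mean: float = 66.0
    age_sd: float = 10.0
    p_right_sided: float = 0.33
    p_left_sided: float = 0.62  # remainder: unspecified C18.9
    bmi_mean: float = 22.3
    bmi_sd: float = 3.7
    p_adl_independent: float = 0.91

    #: P(transition) from line k to k+1 is entry k-1; the adjuvant ->
    #: second-line step is always present for the early recurrence arm
    line_transition_probs: list[float] = Field(
        default_factory=lambda: [0.63, 0.57, 0.52, 0.45]
    )
    adjuvant_backbones: dict[str, float] = Field(
        default_factory=lambda: {"CAPOX": 0.40, "CAPE": 0.30, "UFT": 0.20, "SOX": 0.10}
    )
    first_line_backbones: dict[str, float] = Field(
        default_factory=lambda: {
            "FOLFOX": 0.40, "CAPOX": 0.28, "FOLFIRI": 0.12, "SOX": 0.08,
            "FOLFOXIRI": 0.06, "CAPE": 0.06,
        }
    )
    second_line_backbones: dict[str, float] = Field(
        default_factory=lambda: {
            "FOLFIRI": 0.62, "IRIS": 0.15, "FOLFOX": 0.08, "CAPOX": 0.08, "SOX": 0.07,
        }
    )
    later_line_backbones: dict[str, float] = Field(
        default_factory=lambda: {"FTD/TPI": 0.45, "REG": 0.25, "IRI": 0.20, "PEMBRO": 0.10}
    )
    p_first_line_anti_egfr_wild: float = 0.65
    p_aa_second_line: float = 0.67
    aa_weights: dict[str, float] = Field(
        default_factory=lambda: {"bevacizumab": 0.53, "ramucirumab": 0.35,
                                 "aflibercept_beta": 0.12}
    )
    p_second_line_anti_egfr_wild: float = 0.45
    p_biologic_addition: float = 0.25  # of chemotherapy-only second lines

    cycle_jitter_days: int = 2
    p_cycle_delay: float = 0.12
    cycle_delay_days: tuple[int, int] = (7, 15)
    inter_line_gap_days: tuple[int, int] = (14, 90)
    p_gap_restart: float = 0.04
    gap_restart_days: tuple[int, int] = (200, 320)

    first_line_duration_shape: float = 2.0
    first_line_duration_scale: float = 88.0
    baseline_hazard_per_day: float = 0.0035
    cox_log_hrs: dict[str, float] = Field(
        default_factory=lambda: {
            "designated_cancer_hospital": math.log(1.13),
            "age_ge70_at_2l": math.log(1.06),
            "male": math.log(1.05),
            "left_sided": math.log(0.85),
            "presumed_ras_wild": math.log(0.64),
            "bmi_le_18_5": math.log(1.31),
            "adl_not_independent": math.log(1.36),
            "oral_fp_prev_line": math.log(0.80),
            "irinotecan_prev_line": math.log(1.16),
            "prev_line_ge180d": math.log(0.91),
            "early_recurrence": math.log(0.68),
            "qual_proteinuria_2l": math.log(0.73),
            "quant_proteinuria_2l": math.log(0.90),
            "antihypertensive_2l": math.log(0.89),
            "anticholinergic_2l": math.log(0.91),
            "anticoagulant_2l": math.log(0.94),
        }
    )
    #: intercept chosen so the marginal single-prescription rate under the
    #: default effects is ~11-12%
    logistic_intercept: float = math.log(0.10 / 0.90)
    logistic_effects: dict[str, float] = Field(
        default_factory=lambda: {
            "age_ge70_at_2l": math.log(1.72),
            "adl_not_independent": math.log(2.04),
            "presumed_ras_wild": math.log(0.53),
            "early_recurrence": math.log(0.50),
        }
    )
    p_dose_reduction: float = 0.12
    missing_bmi_rate: float = 0.10
    missing_adl_rate: float = 0.10
    p_concomitant: dict[str, float] = Field(
        default_factory=lambda: {
            "antihypertensive": 0.21, "anticholinergic": 0.15, "anticoagulant": 0.05,
            "proteinuria_qualitative": 0.50, "proteinuria_quantitative": 0.07,
        }
    )
    p_resection_first_line: float = 0.25
    data_end_lag_mean_days: float = 300.0

    @model_validator(mode="after")
    def _check(self):
        for name in ("p_early_recurrence", "p_ras_wildtype", "p_decoy", "p_male",
                     "p_aa_second_line", "p_cycle_delay", "p_dose_reduction",
                     "missing_bmi_rate", "missing_adl_rate", "p_gap_restart"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if (self.enrollment_end - self.enrollment_start).days < 28:
            raise ConfigError("enrollment window shorter than one regimen cycle")
        for menu in (self.adjuvant_backbones, self.first_line_backbones,
                     self.second_line_backbones, self.later_line_backbones):
            if any(w < 0 for w in menu.values()) or sum(menu.values()) <= 0:
                raise ConfigError("menu weights must be nonnegative and normalisable")
        if not all(0.0 <= p <= 1.0 for p in self.line_transition_probs):
            raise ConfigError("transition probabilities outside [0, 1]")
        if self.baseline_hazard_per_day <= 0:
            raise ConfigError("baseline hazard must be positive")
        return self

    def noise_free(self, **overrides) -> "SimulationConfig":
        """Copy with jitter, cycle delays and missingness switched off."""
        return self.model_copy(
            update={"cycle_jitter_days": 0, "p_cycle_delay": 0.0,
                    "missing_bmi_rate": 0.0, "missing_adl_rate": 0.0, **overrides}
        )


def cox_recovery_config(n_patients: int = 2000, covariate: str = "bmi_le_18_5",
                        log_hr: float = math.log(1.5), **overrides) -> SimulationConfig:
    """Configuration for the Cox effect-recovery experiment: every patient
    reaches a FOLFIRI + antiangiogenic second line, one covariate carries a
    nonzero log hazard ratio, and missingness is off so the estimation
    error of the hazard effect is isolated from complete-case attrition."""
    return SimulationConfig(
        n_patients=n_patients,
        line_transition_probs=[1.0, 0.57, 0.52, 0.45],
        second_line_backbones={"FOLFIRI": 1.0},
        p_aa_second_line=1.0,
        p_biologic_addition=0.0,
        p_gap_restart=0.0,
        p_decoy=0.0,
        missing_bmi_rate=0.0,
        missing_adl_rate=0.0,
        cox_log_hrs={covariate: log_hr},
        logistic_effects={},
        **overrides,
    )


def logistic_recovery_config(n_patients: int = 2200, covariate: str = "age_ge70_at_2l",
                             log_or: float = math.log(2.0), **overrides) -> SimulationConfig:
    """Configuration for the logistic effect-recovery experiment."""
    cfg = cox_recovery_config(n_patients=n_patients, **overrides)
    return cfg.model_copy(
        update={"cox_log_hrs": {}, "logistic_effects": {covariate: log_or}}
    )


def null_config(n_patients: int = 500, **overrides) -> SimulationConfig:
    """All outcome-model effects zero, for null calibration."""
    return cox_recovery_config(n_patients=n_patients, **overrides).model_copy(
        update={"cox_log_hrs": {}, "logistic_effects": {}}
    )


def analysis_config_for_simulation(config: SimulationConfig) -> AnalysisConfig:
    """Analysis windows matched to the simulated horizon (follow-up can run
    past September 2019, so the analysis end is extended accordingly)."""
    return AnalysisConfig(
        enrollment_start=config.enrollment_start,
        diagnosis_end=config.enrollment_end,
        analysis_end=date(2030, 12, 31),
    )


@dataclass
class TruthLine:
    line_number: int
    start_date: date
    end_date: date
    end_reason: str
    base_drugs: frozenset[str]
    additions: list[tuple[date, str]]
    expected_final_dose_date: date

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days


@dataclass
class TruthPatient:
    patient_id: str
    population: Optional[str]  # 'first_line' | 'early_recurrence' | None
    decoy_kind: Optional[str]
    presumed_ras_wild: bool
    lines: list[TruthLine] = field(default_factory=list)
    index_date: Optional[date] = None
    in_subpop: bool = False
    second_line_aa_drug: Optional[str] = None
    single_use: Optional[bool] = None
    covariates: dict[str, bool] = field(default_factory=dict)
    bmi_missing: bool = False
    adl_missing: bool = False
    overall_duration_days: Optional[int] = None
    overall_event: Optional[bool] = None
    data_end: Optional[date] = None


@dataclass
class GroundTruth:
    config: SimulationConfig
    seed: int
    patients: dict[str, TruthPatient] = field(default_factory=dict)

    def lines(self, patient_id: str) -> list[TruthLine]:
        if patient_id not in self.patients:
            raise KeyError(f"unknown patient_id {patient_id!r}")
        return self.patients[patient_id].lines


def truth_lines(truth: GroundTruth, patient_id: str) -> list[TruthLine]:
    """Oracle line sequence for one simulated patient."""
    return truth.lines(patient_id)


def _weighted_choice(rng, menu: dict[str, float]) -> str:
    keys = sorted(menu)
    w = np.array([menu[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _line_cycle_days(drugs: tuple[str, ...] | frozenset, vocab: DrugVocabulary) -> int:
    return max(vocab.get(d).default_cycle_days for d in drugs)


def _breaks_line(prev_drugs: set[str], prev_is_first: bool, next_drugs: tuple[str, ...],
                 vocab: DrugVocabulary) -> bool:
    """Would starting ``next_drugs`` terminate the previous line under the
    new-drug rule, accounting for the biologic-addition exception?"""
    new = [d for d in next_drugs if vocab.is_antitumor(d) and d not in prev_drugs]
    if not new:
        return False
    if prev_is_first:
        return True
    if any(vocab.is_biologic(d) for d in prev_drugs):
        return True
    return any(not vocab.is_biologic(d) for d in new)


def _age_on(birth_year: int, on_date: date) -> int:
    age = on_date.year - int(birth_year)
    if on_date < date(on_date.year, 7, 1):
        age -= 1
    return age


def simulate_bundle(config: SimulationConfig,
                    seed: Optional[int] = None) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate a claims bundle plus its ground truth.

    Deterministic under fixed ``(config, seed)``; ``seed`` overrides
    ``config.seed`` when given.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    vocab = DrugVocabulary.default()
    truth = GroundTruth(config=config, seed=seed)

    # fixed designated-hospital count so the covariate never degenerates
    n_designated = min(max(int(round(config.p_designated_cancer * config.n_hospitals)), 1),
                       config.n_hospitals - 1) if config.n_hospitals > 1 else 1
    designated_flags = rng.permutation(
        [True] * n_designated + [False] * (config.n_hospitals - n_designated)
    )
    hospitals = []
    for i in range(config.n_hospitals):
        bed = ("<200", "200-499", ">=500")[rng.choice(3, p=[0.06, 0.57, 0.37])]
        hospitals.append(
            {"hospital_id": f"H{i+1:03d}", "bed_class": bed,
             "designated_cancer": bool(designated_flags[i])}
        )
    designated = {h["hospital_id"]: h["designated_cancer"] for h in hospitals}

    patients_rows: list[dict] = []
    dx_rows: list[dict] = []
    rx_rows: list[dict] = []
    proc_rows: list[dict] = []
    ass_rows: list[dict] = []
    window_days = max((config.enrollment_end - config.enrollment_start).days, 1)
    jit = config.cycle_jitter_days
    glo, ghi = config.inter_line_gap_days
    probs = config.line_transition_probs

    for i in range(config.n_patients):
        pid = f"P{i+1:06d}"
        rx_buf: list[tuple[date, str, Optional[float], Optional[int]]] = []
        proc_buf: list[tuple[date, str]] = []
        ass_buf: list[tuple[date, str, str]] = []
        dx_buf: list[tuple[date, str, bool]] = []

        decoy = (
            DECOY_KINDS[rng.choice(len(DECOY_KINDS))]
            if rng.random() < config.p_decoy else None
        )
        early = rng.random() < config.p_early_recurrence
        if decoy == "adjuvant_only":
            early = True
        elif decoy is not None:
            early = False
        population = "early_recurrence" if early else "first_line"

        hospital = hospitals[int(rng.choice(len(hospitals)))]["hospital_id"]
        sex = "male" if rng.random() < config.p_male else "female"
        age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 22, 93))
        therapy_start = config.enrollment_start + timedelta(
            days=int(rng.integers(0, window_days + 1))
        )
        if decoy == "pre_enrollment":
            therapy_start = config.enrollment_start - timedelta(
                days=int(rng.integers(30, 360))
            )
        birth_year = therapy_start.year - age
        if decoy == "under_age":
            birth_year = therapy_start.year - 19

        ras_latent = rng.random() < config.p_ras_wildtype
        side_u = rng.random()
        if side_u < config.p_right_sided:
            icd, left, right = _RIGHT_CODES[int(rng.choice(len(_RIGHT_CODES)))], False, True
        elif side_u < config.p_right_sided + config.p_left_sided:
            icd, left, right = _LEFT_CODES[int(rng.choice(len(_LEFT_CODES)))], True, False
        else:
            icd, left, right = "C18.9", False, False
        if decoy == "wrong_icd":
            icd = "C17.9"

        # round to the 1-decimal precision the assessment table carries
        bmi_val = round(float(np.clip(rng.normal(config.bmi_mean, config.bmi_sd),
                                      15.0, 45.0)), 1)
        adl_independent = rng.random() < config.p_adl_independent
        barthel = list(BARTHEL_ITEM_MAX)
        if not adl_independent:
            for k in rng.choice(len(barthel), size=int(rng.integers(1, 4)), replace=False):
                barthel[k] = max(0, barthel[k] - int(rng.integers(5, barthel[k] + 1)))

        resection_date: Optional[date] = None
        if early:
            resection_date = therapy_start - timedelta(days=int(rng.integers(14, 86)))
            dx_date = resection_date - timedelta(days=int(rng.integers(7, 61)))
        else:
            dx_date = therapy_start - timedelta(days=int(rng.integers(20, 81)))
            if decoy is None and rng.random() < config.p_resection_first_line:
                resection_date = dx_date + timedelta(days=int(rng.integers(5, 15)))

        # --- plan line numbers -----------------------------------------
        if decoy == "adjuvant_only":
            line_numbers = [0]
        else:
            line_numbers = [0, 2] if early else [1]
            while line_numbers[-1] not in (0,) and line_numbers[-1] < 5:
                cur = line_numbers[-1]
                p = probs[cur - 1] if cur - 1 < len(probs) else 0.0
                if rng.random() >= p:
                    break
                line_numbers.append(2 if cur == 0 else cur + 1)

        # --- plan regimens ---------------------------------------------
        no_biologic = decoy in ("no_biologic", "adjuvant_only")
        egfr_used = False
        regimens: list[tuple[str, ...]] = []
        aa_drug_2l: Optional[str] = None
        addition_planned = False
        for j, n in enumerate(line_numbers):
            prev = set(regimens[-1]) if regimens else set()
            prev_is_first = j == 1
            for _attempt in range(40):
                if n == 0:
                    drugs = BACKBONE_DRUGS[_weighted_choice(rng, config.adjuvant_backbones)]
                elif n == 1:
                    drugs = BACKBONE_DRUGS[_weighted_choice(rng, config.first_line_backbones)]
                    if not no_biologic:
                        if ras_latent and rng.random() < config.p_first_line_anti_egfr_wild:
                            mab = "panitumumab" if rng.random() < 0.75 else "cetuximab"
                            egfr_used = True
                        else:
                            mab = "bevacizumab"
                        drugs = drugs + (mab,)
                elif n == 2:
                    drugs = BACKBONE_DRUGS[_weighted_choice(rng, config.second_line_backbones)]
                    aa_drug_2l = None
                    addition_planned = False
                    if not no_biologic and rng.random() < config.p_aa_second_line:
                        aa_drug_2l = _weighted_choice(rng, config.aa_weights)
                        drugs = drugs + (aa_drug_2l,)
                    elif not no_biologic and ras_latent and \
                            rng.random() < config.p_second_line_anti_egfr_wild:
                        drugs = drugs + ("panitumumab",)
                        egfr_used = True
                    else:
                        addition_planned = (
                            not no_biologic
                            and rng.random() < config.p_biologic_addition
                        )
                else:
                    drugs = BACKBONE_DRUGS[_weighted_choice(rng, config.later_line_backbones)]
                if not regimens or _breaks_line(prev, prev_is_first, drugs, vocab):
                    break
            else:
                drugs = drugs + ("trifluridine_tipiracil",)
            regimens.append(drugs)

        has_2l = 2 in line_numbers
        L = [_line_cycle_days(r, vocab) for r in regimens]

        # --- events common to everyone ---------------------------------
        dx_buf.append((dx_date, icd, decoy != "unconfirmed"))
        if resection_date is not None:
            proc_buf.append((resection_date, "colorectal_resection"))
        if decoy == "prior_antibody":
            rx_buf.append((dx_date - timedelta(days=int(rng.integers(10, 270))),
                           "bevacizumab", _AA_DOSES["bevacizumab"], None))

        # --- line 1 / adjuvant span ------------------------------------
        d1 = float(rng.gamma(config.first_line_duration_shape,
                             config.first_line_duration_scale))
        min_span1 = 78 if early else L[0]  # keep the antibody clear of the 91-day rule
        k1 = max(int(math.ceil(max(d1, float(min_span1)) / L[0])), 1)
        span1 = k1 * L[0]

        def emit_line(regimen: tuple[str, ...], start: date, span: int,
                      aa_single: bool = False, addition_cycle: Optional[int] = None,
                      addition_drug: Optional[str] = None, reduce_dose: bool = False):
            """Emit one line's prescriptions; returns (max EFD, additions)."""
            Lc = _line_cycle_days(regimen, vocab)
            n_cycles = max(1, span // Lc)
            reduce_at = (int(rng.integers(1, n_cycles))
                         if reduce_dose and n_cycles > 1 else None)
            efd_max: Optional[date] = None
            additions: list[tuple[date, str]] = []
            shift = 0
            for c in range(n_cycles):
                if c > 0 and rng.random() < config.p_cycle_delay:
                    shift += int(rng.integers(*config.cycle_delay_days))
                offs = 0 if (c == 0 or jit == 0) else int(rng.integers(-jit, jit + 1))
                day = start + timedelta(days=c * Lc + shift + offs)
                cycle_drugs = list(regimen)
                if addition_cycle is not None and c >= addition_cycle:
                    if c == addition_cycle:
                        additions.append((day, addition_drug))
                    cycle_drugs.append(addition_drug)
                for drug in cycle_drugs:
                    e = vocab.get(drug)
                    is_aa = drug in _AA_DOSES
                    if is_aa and aa_single and c > 0:
                        continue
                    dose = None
                    if drug in _MAB_DOSES:
                        dose = _MAB_DOSES[drug]
                        if is_aa and reduce_at is not None and c >= reduce_at:
                            dose = round(dose * 0.8, 1)
                    elif drug in _IV_DOSES:
                        dose = _IV_DOSES[drug]
                    supplied = Lc if (drug in _ORAL_DRUGS and e.is_antitumor) else None
                    rx_buf.append((day, drug, dose, supplied))
                    if e.is_antitumor:
                        cover = supplied if supplied is not None else e.default_cycle_days
                        efd = day + timedelta(days=cover)
                        if efd_max is None or efd > efd_max:
                            efd_max = efd
            return efd_max, additions

        t_lines: list[TruthLine] = []
        efd1, _ = emit_line(regimens[0], therapy_start, span1)
        t_lines.append(
            TruthLine(line_number=line_numbers[0], start_date=therapy_start,
                      end_date=efd1, end_reason="data_end",
                      base_drugs=frozenset(regimens[0]), additions=[],
                      expected_final_dose_date=efd1)
        )
        if decoy == "non_jsccr":
            rx_buf.append((therapy_start + timedelta(days=3), "sorafenib", None, 28))

        # --- covariates, outcome draws, later lines --------------------
        cov: dict[str, bool] = {}
        single_use: Optional[bool] = None
        index_date: Optional[date] = None
        bmi_missing = adl_missing = False

        if len(line_numbers) > 1:
            gap1 = int(rng.integers(glo, ghi + 1))
            start2 = efd1 + timedelta(days=gap1)
            if has_2l:
                index_date = start2
                prev_classes = {vocab.drug_class(d) for d in regimens[0]}
                cov = {
                    "designated_cancer_hospital": designated[hospital],
                    "age_ge70_at_2l": _age_on(birth_year, index_date) >= 70,
                    "male": sex == "male",
                    "left_sided": left,
                    "right_sided": right,
                    "presumed_ras_wild": egfr_used,
                    "bmi_le_18_5": bmi_val <= 18.5,
                    "adl_not_independent": not adl_independent,
                    "oral_fp_prev_line": "fluoropyrimidine_oral" in prev_classes,
                    "irinotecan_prev_line": "irinotecan" in prev_classes,
                    "prev_line_ge180d": (start2 - therapy_start).days >= 180,
                    "early_recurrence": early,
                }
                for kind, flag in (("antihypertensive", "antihypertensive_2l"),
                                   ("anticholinergic", "anticholinergic_2l"),
                                   ("anticoagulant", "anticoagulant_2l"),
                                   ("proteinuria_qualitative", "qual_proteinuria_2l"),
                                   ("proteinuria_quantitative", "quant_proteinuria_2l")):
                    cov[flag] = rng.random() < config.p_concomitant[kind]
                if aa_drug_2l is not None:
                    eta = config.logistic_intercept + sum(
                        config.logistic_effects.get(c, 0.0) * float(cov.get(c, False))
                        for c in _LOGISTIC_COVS
                    )
                    single_use = bool(rng.random() < 1.0 / (1.0 + math.exp(-eta)))

            # spans for lines 2+ from the proportional-hazards duration
            rate = config.baseline_hazard_per_day * math.exp(
                sum(config.cox_log_hrs.get(c, 0.0) * float(cov.get(c, False))
                    for c in _COX_COVS)
            )
            D = max(float(L[1]), rng.exponential(1.0 / rate))
            spans = [span1]
            gaps = [gap1]
            remaining = D
            for j in range(1, len(regimens)):
                Lj = L[j]
                if j == len(regimens) - 1:
                    span = max(Lj, int(math.ceil(remaining / Lj)) * Lj)
                else:
                    u = float(rng.uniform(0.35, 0.7))
                    span = max(Lj, int(math.ceil(u * remaining / Lj)) * Lj)
                    g = int(rng.integers(glo, ghi + 1))
                    gaps.append(g)
                    remaining = max(0.0, remaining - span - g)
                spans.append(span)
            # multi-prescription antiangiogenic users must show >= 2 cycles
            if has_2l and aa_drug_2l is not None and single_use is False:
                j2 = line_numbers.index(2)
                spans[j2] = max(spans[j2], 2 * L[j2])

            start = start2
            for j in range(1, len(regimens)):
                n = line_numbers[j]
                aa_single = bool(n == 2 and aa_drug_2l is not None and single_use)
                addition_cycle = addition_drug = None
                if n == 2 and aa_drug_2l is None and addition_planned:
                    Lc = L[j]
                    n_cycles = max(1, spans[j] // Lc)
                    cand = max(2, int(math.ceil((28.0 + jit) / Lc)))
                    if n_cycles > cand:
                        addition_cycle = cand
                        addition_drug = _weighted_choice(rng, config.aa_weights)
                reduce_dose = bool(
                    n == 2 and aa_drug_2l is not None and not aa_single
                    and rng.random() < config.p_dose_reduction
                )
                efd, additions = emit_line(regimens[j], start, spans[j], aa_single,
                                           addition_cycle, addition_drug, reduce_dose)
                t_lines[-1].end_date = start
                t_lines[-1].end_reason = "new_drug"
                t_lines.append(
                    TruthLine(line_number=n, start_date=start, end_date=efd,
                              end_reason="data_end", base_drugs=frozenset(regimens[j]),
                              additions=additions, expected_final_dose_date=efd)
                )
                if j + 1 < len(regimens):
                    start = efd + timedelta(days=gaps[j])

        # gap-restart: repeat the final regimen after a long pause
        if len(line_numbers) >= 2 and rng.random() < config.p_gap_restart:
            last = t_lines[-1]
            pause = int(rng.integers(*config.gap_restart_days))
            r_start = last.expected_final_dose_date + timedelta(days=pause)
            r_regimen = regimens[-1]
            r_span = int(rng.integers(1, 4)) * _line_cycle_days(r_regimen, vocab)
            r_efd, _ = emit_line(r_regimen, r_start, r_span)
            last.end_date = last.expected_final_dose_date
            last.end_reason = "gap_180"
            t_lines.append(
                TruthLine(line_number=last.line_number + 1, start_date=r_start,
                          end_date=r_efd, end_reason="data_end",
                          base_drugs=frozenset(r_regimen), additions=[],
                          expected_final_dose_date=r_efd)
            )

        # --- assessments and concomitant events ------------------------
        if index_date is not None:
            bmi_missing = rng.random() < config.missing_bmi_rate
            adl_missing = rng.random() < config.missing_adl_rate
            if not bmi_missing:
                ass_buf.append((index_date - timedelta(days=int(rng.integers(0, 61))),
                                "bmi", f"{bmi_val:.1f}"))
            if not adl_missing:
                ass_buf.append((index_date - timedelta(days=int(rng.integers(0, 61))),
                                "barthel", ";".join(str(v) for v in barthel)))
            for kind, flag in (("antihypertensive", "antihypertensive_2l"),
                               ("anticholinergic", "anticholinergic_2l"),
                               ("anticoagulant", "anticoagulant_2l"),
                               ("proteinuria_qualitative", "qual_proteinuria_2l"),
                               ("proteinuria_quantitative", "quant_proteinuria_2l")):
                if not cov.get(flag, False):
                    continue
                when = index_date + timedelta(days=int(rng.integers(0, 14)))
                if kind.startswith("proteinuria"):
                    proc_buf.append((when, kind))
                else:
                    drug = {"antihypertensive": "amlodipine",
                            "anticholinergic": "butylscopolamine",
                            "anticoagulant": "warfarin"}[kind]
                    rx_buf.append((when, drug, None, 28))

        # --- data end, truth record ------------------------------------
        last_event = max(
            [d for d, *_ in rx_buf] + [d for d, _ in proc_buf]
            + [d for d, *_ in ass_buf] + [d for d, *_ in dx_buf]
        )
        lag = 1 + int(rng.exponential(config.data_end_lag_mean_days))
        data_end = last_event + timedelta(days=lag)
        last = t_lines[-1]
        if last.end_reason == "data_end":
            last.end_date = min(last.expected_final_dose_date, data_end)

        overall_duration = overall_event = None
        if index_date is not None:
            final_efd = t_lines[-1].expected_final_dose_date
            overall_event = (data_end - final_efd).days >= 60
            end = final_efd if overall_event else min(final_efd, data_end)
            overall_duration = (end - index_date).days

        line2_base = next((t.base_drugs for t in t_lines if t.line_number == 2), None)
        in_subpop = bool(
            decoy is None and aa_drug_2l is not None and line2_base is not None
            and set(BACKBONE_DRUGS["FOLFIRI"]) | {aa_drug_2l} == set(line2_base)
        )

        truth.patients[pid] = TruthPatient(
            patient_id=pid,
            population=None if decoy else population,
            decoy_kind=decoy,
            presumed_ras_wild=egfr_used,
            lines=t_lines,
            index_date=index_date,
            in_subpop=in_subpop,
            second_line_aa_drug=aa_drug_2l if in_subpop else None,
            single_use=single_use,
            covariates=cov,
            bmi_missing=bmi_missing,
            adl_missing=adl_missing,
            overall_duration_days=overall_duration,
            overall_event=overall_event,
            data_end=data_end,
        )
        patients_rows.append(
            {"patient_id": pid, "sex": sex, "birth_year": birth_year,
             "hospital_id": hospital, "data_end": data_end}
        )
        for d, code, conf in dx_buf:
            dx_rows.append({"patient_id": pid, "date": d, "icd10": code, "confirmed": conf})
        for d, drug, dose, supplied in rx_buf:
            rx_rows.append({"patient_id": pid, "date": d, "drug_id": drug, "dose": dose,
                            "route": "oral" if drug in _ORAL_DRUGS else "intravenous",
                            "days_supplied": supplied})
        for d, kind in proc_buf:
            proc_rows.append({"patient_id": pid, "date": d, "kind": kind})
        for d, kind, value in ass_buf:
            ass_rows.append({"patient_id": pid, "date": d, "kind": kind, "value": value})

    bundle = make_bundle(
        patients=patients_rows or None, hospitals=hospitals,
        diagnoses=dx_rows or None, prescriptions=rx_rows or None,
        procedures=proc_rows or None, assessments=ass_rows or None,
        vocab=vocab,
    )
    return bundle, truth
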