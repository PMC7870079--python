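"""Simulation experiments: oracle agreement, effect recovery, calibration.

These functions run the whole pipeline (generate -> select cohorts ->
derive lines -> build covariates -> fit) on simulated bundles and compare
the results with the generator's ground truth.  They are shared by the
test suite and the acceptance script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohorts import build_cohorts
from .lines import TherapyLine
from .metrics import second_line_aa_report
from .simulate import (
    SimulationConfig,
    TruthLine,
    analysis_config_for_simulation,
    simulate_bundle,
)
from .stats import (
    build_covariates_bulk,
    build_overall_duration_records,
    covariates_to_frame,
    fit_overall_duration_cox,
    fit_single_dose_logistic,
)
from .vocab import DrugVocabulary


def replicate_seed(base_seed: int, k: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    return (base_seed * 100_003 + 7 * k + 1) % (2**31 - 1)


def lines_equal(derived: TherapyLine, truth: TruthLine) -> bool:
    return (
        derived.line_number == truth.line_number
        and derived.start_date == truth.start_date
        and derived.end_date == truth.end_date
        and derived.end_reason == truth.end_reason
        and frozenset(derived.regimen.base_drugs) == truth.base_drugs
        and list(derived.regimen.additions) == list(truth.additions)
        and derived.expected_final_dose_date == truth.expected_final_dose_date
    )


@dataclass
class OracleAgreement:
    n_truth_members: int
    n_selected: int
    population_match_rate: float  # fraction of truth members recovered with the right label
    line_match_rate: float  # fraction of matched members whose full line sequence agrees
    subpop_match_rate: float  # agreement on subpopulation membership + attributed drug


def oracle_agreement(config: SimulationConfig, seed: int | None = None) -> OracleAgreement:
    """Simulate, run selection + derivation, compare with ground truth."""
    bundle, truth = simulate_bundle(config, seed)
    vocab = DrugVocabulary.default()
    acfg = analysis_config_for_simulation(config)
    res = build_cohorts(bundle, vocab, acfg)

    truth_members = {p.patient_id: p for p in truth.patients.values()
                     if p.population is not None}
    selected = {m.patient_id: m for m in res.members}

    n_pop_match = sum(
        1 for pid, tp in truth_members.items()
        if pid in selected and selected[pid].population == tp.population
    )
    extra = set(selected) - set(truth_members)
    n_pop_match -= len(extra)  # selecting a decoy is an error

    n_line_match = 0
    for pid, tp in truth_members.items():
        if pid not in selected:
            continue
        derived = res.lines.get(pid, [])
        if len(derived) == len(tp.lines) and all(
            lines_equal(d, t) for d, t in zip(derived, tp.lines)
        ):
            n_line_match += 1

    n_sub_match = sum(
        1 for pid, tp in truth_members.items()
        if pid in selected
        and selected[pid].in_folfiri_aa_subpop == tp.in_subpop
        and selected[pid].second_line_aa_drug == tp.second_line_aa_drug
    )
    n = len(truth_members)
    return OracleAgreement(
        n_truth_members=n,
        n_selected=len(selected),
        population_match_rate=n_pop_match / n if n else 1.0,
        line_match_rate=n_line_match / n if n else 1.0,
        subpop_match_rate=n_sub_match / n if n else 1.0,
    )


def _subpop_fits_inputs(config: SimulationConfig, seed: int | None):
    bundle, truth = simulate_bundle(config, seed)
    vocab = DrugVocabulary.default()
    acfg = analysis_config_for_simulation(config)
    res = build_cohorts(bundle, vocab, acfg)
    members = [m for m in res.members if m.in_folfiri_aa_subpop]
    report = second_line_aa_report(bundle, res.members, res.lines, vocab, acfg)
    covs = build_covariates_bulk(bundle, members, res.lines, vocab, acfg)
    X = covariates_to_frame(covs)
    records = build_overall_duration_records(bundle, members, res.lines, acfg)
    return bundle, truth, res, members, report, X, records


def cox_log_hr_estimate(config: SimulationConfig, seed: int, covariate: str) -> float:
    """One replicate of the Cox stage; returns the estimated log hazard
    ratio for ``covariate``."""
    _, _, _, _, _, X, records = _subpop_fits_inputs(config, seed)
    fit = fit_overall_duration_cox(X, records)
    row = fit.table.set_index("term").loc[covariate]
    return float(math.log(row["estimate"]))


def logistic_or_estimate(config: SimulationConfig, seed: int, covariate: str) -> float:
    """One replicate of the logistic stage; returns the estimated odds
    ratio for ``covariate``."""
    _, _, _, _, report, X, _ = _subpop_fits_inputs(config, seed)
    y = report.single_use
    fit = fit_single_dose_logistic(X.loc[X.index.intersection(y.index)],
                                   y.astype(bool))
    row = fit.table.set_index("term").loc[covariate]
    return float(row["estimate"])


def cox_null_pvalues(config: SimulationConfig, seed: int) -> list[float]:
    """One null replicate of the Cox stage; returns all covariate p-values."""
    _, _, _, _, _, X, records = _subpop_fits_inputs(config, seed)
    fit = fit_overall_duration_cox(X, records)
    return [float(p) for p in fit.table["p"]]


def recovery_coverage(estimates: list[float], low: float, high: float) -> float:
    inside = sum(1 for e in estimates if low <= e <= high)
    return inside / len(estimates)


def single_use_fraction(config: SimulationConfig, seed: int | None = None) -> tuple[float, int]:
    """Observed single-prescription fraction among evaluable subpopulation
    members, with the denominator."""
    _, _, _, _, report, _, _ = _subpop_fits_inputs(config, seed)
    y = report.single_use
    return (float(y.mean()) if len(y) else float("nan"), int(len(y)))
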