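"""Transition rates, sequence tables and second-line antiangiogenic metrics.

Percentages are rounded half-up to one decimal, matching the reporting
convention of the source tables; a rate with zero evaluable patients is
reported as absent, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd

from .cohorts import AnalysisConfig, CohortMember, second_line
from .events import collect_events
from .io import ClaimsBundle
from .lines import TherapyLine, expected_final_dose_date
from .vocab import ANTIANGIOGENIC_DRUGS, DrugVocabulary, regimen_group


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 56.05 -> 56.1, never banker's 56.0)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def rate_percent(numerator: int, denominator: int) -> Optional[float]:
    """``100 * n / d`` rounded half-up to one decimal; None when d == 0."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, 1)


def transition_rates(
    lines_by_pid: dict[str, list[TherapyLine]],
    members: list[CohortMember],
    max_from_line: int = 5,
) -> pd.DataFrame:
    """Per-stratum transition rates between consecutive lines of therapy.

    Strata are population x presumed RAS status.  Denominators are
    evaluable patients (next line observed, or >60 days of data after the
    line end).  The adjuvant -> second-line transition is omitted for the
    early recurrence population (100% by construction of that population).
    """
    rows = []
    for population in ("first_line", "early_recurrence"):
        for ras in ("mutant", "wild_type"):
            cohort = [m for m in members
                      if m.population == population and m.presumed_ras == ras]
            start = 1 if population == "first_line" else 2
            for from_line in range(start, max_from_line):
                n_eval = 0
                n_trans = 0
                for m in cohort:
                    for line in lines_by_pid.get(m.patient_id, []):
                        if line.line_number != from_line:
                            continue
                        if line.evaluable_for_transition:
                            n_eval += 1
                            if line.transitioned:
                                n_trans += 1
                rows.append(
                    {
                        "population": population,
                        "presumed_ras": ras,
                        "from_line": from_line,
                        "to_line": from_line + 1,
                        "n_evaluable": n_eval,
                        "n_transitioned": n_trans,
                        "rate_percent": rate_percent(n_trans, n_eval),
                    }
                )
    return pd.DataFrame(rows)


def sequence_table(
    lines_by_pid: dict[str, list[TherapyLine]],
    members: list[CohortMember],
    vocab: DrugVocabulary,
    max_line: int = 3,
) -> pd.DataFrame:
    """Regimen-label frequencies per stratum and line, sorted descending."""
    rows = []
    for m in members:
        for line in lines_by_pid.get(m.patient_id, []):
            if line.line_number > max_line:
                continue
            rows.append(
                {
                    "population": m.population,
                    "presumed_ras": m.presumed_ras,
                    "line": line.line_label,
                    "regimen": line.regimen.label(vocab).display,
                }
            )
    if not rows:
        return pd.DataFrame(columns=["population", "presumed_ras", "line", "regimen", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["population", "presumed_ras", "line", "regimen"], sort=True)
        .size()
        .reset_index(name="n")
        .sort_values(
            ["population", "presumed_ras", "line", "n", "regimen"],
            ascending=[True, True, True, False, True],
            kind="mergesort",
        )
        .reset_index(drop=True)
    )
    return out


def group_flows(
    lines_by_pid: dict[str, list[TherapyLine]],
    members: list[CohortMember],
    vocab: DrugVocabulary,
) -> pd.DataFrame:
    """From -> to regimen-group flows between consecutive lines (the
    tabular export behind a sequence/Sankey figure)."""
    rows = []
    for m in members:
        lines = lines_by_pid.get(m.patient_id, [])
        for a, b in zip(lines, lines[1:]):
            rows.append(
                {
                    "population": m.population,
                    "presumed_ras": m.presumed_ras,
                    "from_line": a.line_label,
                    "to_line": b.line_label,
                    "from_group": regimen_group(a.regimen.label(vocab), vocab),
                    "to_group": regimen_group(b.regimen.label(vocab), vocab),
                }
            )
    cols = ["population", "presumed_ras", "from_line", "to_line", "from_group", "to_group"]
    if not rows:
        return pd.DataFrame(columns=cols + ["n"])
    return (
        pd.DataFrame(rows)
        .groupby(cols, sort=True)
        .size()
        .reset_index(name="n")
    )


@dataclass
class SecondLineAAReport:
    """Prescription characteristics of second-line antiangiogenic therapy.

    ``table`` has one row per stratum ('all' plus each attributed drug)
    with counts and half-up percentages over the evaluable denominator;
    ``km_records`` holds (patient_id, duration_days, event) for the
    duration stage, built from the first second-line prescription to the
    last antiangiogenic expected final dose date, with completion of all
    antiangiogenic therapy (60-day rule) as the event.
    """

    n_subpop: int
    table: pd.DataFrame
    km_records: pd.DataFrame
    single_use: pd.Series  # patient_id -> bool, evaluable subpop members only


def _aa_rx_in_line(ev_rx: list, line: TherapyLine) -> list:
    """Antiangiogenic prescriptions inside a line's interval, sorted.

    Intervals are half-open at a new-drug boundary (the boundary
    prescription opens the next line) and closed otherwise."""
    out = []
    for d, drug, dose, supplied in ev_rx:
        if drug not in ANTIANGIOGENIC_DRUGS or d < line.start_date:
            continue
        if d < line.end_date or (line.end_reason != "new_drug" and d == line.end_date):
            out.append((d, drug, dose, supplied))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def second_line_aa_report(
    bundle: ClaimsBundle,
    members: list[CohortMember],
    lines_by_pid: dict[str, list[TherapyLine]],
    vocab: DrugVocabulary,
    config: AnalysisConfig | None = None,
) -> SecondLineAAReport:
    config = config or AnalysisConfig()
    events = collect_events(bundle)
    data_end = dict(zip(bundle.patients["patient_id"], bundle.patients["data_end"]))
    margin = config.line.completion_margin_days

    subpop = [m for m in members if m.in_folfiri_aa_subpop]
    per_patient = []
    km_rows = []
    for m in subpop:
        line2 = second_line(lines_by_pid[m.patient_id])
        aa = _aa_rx_in_line(events[m.patient_id].rx, line2)
        dates = [d for d, *_ in aa]
        n_rx = len(dates)
        gaps = [(b - a).days for a, b in zip(dates, dates[1:])]
        gap_ge21 = any(g >= 21 for g in gaps)
        # dose reduction: consecutive same-drug prescriptions, both dosed
        dose_reduced = False
        for drug in {drug for _, drug, _, _ in aa}:
            doses = [dose for _, dg, dose, _ in aa if dg == drug and dose is not None]
            if any(b < a for a, b in zip(doses, doses[1:])):
                dose_reduced = True
        last_aa_efd = None
        for d, drug, dose, supplied in aa:
            efd = expected_final_dose_date(vocab, drug, d, supplied)
            if last_aa_efd is None or efd > last_aa_efd:
                last_aa_efd = efd
        duration = (last_aa_efd - line2.start_date).days
        event = (data_end[m.patient_id] - last_aa_efd).days >= margin
        km_rows.append({"patient_id": m.patient_id, "duration_days": duration,
                        "event": event})
        per_patient.append(
            {
                "patient_id": m.patient_id,
                "aa_drug": m.second_line_aa_drug,
                "n_aa_rx": n_rx,
                "gap_ge21": gap_ge21,
                "dose_reduced": dose_reduced,
                "single_use": n_rx == 1,
                "evaluable": line2.evaluable_for_transition,
                "transitioned": line2.transitioned,
            }
        )

    pp = pd.DataFrame(per_patient, columns=["patient_id", "aa_drug", "n_aa_rx",
                                            "gap_ge21", "dose_reduced", "single_use",
                                            "evaluable", "transitioned"])
    km = pd.DataFrame(km_rows, columns=["patient_id", "duration_days", "event"])

    def stratum_row(name: str, sub: pd.DataFrame) -> dict:
        ev = sub[sub["evaluable"].astype(bool)]
        n_eval = len(ev)
        return {
            "stratum": name,
            "n_subpop": len(sub),
            "n_evaluable": n_eval,
            "n_transitioned_3rd": int(ev["transitioned"].sum()),
            "pct_transitioned_3rd": rate_percent(int(ev["transitioned"].sum()), n_eval),
            "aa_rx_median": float(np.median(ev["n_aa_rx"])) if n_eval else None,
            "aa_rx_q1": float(np.percentile(ev["n_aa_rx"], 25)) if n_eval else None,
            "aa_rx_q3": float(np.percentile(ev["n_aa_rx"], 75)) if n_eval else None,
            "n_dose_reduced": int(ev["dose_reduced"].sum()),
            "pct_dose_reduced": rate_percent(int(ev["dose_reduced"].sum()), n_eval),
            "n_gap_ge21": int(ev["gap_ge21"].sum()),
            "pct_gap_ge21": rate_percent(int(ev["gap_ge21"].sum()), n_eval),
            "n_single_use": int(ev["single_use"].sum()),
            "pct_single_use": rate_percent(int(ev["single_use"].sum()), n_eval),
        }

    strata = [stratum_row("all", pp)]
    for drug in ANTIANGIOGENIC_DRUGS:
        strata.append(stratum_row(drug, pp[pp["aa_drug"] == drug]))
    table = pd.DataFrame(strata)

    single = (
        pp.loc[pp["evaluable"]].set_index("patient_id")["single_use"]
        if len(pp)
        else pd.Series(dtype=bool)
    )
    return SecondLineAAReport(
        n_subpop=len(subpop), table=table, km_records=km, single_use=single
    )
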