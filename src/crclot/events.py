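"""Lightweight per-patient event index.

Per-patient rule evaluation (anchor scans, window checks, line derivation)
touches a handful of rows at a time; plain tuples are far cheaper there
than many tiny DataFrame slices.  ``collect_events`` converts a validated
bundle into per-patient, date-sorted tuple lists in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import ClaimsBundle


@dataclass
class PatientEvents:
    """Date-sorted event tuples for one patient."""

    rx: list = field(default_factory=list)  # (date, drug_id, dose, days_supplied)
    dx: list = field(default_factory=list)  # (date, icd10, confirmed)
    proc: list = field(default_factory=list)  # (date, kind)
    ass: list = field(default_factory=list)  # (date, kind, value)


def collect_events(bundle: ClaimsBundle) -> dict[str, PatientEvents]:
    out: dict[str, PatientEvents] = {
        pid: PatientEvents() for pid in bundle.patients["patient_id"]
    }
    rx = bundle.prescriptions
    if len(rx):
        doses = [None if pd.isna(x) else float(x) for x in rx["dose"]]
        supplied = [None if pd.isna(x) else int(x) for x in rx["days_supplied"]]
        for pid, d, drug, dose, sup in zip(
            rx["patient_id"], rx["date"], rx["drug_id"], doses, supplied
        ):
            out[pid].rx.append((d, drug, dose, sup))
    dx = bundle.diagnoses
    if len(dx):
        for pid, d, code, conf in zip(dx["patient_id"], dx["date"], dx["icd10"],
                                      dx["confirmed"]):
            out[pid].dx.append((d, str(code), bool(conf)))
    proc = bundle.procedures
    if len(proc):
        for pid, d, kind in zip(proc["patient_id"], proc["date"], proc["kind"]):
            out[pid].proc.append((d, kind))
    ass = bundle.assessments
    if len(ass):
        for pid, d, kind, value in zip(ass["patient_id"], ass["date"], ass["kind"],
                                       ass["value"]):
            out[pid].ass.append((d, kind, value))
    return out
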