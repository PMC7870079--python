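"""Line-of-therapy derivation from prescription claims.

The derivation turns a patient's dated antitumor prescriptions into an
ordered, non-overlapping sequence of therapy lines:

* the **regimen** of a line is the combination of all antitumor drugs (plus
  leucovorin) prescribed within the initial 28-day window of the line's
  first prescription;
* a line **ends** at the first of (a) a gap of 180 days or more between the
  running expected-final-dose date and the next antitumor prescription
  (``gap_180``; the line ends at the expected-final-dose date), or (b) a
  prescription containing an antitumor drug not in the current regimen
  (``new_drug``; the line ends at, and the next line starts at, that
  prescription's date);
* **exception** for second and later lines only: a biologic prescribed into
  a chemotherapy-only regimen is an addition to the regimen, not a new
  line.  The exception is narrow -- it does not apply to first-line or
  adjuvant therapy, to regimens already containing a biologic, or when the
  same prescription date also introduces a new non-biologic drug;
* if neither rule fires, the last line ends at
  ``min(expected final dose date, data_end)`` with reason ``data_end``.

Expected final dose dates are the prescription date plus ``days_supplied``
when present, otherwise plus the drug's default cycle length from the
vocabulary.  The 180-day gap clock runs from the running *maximum*
expected-final-dose date of the line, i.e. from the end of covered
exposure, not from the last prescription date.

Completion and evaluability use the per-patient ``data_end``:

* a line is *evaluable for transition* when a subsequent line exists or
  more than 60 days of data remain after its end date;
* the patient's therapy is *completed* when 60 days or more separate the
  expected final dose date from ``data_end``; otherwise the duration is
  censored at the expected final dose date.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import pandas as pd

from .vocab import DrugVocabulary, RegimenLabel, name_regimen

#: days per month for month-scale summaries
DAYS_PER_MONTH = 30.4375

ADJUVANT_LINE_NUMBER = 0  # adjuvant therapy sorts before numbered lines

END_REASONS = ("gap_180", "new_drug", "data_end")


@dataclass
class LineConfig:
    regimen_window_days: int = 28
    gap_days: int = 180
    completion_margin_days: int = 60


@dataclass
class Regimen:
    """Drug content of a line: 28-day-window base plus later biologic additions."""

    base_drugs: frozenset[str]
    additions: list[tuple[date, str]] = field(default_factory=list)

    @property
    def all_drugs(self) -> frozenset[str]:
        return self.base_drugs | {d for _, d in self.additions}

    def label(self, vocab: DrugVocabulary) -> RegimenLabel:
        return name_regimen(self.all_drugs, vocab)


@dataclass
class TherapyLine:
    patient_id: str
    line_number: int  # 0 = adjuvant, then 1, 2, 3, ...
    start_date: date
    end_date: date
    end_reason: str
    regimen: Regimen
    expected_final_dose_date: date
    completed: bool = False
    evaluable_for_transition: bool = False
    transitioned: bool = False

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days

    @property
    def duration_months(self) -> float:
        return self.duration_days / DAYS_PER_MONTH

    @property
    def line_label(self) -> str:
        return "adjuvant" if self.line_number == ADJUVANT_LINE_NUMBER else str(self.line_number)


def expected_final_dose_date(
    vocab: DrugVocabulary, drug_id: str, rx_date: date, days_supplied=None
) -> date:
    """Date through which a single prescription covers exposure."""
    entry = vocab.get(drug_id)
    if not entry.is_antitumor:
        raise ValueError(
            f"expected_final_dose_date applies to antitumor drugs; {drug_id!r} is "
            f"{entry.drug_class}"
        )
    if days_supplied is not None and not pd.isna(days_supplied):
        return rx_date + timedelta(days=int(days_supplied))
    return rx_date + timedelta(days=entry.default_cycle_days)


def assemble_regimen(
    prescriptions: pd.DataFrame, anchor_date: date, vocab: DrugVocabulary,
    window_days: int = 28,
) -> Regimen:
    """Collect the base regimen: all antitumor drugs (plus leucovorin)
    prescribed in ``[anchor, anchor + window_days - 1]``."""
    window_end = anchor_date + timedelta(days=window_days - 1)
    in_window = prescriptions[
        (prescriptions["date"] >= anchor_date) & (prescriptions["date"] <= window_end)
    ]
    drugs = frozenset(
        d
        for d in in_window["drug_id"]
        if vocab.is_antitumor(d) or vocab.drug_class(d) == "leucovorin"
    )
    if not drugs:
        raise ValueError(f"no antitumor prescriptions in the 28-day window at {anchor_date}")
    return Regimen(base_drugs=drugs)


def derive_lines(
    prescriptions: pd.DataFrame,
    anchor_date: date,
    data_end: date,
    vocab: DrugVocabulary,
    first_line_number: int = 1,
    config: LineConfig | None = None,
    patient_id: str | None = None,
) -> list[TherapyLine]:
    """Segment one patient's prescriptions into therapy lines.

    ``prescriptions`` is the patient's prescription table -- a DataFrame
    with ``date``/``drug_id``/``days_supplied`` columns or an iterable of
    tuples whose first, second and last elements are date, drug_id and
    days_supplied.  Any drugs may be present; the function keeps antitumor
    drugs and leucovorin dated on/after ``anchor_date``.
    ``first_line_number`` is 1 for the first-line population and 0
    (adjuvant) for the early recurrence population; after an adjuvant line
    the numbering continues at 2 (second-line therapy).
    """
    config = config or LineConfig()
    if isinstance(prescriptions, pd.DataFrame):
        if patient_id is None and len(prescriptions):
            patient_id = str(prescriptions["patient_id"].iloc[0])
        tuples = list(zip(prescriptions["date"], prescriptions["drug_id"],
                          prescriptions["days_supplied"]))
    else:
        tuples = list(prescriptions)

    rows = []
    for t in tuples:
        d, drug, supplied = t[0], t[1], t[-1]
        if d < anchor_date:
            continue
        if supplied is not None and pd.isna(supplied):
            supplied = None
        cls = vocab.drug_class(drug)
        if cls == "leucovorin" or vocab.is_antitumor(drug):
            rows.append((d, drug, supplied))
    if not rows:
        return []
    rows.sort(key=lambda t: (t[0], t[1]))

    # group prescriptions by date
    by_date: list[tuple[date, list[tuple[str, object]]]] = []
    for d, drug, supplied in rows:
        if by_date and by_date[-1][0] == d:
            by_date[-1][1].append((drug, supplied))
        else:
            by_date.append((d, [(drug, supplied)]))

    lines: list[TherapyLine] = []

    def next_line_number() -> int:
        if not lines:
            return first_line_number
        prev = lines[-1].line_number
        return 2 if prev == ADJUVANT_LINE_NUMBER else prev + 1

    cur_start: date | None = None
    cur_number = first_line_number
    base: set[str] = set()
    additions: list[tuple[date, str]] = []
    running_efd: date | None = None
    window_end: date | None = None

    def update_efd(d: date, drugs: list[tuple[str, object]]) -> None:
        nonlocal running_efd
        for drug, supplied in drugs:
            if not vocab.is_antitumor(drug):
                continue  # leucovorin never drives the exposure clock
            efd = expected_final_dose_date(vocab, drug, d, supplied)
            if running_efd is None or efd > running_efd:
                running_efd = efd

    def open_line(d: date, drugs: list[tuple[str, object]]) -> None:
        nonlocal cur_start, cur_number, base, additions, running_efd, window_end
        cur_start = d
        cur_number = next_line_number()
        base = {
            drug for drug, _ in drugs
            if vocab.is_antitumor(drug) or vocab.drug_class(drug) == "leucovorin"
        }
        additions = []
        running_efd = None
        window_end = d + timedelta(days=config.regimen_window_days - 1)
        update_efd(d, drugs)

    def close_line(end: date, reason: str) -> None:
        lines.append(
            TherapyLine(
                patient_id=patient_id or "",
                line_number=cur_number,
                start_date=cur_start,
                end_date=end,
                end_reason=reason,
                regimen=Regimen(base_drugs=frozenset(base), additions=list(additions)),
                expected_final_dose_date=running_efd,
            )
        )

    for d, drugs in by_date:
        if cur_start is None:
            open_line(d, drugs)
            continue
        antitumor_here = [x for x in drugs if vocab.is_antitumor(x[0])]
        if antitumor_here and (d - running_efd).days >= config.gap_days:
            # gap rule fires before the prescription is even seen
            close_line(running_efd, "gap_180")
            open_line(d, drugs)
            continue
        if d <= window_end:
            base |= {
                drug for drug, _ in drugs
                if vocab.is_antitumor(drug) or vocab.drug_class(drug) == "leucovorin"
            }
            update_efd(d, drugs)
            continue
        current = base | {x for _, x in additions}
        new_drugs = [x for x in antitumor_here if x[0] not in current]
        if not new_drugs:
            update_efd(d, drugs)
            continue
        regimen_has_biologic = any(vocab.is_biologic(x) for x in current)
        all_new_biologic = all(vocab.is_biologic(x[0]) for x in new_drugs)
        if (
            cur_number not in (ADJUVANT_LINE_NUMBER, 1)
            and all_new_biologic
            and not regimen_has_biologic
        ):
            for drug, _ in new_drugs:
                additions.append((d, drug))
            update_efd(d, drugs)
            continue
        close_line(d, "new_drug")
        open_line(d, drugs)

    close_line(min(running_efd, data_end), "data_end")
    return lines


def completion_status(
    line: TherapyLine, following_line_exists: bool, data_end: date,
    margin_days: int = 60,
) -> tuple[bool, bool]:
    """Return ``(completed, evaluable_for_transition)`` for one line.

    Evaluability needs strictly more than ``margin_days`` of data after the
    line's end (or an observed next line); completion of all therapy needs
    ``margin_days`` or more between the expected final dose date and
    ``data_end``.
    """
    evaluable = following_line_exists or (data_end - line.end_date).days > margin_days
    completed = (data_end - line.expected_final_dose_date).days >= margin_days
    return completed, evaluable


def annotate_lines(lines: list[TherapyLine], data_end: date,
                   config: LineConfig | None = None) -> list[TherapyLine]:
    """Set completed/evaluable/transitioned flags on a derived sequence."""
    config = config or LineConfig()
    out = []
    for i, line in enumerate(lines):
        has_next = i + 1 < len(lines)
        completed, evaluable = completion_status(
            line, has_next, data_end, config.completion_margin_days
        )
        out.append(
            replace(line, completed=completed, evaluable_for_transition=evaluable,
                    transitioned=has_next)
        )
    return out


def lines_to_frame(lines_by_patient: dict[str, list[TherapyLine]],
                   vocab: DrugVocabulary) -> pd.DataFrame:
    """Flatten derived lines to one row per line, for CSV export."""
    records = []
    for pid, lines in lines_by_patient.items():
        for line in lines:
            label = line.regimen.label(vocab)
            records.append(
                {
                    "patient_id": pid,
                    "line": line.line_label,
                    "start_date": line.start_date,
                    "end_date": line.end_date,
                    "end_reason": line.end_reason,
                    "regimen": label.display,
                    "backbone": label.backbone,
                    "drugs": "|".join(sorted(line.regimen.all_drugs)),
                    "additions": "|".join(f"{d}:{drug}" for d, drug in line.regimen.additions),
                    "expected_final_dose_date": line.expected_final_dose_date,
                    "duration_days": line.duration_days,
                    "completed": line.completed,
                    "evaluable_for_transition": line.evaluable_for_transition,
                    "transitioned": line.transitioned,
                }
            )
    columns = ["patient_id", "line", "start_date", "end_date", "end_reason", "regimen",
               "backbone", "drugs", "additions", "expected_final_dose_date",
               "duration_days", "completed", "evaluable_for_transition", "transitioned"]
    if not records:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame.from_records(records)[columns].sort_values(
        ["patient_id", "start_date"], kind="mergesort"
    ).reset_index(drop=True)
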