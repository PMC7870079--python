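"""Derive therapy lines from a small hand-written prescription history.

Shows the three end rules in action: a new-drug switch, the biologic
addition exception for second-line chemotherapy-only regimens, and
censoring at the end of available data.
"""

from datetime import date, timedelta

import pandas as pd

from crclot import DrugVocabulary, derive_lines

vocab = DrugVocabulary.default()
d0 = date(2017, 3, 1)

rows = []
# first line: FOLFOX + bevacizumab, 6 biweekly cycles
for c in range(6):
    for drug in ("fluorouracil", "leucovorin", "oxaliplatin", "bevacizumab"):
        rows.append((d0 + timedelta(days=14 * c), drug))
# second line from day 120: FOLFIRI without a biologic ...
for c in range(8):
    for drug in ("fluorouracil", "leucovorin", "irinotecan"):
        rows.append((d0 + timedelta(days=120 + 14 * c), drug))
# ... with ramucirumab added on day 148 (an addition, not a new line)
rows.append((d0 + timedelta(days=148), "ramucirumab"))

rx = pd.DataFrame([{"patient_id": "case", "date": d, "drug_id": drug,
                    "dose": None, "route": "intravenous", "days_supplied": None}
                   for d, drug in rows])

for line in derive_lines(rx, anchor_date=d0, data_end=date(2018, 6, 1),
                         vocab=vocab, first_line_number=1):
    label = line.regimen.label(vocab)
    print(f"line {line.line_label}: {line.start_date} .. {line.end_date} "
          f"[{line.end_reason}]  regimen {label.display} "
          f"({line.duration_days} days)")
# Expect two lines: FOLFOX+BEV ending at the FOLFIRI switch (new_drug),
# then FOLFIRI with the ramucirumab addition, censored at data end.
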