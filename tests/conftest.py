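from datetime import date, timedelta

import pandas as pd
import pytest

from crclot.io import make_bundle
from crclot.vocab import DrugVocabulary


@pytest.fixture(scope="session")
def vocab():
    return DrugVocabulary.default()


def rx_frame(rows):
    """Prescription rows as (date, drug_id[, dose[, days_supplied]]) tuples."""
    cols = ["patient_id", "date", "drug_id", "dose", "route", "days_supplied"]
    if not rows:
        return pd.DataFrame(columns=cols)
    out = []
    for r in rows:
        d, drug = r[0], r[1]
        dose = r[2] if len(r) > 2 else None
        supplied = r[3] if len(r) > 3 else None
        out.append({"patient_id": "P1", "date": d, "drug_id": drug,
                    "dose": dose, "route": "intravenous", "days_supplied": supplied})
    return pd.DataFrame(out)


def day(n: int) -> date:
    """Day-offset dates anchored to a fixed in-window origin."""
    return date(2017, 1, 1) + timedelta(days=n)


@pytest.fixture
def tiny_bundle():
    """One hospital, two patients, a handful of events of every kind."""
    return make_bundle(
        patients=[
            {"patient_id": "P1", "sex": "male", "birth_year": 1955,
             "hospital_id": "H1", "data_end": date(2019, 12, 31)},
            {"patient_id": "P2", "sex": "female", "birth_year": 1948,
             "hospital_id": "H1", "data_end": date(2019, 6, 30)},
        ],
        hospitals=[{"hospital_id": "H1", "bed_class": "200-499",
                    "designated_cancer": True}],
        diagnoses=[
            {"patient_id": "P1", "date": date(2016, 12, 1), "icd10": "C18.2",
             "confirmed": True},
            {"patient_id": "P2", "date": date(2017, 2, 1), "icd10": "C20",
             "confirmed": True},
        ],
        prescriptions=[
            {"patient_id": "P1", "date": date(2017, 3, 1), "drug_id": "bevacizumab",
             "dose": 300.0, "route": "intravenous", "days_supplied": None},
            {"patient_id": "P1", "date": date(2017, 3, 1), "drug_id": "fluorouracil",
             "dose": 2400.0, "route": "intravenous", "days_supplied": None},
            {"patient_id": "P2", "date": date(2017, 4, 1), "drug_id": "capecitabine",
             "dose": None, "route": "oral", "days_supplied": 21},
        ],
        procedures=[{"patient_id": "P2", "date": date(2017, 3, 1),
                     "kind": "colorectal_resection"}],
        assessments=[
            {"patient_id": "P1", "date": date(2017, 2, 20), "kind": "bmi",
             "value": "21.5"},
            {"patient_id": "P1", "date": date(2017, 2, 20), "kind": "barthel",
             "value": "10;5;5;10;10;10;10;15;15;10"},
        ],
    )
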