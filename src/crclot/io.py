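"""Claims data model: six delimited tables, reading, writing and validation.

A claims bundle mirrors the shape of a hospital-based administrative
database: per-patient demographics with an explicit ``data_end`` (the final
date of data provided by the hospital, which the 60-day completion rule
needs), hospital attributes, confirmed-diagnosis events (ICD-10),
drug-prescription events, procedure events and functional/anthropometric
assessments.  All dates are ISO-8601 calendar dates and all interval
arithmetic downstream is in integer days.

Rows with a ``confirmed`` flag of False are retained on disk but ignored by
every downstream selection rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": ["patient_id", "sex", "birth_year", "hospital_id", "data_end"],
    "hospitals": ["hospital_id", "bed_class", "designated_cancer"],
    "diagnoses": ["patient_id", "date", "icd10", "confirmed"],
    "prescriptions": ["patient_id", "date", "drug_id", "dose", "route", "days_supplied"],
    "procedures": ["patient_id", "date", "kind"],
    "assessments": ["patient_id", "date", "kind", "value"],
}

DATE_COLUMNS = {"patients": ["data_end"], "diagnoses": ["date"],
                "prescriptions": ["date"], "procedures": ["date"], "assessments": ["date"]}

BED_CLASSES = ("<200", "200-499", ">=500")
PROCEDURE_KINDS = ("colorectal_resection", "proteinuria_qualitative", "proteinuria_quantitative")
ASSESSMENT_KINDS = ("bmi", "barthel")
SEXES = ("male", "female")
ROUTES = ("oral", "intravenous")

_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")

#: maximum score per Barthel ADL item, in fixed order (total 100)
BARTHEL_ITEM_MAX = (10, 5, 5, 10, 10, 10, 10, 15, 15, 10)


class BundleValidationError(ValueError):
    """A bundle violates a schema or referential-integrity invariant."""


@dataclass
class ClaimsBundle:
    patients: pd.DataFrame
    hospitals: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    procedures: pd.DataFrame
    assessments: pd.DataFrame
    #: per-table count of rows dropped at read time for unparseable dates
    rejected_rows: dict[str, int] = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_COLUMNS}

    def data_end(self, patient_id: str) -> date:
        sub = self.patients.loc[self.patients["patient_id"] == patient_id, "data_end"]
        if sub.empty:
            raise KeyError(f"unknown patient_id {patient_id!r}")
        return sub.iloc[0]


def parse_barthel(value: str) -> list[int]:
    """Parse the ';'-separated 10-item Barthel vector stored in ``value``."""
    items = [int(x) for x in str(value).split(";")]
    if len(items) != len(BARTHEL_ITEM_MAX):
        raise ValueError(f"Barthel vector needs {len(BARTHEL_ITEM_MAX)} items, got {len(items)}")
    return items


def barthel_total(value: str) -> int:
    return sum(parse_barthel(value))


def _empty_table(name: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[name]})


def _canonicalize(df: pd.DataFrame, name: str) -> pd.DataFrame:
    """Fix column order, dtypes and row order so equality is well defined."""
    df = df.copy()
    for col in TABLE_COLUMNS[name]:
        if col not in df.columns:
            raise BundleValidationError(f"{name}: missing column {col!r}")
    df = df[TABLE_COLUMNS[name]]
    if name == "patients":
        df["birth_year"] = df["birth_year"].astype("Int64")
    if name == "prescriptions":
        df["dose"] = pd.to_numeric(df["dose"], errors="coerce").astype("Float64")
        df["days_supplied"] = pd.to_numeric(df["days_supplied"], errors="coerce").astype("Int64")
    if name == "assessments":
        df["value"] = df["value"].astype(str)
    for col in ("confirmed", "designated_cancer"):
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: v if isinstance(v, bool) else str(v).strip().lower() == "true"
            )
    sort_cols = [c for c in TABLE_COLUMNS[name] if c not in ("dose", "days_supplied", "value")]
    df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    return df


def _parse_dates(df: pd.DataFrame, name: str) -> tuple[pd.DataFrame, int]:
    n_rejected = 0
    for col in DATE_COLUMNS.get(name, []):
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if name == "patients" and bad.any():
            raise BundleValidationError(
                f"patients: unparseable data_end for patient rows {df.index[bad].tolist()}"
            )
        n_rejected += int(bad.sum() + df[col].isna().sum())
        df = df.loc[parsed.notna()].copy()
        df[col] = parsed.loc[parsed.notna()].dt.date
    return df, n_rejected


def validate_bundle(bundle: ClaimsBundle, vocab=None) -> None:
    """Raise :class:`BundleValidationError` on the first violated invariant."""
    pat = bundle.patients
    if pat["patient_id"].duplicated().any():
        dups = pat.loc[pat["patient_id"].duplicated(), "patient_id"].tolist()
        raise BundleValidationError(f"patients: duplicate patient_id {dups}")
    hosp = bundle.hospitals
    if hosp["hospital_id"].duplicated().any():
        raise BundleValidationError("hospitals: duplicate hospital_id")
    bad_sex = set(pat["sex"]) - set(SEXES)
    if bad_sex:
        raise BundleValidationError(f"patients: invalid sex values {sorted(bad_sex)}")
    bad_bed = set(hosp["bed_class"]) - set(BED_CLASSES)
    if bad_bed:
        raise BundleValidationError(f"hospitals: invalid bed_class values {sorted(bad_bed)}")

    known_patients = set(pat["patient_id"])
    known_hospitals = set(hosp["hospital_id"])
    missing_h = set(pat["hospital_id"]) - known_hospitals
    if missing_h:
        raise BundleValidationError(f"patients: unresolvable hospital_id {sorted(missing_h)}")

    data_end = dict(zip(pat["patient_id"], pat["data_end"]))
    for name in ("diagnoses", "prescriptions", "procedures", "assessments"):
        df = getattr(bundle, name)
        if df.empty:
            continue
        orphans = set(df["patient_id"]) - known_patients
        if orphans:
            raise BundleValidationError(f"{name}: unresolvable patient_id {sorted(orphans)}")
        late = df["date"] > df["patient_id"].map(data_end)
        if late.any():
            rows = df.loc[late, ["patient_id", "date"]].head(5).to_dict("records")
            raise BundleValidationError(f"{name}: event dated after patient data_end: {rows}")

    dx = bundle.diagnoses
    if not dx.empty:
        bad = ~dx["icd10"].astype(str).str.match(_ICD10_RE)
        if bad.any():
            raise BundleValidationError(
                f"diagnoses: malformed ICD-10 codes {dx.loc[bad, 'icd10'].unique().tolist()}"
            )
    rx = bundle.prescriptions
    if not rx.empty:
        bad_dose = rx["dose"].notna() & (rx["dose"] <= 0)
        if bad_dose.any():
            raise BundleValidationError("prescriptions: dose must be > 0 when present")
        bad_route = ~rx["route"].isin(ROUTES)
        if bad_route.any():
            raise BundleValidationError(
                f"prescriptions: invalid route {rx.loc[bad_route, 'route'].unique().tolist()}"
            )
        if vocab is not None:
            unknown = [d for d in rx["drug_id"].unique() if d not in vocab]
            if unknown:
                raise BundleValidationError(f"prescriptions: unknown drug_id {sorted(unknown)}")
    proc = bundle.procedures
    if not proc.empty and (~proc["kind"].isin(PROCEDURE_KINDS)).any():
        raise BundleValidationError("procedures: kind outside the closed set")
    ass = bundle.assessments
    if not ass.empty:
        if (~ass["kind"].isin(ASSESSMENT_KINDS)).any():
            raise BundleValidationError("assessments: kind outside the closed set")
        for _, row in ass.iterrows():
            if row["kind"] == "bmi":
                v = float(row["value"])
                if not (5.0 < v < 80.0):
                    raise BundleValidationError(f"assessments: BMI {v} outside (5, 80)")
            else:
                try:
                    items = parse_barthel(row["value"])
                except ValueError as exc:
                    raise BundleValidationError(f"assessments: {exc}") from None
                for item, cap in zip(items, BARTHEL_ITEM_MAX):
                    if not (0 <= item <= cap):
                        raise BundleValidationError(
                            f"assessments: Barthel item {item} outside [0, {cap}]"
                        )


def read_bundle(directory: str | Path, vocab=None) -> ClaimsBundle:
    """Read and validate the six-table bundle stored in ``directory``.

    Event rows with unparseable dates are dropped and counted in
    ``bundle.rejected_rows``; everything else that violates an invariant is
    fatal.
    """
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    rejected: dict[str, int] = {}
    for name in TABLE_COLUMNS:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"bundle is missing required file {path}")
        df = pd.read_csv(path, dtype={"value": str, "patient_id": str, "hospital_id": str,
                                      "drug_id": str, "icd10": str})
        if df.empty:
            df = _empty_table(name)
        df, n_rej = _parse_dates(df, name)
        if n_rej:
            rejected[name] = n_rej
        tables[name] = _canonicalize(df, name)
    bundle = ClaimsBundle(**tables, rejected_rows=rejected)
    validate_bundle(bundle, vocab=vocab)
    return bundle


def write_bundle(bundle: ClaimsBundle, directory: str | Path) -> list[Path]:
    """Write the six CSV files with stable column order and ISO-8601 dates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in TABLE_COLUMNS:
        df = _canonicalize(getattr(bundle, name), name)
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False, date_format="%Y-%m-%d")
        written.append(path)
    return written


def bundles_equal(a: ClaimsBundle, b: ClaimsBundle) -> bool:
    return all(
        _canonicalize(getattr(a, n), n).equals(_canonicalize(getattr(b, n), n))
        for n in TABLE_COLUMNS
    )


def make_bundle(patients=None, hospitals=None, diagnoses=None, prescriptions=None,
                procedures=None, assessments=None, validate: bool = True,
                vocab=None) -> ClaimsBundle:
    """Build a bundle from partial tables (lists of dicts or DataFrames)."""
    def tbl(obj, name):
        if obj is None:
            return _empty_table(name)
        df = pd.DataFrame(obj)
        for col in TABLE_COLUMNS[name]:
            if col not in df.columns:
                df[col] = pd.NA if col in ("dose", "days_supplied") else None
        return _canonicalize(df, name)

    bundle = ClaimsBundle(
        patients=tbl(patients, "patients"),
        hospitals=tbl(hospitals, "hospitals"),
        diagnoses=tbl(diagnoses, "diagnoses"),
        prescriptions=tbl(prescriptions, "prescriptions"),
        procedures=tbl(procedures, "procedures"),
        assessments=tbl(assessments, "assessments"),
    )
    if validate:
        validate_bundle(bundle, vocab=vocab)
    return bundle
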