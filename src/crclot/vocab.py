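"""Antitumor drug vocabulary and regimen naming.

The vocabulary covers the systemic-therapy drugs recommended for advanced
colorectal cancer by the Japanese (JSCCR) guidelines -- cytotoxic agents
(fluoropyrimidines, oxaliplatin, irinotecan, FTD/TPI), antiangiogenic
antibodies (bevacizumab, ramucirumab, aflibercept beta), anti-EGFR
antibodies (cetuximab, panitumumab) and other targeted agents -- plus the
concomitant-drug classes the covariate stage needs (antihypertensives,
anticholinergics, anticoagulants) and leucovorin, which modulates 5-FU but
never counts as an antitumor drug on its own.

Regimen names (FOLFOX, FOLFIRI, CAPOX, ...) are assigned by exact-set match
of the *non-biologic antitumor* drug set against a backbone dictionary;
leucovorin is displayed inside the classic names but never distinguishes
backbones.  Biologics are appended as an ordered suffix (BEV < RAM < AFL <
CET < PANI).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

ANTITUMOR_CLASSES = frozenset(
    {
        "fluoropyrimidine_oral",
        "fluoropyrimidine_iv",
        "oxaliplatin",
        "irinotecan",
        "ftd_tpi",
        "antiangiogenic",
        "anti_egfr",
        "other_targeted",
    }
)

FLUOROPYRIMIDINE_CLASSES = frozenset({"fluoropyrimidine_oral", "fluoropyrimidine_iv"})

#: display codes for the biologic suffix, also its fixed ordering
BIOLOGIC_CODES = {
    "bevacizumab": "BEV",
    "ramucirumab": "RAM",
    "aflibercept_beta": "AFL",
    "cetuximab": "CET",
    "panitumumab": "PANI",
}
BIOLOGIC_ORDER = tuple(BIOLOGIC_CODES)

ANTIANGIOGENIC_DRUGS = ("bevacizumab", "ramucirumab", "aflibercept_beta")
ANTI_EGFR_DRUGS = ("cetuximab", "panitumumab")
#: antibodies that anchor the first-line population
FIRST_LINE_MAB_DRUGS = ("bevacizumab", "cetuximab", "panitumumab")

#: backbone dictionary keyed by the frozenset of non-biologic antitumor drugs
_BACKBONES = {
    frozenset({"fluorouracil", "oxaliplatin"}): "FOLFOX",
    frozenset({"capecitabine", "oxaliplatin"}): "CAPOX",
    frozenset({"fluorouracil", "irinotecan"}): "FOLFIRI",
    frozenset({"fluorouracil", "oxaliplatin", "irinotecan"}): "FOLFOXIRI",
    frozenset({"s1", "oxaliplatin"}): "SOX",
    frozenset({"s1", "irinotecan"}): "IRIS",
    frozenset({"capecitabine"}): "CAPE",
    frozenset({"s1"}): "S-1",
    frozenset({"fluorouracil"}): "5-FU",
    frozenset({"uft"}): "UFT",
    frozenset({"trifluridine_tipiracil"}): "FTD/TPI",
    frozenset({"irinotecan"}): "IRI",
}


class UnknownDrugError(KeyError):
    """Raised when a drug_id is not present in the vocabulary."""


@dataclass(frozen=True)
class DrugEntry:
    drug_id: str
    canonical_name: str
    drug_class: str
    is_biologic: bool
    default_cycle_days: int

    @property
    def is_antitumor(self) -> bool:
        return self.drug_class in ANTITUMOR_CLASSES


@dataclass(frozen=True)
class RegimenLabel:
    """A named regimen: chemotherapy backbone plus ordered biologic suffix."""

    backbone: str
    biologics: tuple[str, ...]
    raw_drug_set: frozenset[str]

    @property
    def multi_biologic(self) -> bool:
        """More than one biologic in the same regimen window; unusual, kept and flagged."""
        return len(self.biologics) > 1

    @property
    def display(self) -> str:
        if not self.biologics:
            return self.backbone
        suffix = "+".join(BIOLOGIC_CODES[b] for b in self.biologics)
        return f"{self.backbone}+{suffix}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display


class DrugVocabulary:
    """Lookup table of :class:`DrugEntry` rows, loaded from a CSV file.

    The packaged default can be extended or replaced via :meth:`from_csv`.
    """

    def __init__(self, entries: Iterable[DrugEntry]):
        self._entries: dict[str, DrugEntry] = {}
        for e in entries:
            if e.drug_id in self._entries:
                raise ValueError(f"duplicate drug_id {e.drug_id!r} in vocabulary")
            self._entries[e.drug_id] = e

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugVocabulary":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    DrugEntry(
                        drug_id=row["drug_id"],
                        canonical_name=row["canonical_name"],
                        drug_class=row["drug_class"],
                        is_biologic=row["is_biologic"].strip().lower() == "true",
                        default_cycle_days=int(row["default_cycle_days"]),
                    )
                )
        return cls(entries)

    @classmethod
    def default(cls) -> "DrugVocabulary":
        ref = resources.files("crclot").joinpath("data/drug_vocabulary.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def get(self, drug_id: str) -> DrugEntry:
        try:
            return self._entries[drug_id]
        except KeyError:
            raise UnknownDrugError(f"unknown drug_id {drug_id!r}") from None

    # classify_drug is the documented operation name; get() is the short form
    classify_drug = get

    def drug_class(self, drug_id: str) -> str:
        return self.get(drug_id).drug_class

    def is_antitumor(self, drug_id: str) -> bool:
        return self.get(drug_id).is_antitumor

    def is_biologic(self, drug_id: str) -> bool:
        return self.get(drug_id).is_biologic

    def ids_of_class(self, drug_class: str) -> frozenset[str]:
        return frozenset(e.drug_id for e in self if e.drug_class == drug_class)

    def antitumor_ids(self) -> frozenset[str]:
        return frozenset(e.drug_id for e in self if e.is_antitumor)


def name_regimen(drug_ids: Iterable[str], vocab: DrugVocabulary) -> RegimenLabel:
    """Name the regimen formed by ``drug_ids`` (any iterable; order-free).

    The backbone is determined solely by the set of non-biologic antitumor
    drugs; leucovorin and concomitant drugs are retained in the raw set but
    never change the backbone.  Unmatched combinations map to ``OTHER``.
    """
    raw = frozenset(drug_ids)
    if not raw:
        raise ValueError("cannot name a regimen from an empty drug set")
    entries = [vocab.get(d) for d in sorted(raw)]
    chemo = frozenset(e.drug_id for e in entries if e.is_antitumor and not e.is_biologic)
    biologics = tuple(
        b for b in BIOLOGIC_ORDER if b in raw and vocab.get(b).is_biologic
    )
    backbone = _BACKBONES.get(chemo, "OTHER") if chemo else "OTHER"
    return RegimenLabel(backbone=backbone, biologics=biologics, raw_drug_set=raw)


def regimen_group(label: RegimenLabel, vocab: DrugVocabulary) -> str:
    """Coarse grouping used for the from->to sequence flow tables.

    Oxaliplatin-and-irinotecan regimens (FOLFOXIRI and unnamed combinations
    containing both) are reported under a combined group of their own.
    """
    chemo = {
        d
        for d in label.raw_drug_set
        if vocab.get(d).is_antitumor and not vocab.get(d).is_biologic
    }
    classes = {vocab.drug_class(d) for d in chemo}
    has_ox = "oxaliplatin" in classes
    has_iri = "irinotecan" in classes
    if has_ox and has_iri:
        return "oxaliplatin_irinotecan_based"
    if has_ox:
        return "oxaliplatin_based"
    if has_iri:
        return "irinotecan_based"
    if len(chemo) == 1 and classes <= FLUOROPYRIMIDINE_CLASSES:
        return "fluoropyrimidine_monotherapy"
    return "other"
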