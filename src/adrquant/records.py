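"""Record schemas and file I/O.

Spontaneous adverse-drug-event (ADE) reports are carried as pydantic
models and serialized as JSONL (one report per line, preceded by a
schema-version header line). An openFDA-dialect JSON array reader is
provided for FAERS-style exports. Prescription records travel as CSV.

The drug dictionary (canonical id, synonyms, product codes, ATC code)
and the ADR ontology (preferred term id, synonyms, system organ class)
back the normalization steps of the qualification stage.
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .vocab import Outcome

SCHEMA_VERSION = 1

# ---------------------------------------------------------------------------
# report records
# ---------------------------------------------------------------------------


class DrugMention(BaseModel):
    """One raw drug mention inside a report."""

    name: str
    product_code: Optional[str] = None
    single_ingredient: bool = True
    small_molecule: bool = True
    # filled by normalization
    drug_id: Optional[str] = None
    resolution: Optional[str] = None  # product_code | exact | cleaned
    unresolved_reason: Optional[str] = None


class ADRMention(BaseModel):
    """One raw adverse-reaction mention with its treatment outcome."""

    term: str
    soc: Optional[str] = None
    outcome: Optional[Outcome] = None
    # filled by normalization
    pt_id: Optional[str] = None
    unresolved_reason: Optional[str] = None


class ADEReport(BaseModel):
    """One spontaneous adverse-drug-event report."""

    report_id: str
    reporter_class: Literal["professional", "nonprofessional"]
    drugs: list[DrugMention]
    adrs: list[ADRMention]


class PrescriptionRecord(BaseModel):
    """One person-weighted prescription event (survey-style)."""

    raw_name: str
    product_code: Optional[str] = None
    year: int
    person_weight: float = Field(gt=0)


PRESCRIPTION_COLUMNS = ["raw_name", "product_code", "year", "person_weight"]


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------


def write_reports_jsonl(reports: Iterable[ADEReport], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        header = {"schema_version": SCHEMA_VERSION, "kind": "ade_reports"}
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for rep in reports:
            fh.write(rep.model_dump_json(exclude_none=True) + "\n")


def read_reports_jsonl(path: str | Path) -> list[ADEReport]:
    reports: list[ADEReport] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if "kind" in obj and "report_id" not in obj:
                continue  # schema header
            reports.append(ADEReport.model_validate(obj))
    return reports


_OPENFDA_PROFESSIONAL_CODES = {"1", "2", "3"}  # physician/pharmacist/other HCP
_OPENFDA_OUTCOMES = {
    "1": Outcome.RECOVERED,
    "2": Outcome.RECOVERING,
    "3": Outcome.NOT_RECOVERED,
    "4": Outcome.SEQUELAE,
    "5": Outcome.FATAL,
    # "6" = unknown -> missing
}


def read_reports_openfda(path: str | Path) -> list[ADEReport]:
    """Read an openFDA-dialect JSON array of safety reports.

    Only the fields the pipeline consumes are interpreted: report id,
    reporter qualification, drug mentions (name, product code), and
    reactions (preferred term, optional SOC, treatment outcome code).
    """
    with Path(path).open("r", encoding="utf-8") as fh:
        payload = json.load(fh)
    raw_reports = payload["results"] if isinstance(payload, dict) else payload

    reports: list[ADEReport] = []
    for raw in raw_reports:
        qual = str(raw.get("primarysource", {}).get("qualification", ""))
        reporter = (
            "professional" if qual in _OPENFDA_PROFESSIONAL_CODES else "nonprofessional"
        )
        patient = raw.get("patient", {})
        drugs = []
        for d in patient.get("drug", []):
            ndcs = d.get("openfda", {}).get("product_ndc", [])
            drugs.append(
                DrugMention(
                    name=d.get("medicinalproduct", ""),
                    product_code=ndcs[0] if ndcs else None,
                )
            )
        adrs = []
        for r in patient.get("reaction", []):
            adrs.append(
                ADRMention(
                    term=r.get("reactionmeddrapt", ""),
                    soc=r.get("reactionsoc"),
                    outcome=_OPENFDA_OUTCOMES.get(str(r.get("reactionoutcome", ""))),
                )
            )
        reports.append(
            ADEReport(
                report_id=str(raw.get("safetyreportid", "")),
                reporter_class=reporter,
                drugs=drugs,
                adrs=adrs,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# prescription I/O
# ---------------------------------------------------------------------------


def write_prescriptions_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write prescription records; deterministic float formatting so a
    fixed seed yields a byte-identical file."""
    df = df[PRESCRIPTION_COLUMNS]
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION} kind=prescriptions\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_prescriptions_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"product_code": "string"})
    missing = set(PRESCRIPTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"prescription CSV missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# drug dictionary
# ---------------------------------------------------------------------------

_DOSAGE_TOKEN = re.compile(r"^\d+(\.\d+)?(mg|mcg|g|ml|iu|%)?$")

DEFAULT_STOP_TOKENS: frozenset[str] = frozenset(
    {
        "mg", "mcg", "g", "ml", "iu",
        "tablet", "tablets", "capsule", "capsules", "caplet", "caplets",
        "chewable", "ophthalmic", "oral", "topical", "nasal",
        "solution", "suspension", "injection", "cream", "ointment",
        "syrup", "drops", "spray", "patch",
        "extended", "release", "er", "xr", "sr", "hcl",
        "coated", "film",
    }
)


def clean_drug_name(name: str, stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS) -> str:
    """Case-fold, drop dosage/form tokens, collapse whitespace."""
    tokens = re.split(r"[^a-z0-9.%]+", name.casefold())
    kept = [
        t for t in tokens
        if t and t not in stop_tokens and not _DOSAGE_TOKEN.match(t)
    ]
    return " ".join(kept)


class DrugEntry(BaseModel):
    drug_id: str
    name: str
    synonyms: list[str] = Field(default_factory=list)
    product_codes: list[str] = Field(default_factory=list)
    atc: Optional[str] = None

    @field_validator("synonyms")
    @classmethod
    def _include_name(cls, v, info):
        return v


class Resolution(BaseModel):
    drug_id: Optional[str] = None
    route: Optional[Literal["product_code", "exact", "cleaned"]] = None
    reason: Optional[str] = None  # why unresolved


class DrugDictionary:
    """Maps raw drug mentions to canonical ids via a three-route search:
    product-code lookup, exact synonym match, cleaned-name match."""

    def __init__(self, entries: Iterable[DrugEntry],
                 stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS):
        self.entries: dict[str, DrugEntry] = {e.drug_id: e for e in entries}
        self.stop_tokens = stop_tokens
        self._by_code: dict[str, str] = {}
        self._by_exact: dict[str, str] = {}
        self._by_clean: dict[str, set[str]] = {}
        for e in self.entries.values():
            for code in e.product_codes:
                self._by_code[code] = e.drug_id
            for syn in [e.name, *e.synonyms]:
                key = syn.casefold().strip()
                self._by_exact.setdefault(key, e.drug_id)
                ckey = clean_drug_name(syn, stop_tokens)
                if ckey:
                    self._by_clean.setdefault(ckey, set()).add(e.drug_id)

    def __len__(self) -> int:
        return len(self.entries)

    def atc_map(self) -> dict[str, Optional[str]]:
        return {d: e.atc for d, e in self.entries.items()}

    def resolve(self, name: str, product_code: Optional[str] = None) -> Resolution:
        if product_code and product_code in self._by_code:
            return Resolution(drug_id=self._by_code[product_code], route="product_code")
        key = name.casefold().strip()
        if key in self._by_exact:
            return Resolution(drug_id=self._by_exact[key], route="exact")
        ckey = clean_drug_name(name, self.stop_tokens)
        hits = self._by_clean.get(ckey, set())
        if len(hits) == 1:
            return Resolution(drug_id=next(iter(hits)), route="cleaned")
        if len(hits) > 1:
            return Resolution(reason=f"ambiguous cleaned-name match ({len(hits)} ids)")
        return Resolution(reason="no dictionary match")

    # -- serialization --
    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "kind": "drug_dictionary",
            "entries": [e.model_dump(exclude_none=True)
                        for e in sorted(self.entries.values(), key=lambda e: e.drug_id)],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "DrugDictionary":
        payload = json.loads(Path(path).read_text())
        return cls(DrugEntry.model_validate(e) for e in payload["entries"])


# ---------------------------------------------------------------------------
# ADR ontology
# ---------------------------------------------------------------------------


class ADRTerm(BaseModel):
    pt_id: str
    pt_name: str
    soc: Optional[str] = None
    synonyms: list[str] = Field(default_factory=list)


class ADROntology:
    """Preferred-term ontology: case-insensitive synonym resolution."""

    def __init__(self, terms: Iterable[ADRTerm]):
        self.terms: dict[str, ADRTerm] = {t.pt_id: t for t in terms}
        self._by_syn: dict[str, str] = {}
        for t in self.terms.values():
            for syn in [t.pt_name, *t.synonyms]:
                self._by_syn.setdefault(syn.casefold().strip(), t.pt_id)

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term: str) -> Optional[str]:
        return self._by_syn.get(term.casefold().strip())

    def soc_of(self, pt_id: str) -> Optional[str]:
        t = self.terms.get(pt_id)
        return t.soc if t else None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "kind": "adr_ontology",
            "terms": [t.model_dump(exclude_none=True)
                      for t in sorted(self.terms.values(), key=lambda t: t.pt_id)],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ADROntology":
        payload = json.loads(Path(path).read_text())
        return cls(ADRTerm.model_validate(t) for t in payload["terms"])


# ---------------------------------------------------------------------------
# expert grade table and target map
# ---------------------------------------------------------------------------


def write_grade_table(table: dict[str, set], path: str | Path) -> None:
    from .vocab import Grade

    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "grade_table",
        "grades": {pt: sorted(g.value for g in grades) for pt, grades in table.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_grade_table(path: str | Path) -> dict[str, set]:
    from .vocab import Grade

    payload = json.loads(Path(path).read_text())
    return {pt: {Grade(g) for g in grades} for pt, grades in payload["grades"].items()}


def write_target_map(target_map: dict[str, list[str]], path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "target_map",
        "targets": {d: sorted(ts) for d, ts in target_map.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_target_map(path: str | Path) -> dict[str, list[str]]:
    payload = json.loads(Path(path).read_text())
    return dict(payload["targets"])
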