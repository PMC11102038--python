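"""Seeded generators for FAERS/MEPS-like synthetic study data.

The generators emulate the statistical structure the pipeline consumes:

* spontaneous reports with one treatment-outcome code per ADR mention,
  thinned by severity-dependent underreporting (reporting probability
  0.23 for events whose drawn outcome is "resolved with sequelae" or
  "fatal", 0.06 otherwise — the 77%/94% underreporting rates);
* survey-style prescription records whose person weights sum to the
  true annual prescription volume per drug-year, with messy drug-name
  variants (dosage/form tokens) exercising the cleaned-name route;
* expert grade tables with controlled subset/overlap/disjoint mixes
  against a supplied model grading;
* drug->target maps, optionally with one target planted at a chosen
  odds ratio among the carriers of a given ADR.

Every generator is a pure function of its config (including the seed):
identical configs give byte-identical outputs. Ground truth is emitted
for every simulated drug and pair so recovery can be checked.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigError
from .records import (
    ADEReport,
    ADRMention,
    ADROntology,
    ADRTerm,
    DrugDictionary,
    DrugEntry,
    DrugMention,
    PRESCRIPTION_COLUMNS,
    SCHEMA_VERSION,
)
from .vocab import DEFAULT_EXCLUDED_SOCS, OUTCOMES, SERIOUS_OUTCOMES, Grade, GRADES

logger = logging.getLogger(__name__)

# distinct RNG streams per generator, spawned from the config seed
_STREAM_TRUTH = 0
_STREAM_REPORTS = 1
_STREAM_PRESCRIPTIONS = 2
_STREAM_GRADES = 3
_STREAM_TARGETS = 4

_BENIGN_SOCS = (
    "nervous system disorders",
    "gastrointestinal disorders",
    "cardiac disorders",
    "skin and subcutaneous tissue disorders",
    "vascular disorders",
)
_EXCLUDED_SOCS = tuple(sorted(DEFAULT_EXCLUDED_SOCS))
_NOISE_SUFFIXES = (" 10 mg tablets", " 25 mg", " oral solution", " 5 mg capsules")
_ATC2_POOL = ("A10", "C07", "J01", "L01", "N02", "R03")


class SimConfig(BaseModel):
    """Study conditions for the synthetic FAERS/MEPS-like corpus.

    ``incidence_matrix`` (per-prescription probability of each drug-ADR
    event) and ``outcome_profile`` (probability vector over the five
    outcomes per pair) may be given explicitly; left as None they are
    drawn once from the seed: half the pairs causally linked with
    incidence 10^U(-4,-2), outcome profiles Dirichlet-distributed and
    skewed toward recovery.
    """

    n_drugs: int = Field(default=20, ge=0)
    n_adrs: int = Field(default=30, ge=0)
    n_patients_per_drug_year: int = Field(default=10_000, ge=0)
    years: list[int] = Field(default_factory=lambda: list(range(2012, 2020)))
    incidence_matrix: Optional[list[list[float]]] = None
    outcome_profile: Optional[list] = None  # n_drugs x n_adrs x 5, or one 5-vector
    reporting_rate_serious: float = Field(default=0.23, ge=0.0, le=1.0)
    reporting_rate_other: float = Field(default=0.06, ge=0.0, le=1.0)
    nonprofessional_fraction: float = Field(default=0.10, ge=0.0, le=1.0)
    excluded_soc_fraction: float = Field(default=0.10, ge=0.0, le=1.0)
    multi_ingredient_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    missing_outcome_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    name_noise: bool = True
    expert_fractions: tuple[float, float, float] = (0.5, 0.3, 0.2)
    n_targets: int = Field(default=40, ge=0)
    max_targets_per_drug: int = Field(default=4, ge=0)
    seed: int = 0

    @field_validator("incidence_matrix")
    @classmethod
    def _probabilities(cls, v):
        if v is not None:
            arr = np.asarray(v, dtype=float)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("incidence values must lie in [0, 1]")
        return v

    @field_validator("expert_fractions")
    @classmethod
    def _fractions(cls, v):
        if any(f < 0 for f in v) or sum(v) > 1 + 1e-9:
            raise ValueError("expert fractions must be non-negative and sum to <= 1")
        return v

    @model_validator(mode="after")
    def _outcome_profiles_sum(self):
        if self.outcome_profile is not None:
            arr = np.asarray(self.outcome_profile, dtype=float)
            if arr.shape[-1] != 5 or np.any(arr < 0):
                raise ValueError("outcome profiles must be 5 non-negative probabilities")
            if not np.allclose(arr.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError("each outcome profile must sum to 1")
        return self


class GroundTruth(BaseModel):
    """Recovery targets keyed identically to the emitted data sets."""

    true_incidence: dict[str, dict[str, float]] = Field(default_factory=dict)
    true_outcome_profile: dict[str, dict[str, list[float]]] = Field(default_factory=dict)
    true_annual_prescriptions: dict[str, float] = Field(default_factory=dict)
    # generated (pre-thinning) event counts per reporting stratum
    n_events_serious: int = 0
    n_events_other: int = 0
    n_reports: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {"schema_version": SCHEMA_VERSION, "kind": "ground_truth"}
        payload.update(self.model_dump())
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload.pop("schema_version", None)
        payload.pop("kind", None)
        return cls.model_validate(payload)


# ---------------------------------------------------------------------------
# deterministic catalogs
# ---------------------------------------------------------------------------


def drug_ids(config: SimConfig) -> list[str]:
    return [f"D{i:03d}" for i in range(config.n_drugs)]


def adr_ids(config: SimConfig) -> list[str]:
    return [f"ADR{j:03d}" for j in range(config.n_adrs)]


def drug_catalog(config: SimConfig) -> DrugDictionary:
    """Dictionary for the simulated drugs: canonical name, a brand-like
    synonym, one product code, and an ATC code (shared level-2 classes
    so ATC inference has company)."""
    entries = []
    for i, did in enumerate(drug_ids(config)):
        name = f"drugbase{i:03d}"
        atc2 = _ATC2_POOL[i % len(_ATC2_POOL)]
        entries.append(
            DrugEntry(
                drug_id=did,
                name=name,
                synonyms=[f"bramark{i:03d}"],
                product_codes=[f"PC-{i:04d}"],
                atc=f"{atc2}AA{i:02d}",
            )
        )
    return DrugDictionary(entries)


def adr_catalog(config: SimConfig) -> ADROntology:
    """Ontology for the simulated ADR preferred terms; a deterministic
    fraction of terms sits under excluded (non-drug-induced) SOCs."""
    rng = np.random.default_rng([config.seed, _STREAM_TRUTH, 1])
    n = config.n_adrs
    n_excl = int(round(config.excluded_soc_fraction * n))
    excluded_mask = np.zeros(n, dtype=bool)
    if n_excl:
        excluded_mask[rng.permutation(n)[:n_excl]] = True
    terms = []
    for j, pt in enumerate(adr_ids(config)):
        if excluded_mask[j]:
            soc = _EXCLUDED_SOCS[j % len(_EXCLUDED_SOCS)]
        else:
            soc = _BENIGN_SOCS[j % len(_BENIGN_SOCS)]
        terms.append(
            ADRTerm(
                pt_id=pt,
                pt_name=f"Reaction {j:03d}",
                soc=soc,
                synonyms=[f"reaction-{j:03d}"],
            )
        )
    return ADROntology(terms)


# ---------------------------------------------------------------------------
# ground truth materialization
# ---------------------------------------------------------------------------


def _materialize_truth(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Incidence matrix and outcome profiles, drawn once from the seed
    when not supplied explicitly."""
    nd, na = config.n_drugs, config.n_adrs
    rng = np.random.default_rng([config.seed, _STREAM_TRUTH])
    if config.incidence_matrix is not None:
        q = np.asarray(config.incidence_matrix, dtype=float)
        if q.shape != (nd, na):
            raise ConfigError(f"incidence matrix must be {nd}x{na}, got {q.shape}")
        rng.random((nd, na))  # keep stream alignment regardless of source
    else:
        linked = rng.random((nd, na)) < 0.5
        q = 10.0 ** rng.uniform(-4.0, -2.0, size=(nd, na)) * linked
    if config.outcome_profile is not None:
        prof = np.asarray(config.outcome_profile, dtype=float)
        if prof.shape == (5,):
            prof = np.broadcast_to(prof, (nd, na, 5)).copy()
        elif prof.shape != (nd, na, 5):
            raise ConfigError(
                f"outcome profiles must be (5,) or {nd}x{na}x5, got {prof.shape}"
            )
    else:
        # skewed toward recovery; fatal outcomes rare
        prof = rng.dirichlet((5.0, 2.0, 1.5, 0.8, 0.7), size=(nd, na))
    return q, prof


def ground_truth(config: SimConfig) -> GroundTruth:
    q, prof = _materialize_truth(config)
    dids, aids = drug_ids(config), adr_ids(config)
    return GroundTruth(
        true_incidence={
            d: {a: float(q[i, j]) for j, a in enumerate(aids)}
            for i, d in enumerate(dids)
        },
        true_outcome_profile={
            d: {a: [float(x) for x in prof[i, j]] for j, a in enumerate(aids)}
            for i, d in enumerate(dids)
        },
        true_annual_prescriptions={
            d: float(config.n_patients_per_drug_year) for d in dids
        },
    )


# ---------------------------------------------------------------------------
# report generation
# ---------------------------------------------------------------------------


def generate_ade_reports(config: SimConfig) -> tuple[list[ADEReport], GroundTruth]:
    """Simulate spontaneous reports with severity-stratified thinning.

    Per drug-ADR pair and year, the number of true events is binomial in
    the prescription count and the pair's incidence; each event draws an
    outcome from the pair's profile and is reported with probability
    ``reporting_rate_serious`` when the outcome is O4/O5, else
    ``reporting_rate_other``. Each reported event becomes one report
    (one drug, one ADR, one outcome code, possibly masked as missing).
    """
    truth = ground_truth(config)
    if config.n_drugs == 0 or config.n_adrs == 0 or not config.years:
        logger.warning("empty simulation (no drugs, ADRs, or years): no reports")
        return [], truth

    q, prof = _materialize_truth(config)
    rng = np.random.default_rng([config.seed, _STREAM_REPORTS])
    dictionary = drug_catalog(config)
    ontology = adr_catalog(config)
    dids, aids = drug_ids(config), adr_ids(config)

    reports: list[ADEReport] = []
    n_serious = 0
    n_other = 0
    rid = 0
    for i, did in enumerate(dids):
        entry = dictionary.entries[did]
        for j, aid in enumerate(aids):
            if q[i, j] == 0.0:
                continue
            term_entry = ontology.terms[aid]
            for year in config.years:
                n_events = rng.binomial(config.n_patients_per_drug_year, q[i, j])
                if n_events == 0:
                    continue
                by_outcome = rng.multinomial(n_events, prof[i, j])
                for k, outcome in enumerate(OUTCOMES):
                    serious = outcome in SERIOUS_OUTCOMES
                    if serious:
                        n_serious += int(by_outcome[k])
                    else:
                        n_other += int(by_outcome[k])
                    rate = (
                        config.reporting_rate_serious
                        if serious
                        else config.reporting_rate_other
                    )
                    n_rep = rng.binomial(by_outcome[k], rate)
                    for _ in range(n_rep):
                        reports.append(
                            _make_report(rng, config, entry, term_entry, outcome, rid)
                        )
                        rid += 1
    truth = truth.model_copy(
        update={
            "n_events_serious": n_serious,
            "n_events_other": n_other,
            "n_reports": len(reports),
        }
    )
    return reports, truth


def _make_report(rng, config, entry, term_entry, outcome, rid) -> ADEReport:
    reporter = (
        "nonprofessional"
        if rng.random() < config.nonprofessional_fraction
        else "professional"
    )
    name = entry.name if rng.random() < 0.6 else entry.synonyms[0]
    if config.name_noise and rng.random() < 0.3:
        name = name + _NOISE_SUFFIXES[rng.integers(len(_NOISE_SUFFIXES))]
    code = entry.product_codes[0] if rng.random() < 0.5 else None
    single = rng.random() >= config.multi_ingredient_fraction
    term = (
        term_entry.pt_name if rng.random() < 0.7 else term_entry.synonyms[0]
    )
    oc = None if rng.random() < config.missing_outcome_fraction else outcome
    return ADEReport(
        report_id=f"R{rid:08d}",
        reporter_class=reporter,
        drugs=[
            DrugMention(
                name=name,
                product_code=code,
                single_ingredient=bool(single),
                small_molecule=True,
            )
        ],
        adrs=[ADRMention(term=term, soc=term_entry.soc, outcome=oc)],
    )


# ---------------------------------------------------------------------------
# prescription generation
# ---------------------------------------------------------------------------


def generate_prescriptions(config: SimConfig) -> pd.DataFrame:
    """Simulate survey-style prescription records.

    Each drug-year's true volume (``n_patients_per_drug_year``) is split
    across 1-4 records with Dirichlet shares, so the person-weight sum
    per drug-year equals the true annual prescription count. With
    ``name_noise`` on, a fraction of raw names carries dosage/form
    tokens; product codes are present on roughly half the records.
    """
    rng = np.random.default_rng([config.seed, _STREAM_PRESCRIPTIONS])
    dictionary = drug_catalog(config)
    rows = []
    for did in drug_ids(config):
        entry = dictionary.entries[did]
        volume = float(config.n_patients_per_drug_year)
        for year in config.years:
            m = int(rng.integers(1, 5))
            shares = rng.dirichlet(np.ones(m)) if m > 1 else np.array([1.0])
            for w in shares * volume:
                name = entry.name if rng.random() < 0.5 else entry.synonyms[0]
                if config.name_noise and rng.random() < 0.4:
                    name = name + _NOISE_SUFFIXES[rng.integers(len(_NOISE_SUFFIXES))]
                code = entry.product_codes[0] if rng.random() < 0.5 else None
                rows.append(
                    {
                        "raw_name": name,
                        "product_code": code,
                        "year": year,
                        "person_weight": float(w),
                    }
                )
    return pd.DataFrame(rows, columns=PRESCRIPTION_COLUMNS)


# ---------------------------------------------------------------------------
# expert grade table
# ---------------------------------------------------------------------------


def generate_expert_grades(
    config: SimConfig, model_grades: Mapping[str, set]
) -> dict[str, set]:
    """Emit an expert grade table with a controlled consistency mix.

    ``expert_fractions = (subset, overlap, disjoint)`` of the supplied
    model grading's terms receive expert grade sets that are a subset of
    the model's set, overlap it partially, or are disjoint from it;
    counts follow a largest-remainder allocation (so fractions
    (0.5, 0.3, 0.2) at n = 100 give exactly 50/30/20). Terms beyond the
    fractions' sum are omitted (not mutual). Terms whose model set spans
    all five grades admit only the subset state and are allocated there
    first.
    """
    fracs = config.expert_fractions
    rng = np.random.default_rng([config.seed, _STREAM_GRADES])
    pts = sorted(model_grades)
    n = len(pts)
    counts = _largest_remainder(n, fracs)

    full = [pt for pt in pts if len(model_grades[pt]) == 5]
    if len(full) > counts[0]:
        raise ConfigError(
            "model grade sets spanning all five grades exceed the subset quota; "
            "overlap/disjoint states are infeasible for them"
        )
    rest = [pt for pt in pts if len(model_grades[pt]) < 5]
    rest = [rest[k] for k in rng.permutation(len(rest))]

    states = (
        ["subset"] * (counts[0] - len(full))
        + ["overlap"] * counts[1]
        + ["disjoint"] * counts[2]
    )
    assignment = {pt: "subset" for pt in full}
    assignment.update(dict(zip(rest, states)))

    table: dict[str, set] = {}
    for pt in pts:
        if pt not in assignment:
            continue  # beyond the fractions' sum: not a mutual term
        g = sorted(model_grades[pt], key=lambda x: x.index)
        comp = sorted(set(GRADES) - set(g), key=lambda x: x.index)
        state = assignment[pt]
        if state == "subset":
            size = int(rng.integers(1, len(g) + 1))
            chosen = rng.choice(len(g), size=size, replace=False)
            table[pt] = {g[c] for c in chosen}
        elif state == "overlap":
            table[pt] = {
                g[int(rng.integers(len(g)))],
                comp[int(rng.integers(len(comp)))],
            }
        else:  # disjoint
            size = int(rng.integers(1, min(2, len(comp)) + 1))
            chosen = rng.choice(len(comp), size=size, replace=False)
            table[pt] = {comp[c] for c in chosen}
    return table


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    base = [int(np.floor(x)) for x in raw]
    short = int(round(n * sum(fractions))) - sum(base)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(raw[i] - base[i]), i)
    )
    for i in remainders[:short]:
        base[i] += 1
    return base


# ---------------------------------------------------------------------------
# target map
# ---------------------------------------------------------------------------


class PlantedTarget(BaseModel):
    """One target planted at a chosen odds ratio among carrier drugs."""

    target_id: str = "T_PLANT"
    carrier_drugs: set[str]
    odds_ratio: float = Field(gt=0)
    baseline_rate: float = Field(default=0.3, gt=0, lt=1)

    def carrier_rate(self) -> float:
        """Membership probability among carriers giving the planted OR
        against the baseline odds."""
        q0 = self.baseline_rate
        return self.odds_ratio * q0 / (1.0 - q0 + self.odds_ratio * q0)


def generate_target_map(
    config: SimConfig,
    drugs: Optional[Sequence[str]] = None,
    planted: Optional[PlantedTarget] = None,
) -> dict[str, list[str]]:
    """Assign 1..k therapeutic targets per drug from a shared pool.

    With ``planted``, the planted target is attached to each drug with
    probability ``baseline_rate`` (non-carriers) or the odds-scaled rate
    (carriers), so the drug-level target/ADR odds ratio equals the
    configured value in expectation. ``max_targets_per_drug = 0`` or an
    empty pool yields an empty map.
    """
    rng = np.random.default_rng([config.seed, _STREAM_TARGETS])
    drugs = list(drugs) if drugs is not None else drug_ids(config)
    if config.max_targets_per_drug == 0 or config.n_targets == 0 or not drugs:
        return {}
    pool = [f"T{t:03d}" for t in range(config.n_targets)]
    if planted is not None and planted.target_id in pool:
        pool.remove(planted.target_id)

    out: dict[str, list[str]] = {}
    for d in drugs:
        k = int(rng.integers(1, config.max_targets_per_drug + 1))
        k = min(k, len(pool))
        chosen = sorted(pool[c] for c in rng.choice(len(pool), size=k, replace=False))
        out[d] = chosen
    if planted is not None:
        q0, q1 = planted.baseline_rate, planted.carrier_rate()
        for d in drugs:
            p = q1 if d in planted.carrier_drugs else q0
            if rng.random() < p:
                out[d] = sorted([*out[d], planted.target_id])
    return out
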