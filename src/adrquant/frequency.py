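"""Underreporting-corrected ADR frequency estimation.

The per-prescription occurrence rate of an ADR under a drug is

    Freq = count(D-A) / ((1 - URR) * AAP * yr)

where count(D-A) is the pair's report count, AAP the drug's average
annual prescriptions (person-weighted survey volume), yr the length of
the reporting window in years (default 8), and URR the underreporting
rate: 0.77 for very serious ADRs (grades life-threatening and death),
0.94 otherwise — i.e. reporting rates of 23% and 6%.

AAPs are computed directly from prescription records where the drug
name resolves; drugs absent from the survey inherit the mean (or
median) of the direct AAPs in their ATC level-2 (therapeutic subgroup)
class; drugs with no ATC code or an empty class stay unavailable.
"""
from __future__ import annotations

import logging
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .errors import ConfigError, RangeError
from .records import DrugDictionary
from .vocab import FATAL_GRADES, Grade

logger = logging.getLogger(__name__)

#: Left-closed/right-open frequency class edges (per-prescription rate).
FREQUENCY_EDGES = (1e-4, 1e-3, 1e-2, 1e-1)
FREQUENCY_CLASSES = ("very_rare", "rare", "uncommon", "common", "very_common")


class URRConfig(BaseModel):
    """Underreporting rates by severity stratum."""

    very_serious: float = Field(default=0.77, ge=0.0, lt=1.0)
    other: float = Field(default=0.94, ge=0.0, lt=1.0)

    def for_grade(self, grade: Grade) -> float:
        return self.very_serious if grade in FATAL_GRADES else self.other


class AAPEntry(BaseModel):
    drug_id: str
    aap: Optional[float] = None
    source: Literal["direct", "atc_inferred", "unavailable"] = "unavailable"


class FrequencyResult(BaseModel):
    frequency: float = Field(ge=0.0)
    freq_class: str
    urr_used: float


def compute_aap(
    prescriptions: pd.DataFrame,
    dictionary: DrugDictionary,
    period: list[int],
    audit: Optional[dict] = None,
) -> pd.DataFrame:
    """Average annual prescriptions per drug over the period.

    AAP = (sum of person weights of the drug's records in period years)
    / (number of years in the period). Every dictionary drug gets a row;
    drugs with no resolvable records are marked unavailable at this
    stage (ATC inference may fill them in later). Unresolvable raw
    names are counted in the audit, not silently dropped.
    """
    if not period:
        raise ConfigError("AAP period must contain at least one year")
    n_years = len(set(period))
    period_set = set(period)

    weights: dict[str, float] = {}
    unresolved = 0
    in_period = prescriptions[prescriptions["year"].isin(period_set)]
    # resolve distinct (name, code) combinations once, then aggregate
    key_cols = ["raw_name", "product_code"]
    combos = in_period[key_cols].drop_duplicates()
    resolution = {}
    for name, code in combos.itertuples(index=False):
        code = None if pd.isna(code) else code
        resolution[(name, code)] = dictionary.resolve(name, code).drug_id
    for name, code, w in in_period[
        ["raw_name", "product_code", "person_weight"]
    ].itertuples(index=False):
        code = None if pd.isna(code) else code
        did = resolution[(name, code)]
        if did is None:
            unresolved += 1
            continue
        weights[did] = weights.get(did, 0.0) + float(w)

    rows = []
    for did in sorted(dictionary.entries):
        if did in weights:
            rows.append({"drug_id": did, "aap": weights[did] / n_years,
                         "source": "direct"})
        else:
            rows.append({"drug_id": did, "aap": np.nan, "source": "unavailable"})
    if audit is not None:
        audit["aap"] = {
            "records_in_period": int(len(in_period)),
            "unresolved_records": unresolved,
            "direct_drugs": sum(1 for r in rows if r["source"] == "direct"),
        }
    return pd.DataFrame(rows, columns=["drug_id", "aap", "source"])


def infer_aap_by_atc(
    aap: pd.DataFrame,
    atc_map: Mapping[str, Optional[str]],
    method: Literal["mean", "median"] = "mean",
    audit: Optional[dict] = None,
) -> pd.DataFrame:
    """Fill unavailable AAPs from the drug's ATC level-2 class.

    The inferred value is the mean (default) or median of the direct
    AAPs sharing the first three ATC characters. Drugs without an ATC
    code, or whose class holds no directly estimated drug, remain
    unavailable (and are logged, mirroring unestimable drugs).
    """
    aap = aap.copy()
    direct = aap[aap["source"] == "direct"]
    class_values: dict[str, list[float]] = {}
    for did, value in direct[["drug_id", "aap"]].itertuples(index=False):
        atc = atc_map.get(did)
        if atc:
            class_values.setdefault(atc[:3], []).append(float(value))
    agg = np.mean if method == "mean" else np.median

    n_inferred = 0
    unavailable = []
    for idx in aap.index[aap["source"] == "unavailable"]:
        did = aap.at[idx, "drug_id"]
        atc = atc_map.get(did)
        values = class_values.get(atc[:3]) if atc else None
        if values:
            aap.at[idx, "aap"] = float(agg(values))
            aap.at[idx, "source"] = "atc_inferred"
            n_inferred += 1
        else:
            unavailable.append(did)
    if unavailable:
        logger.info("AAP unavailable for %d drugs: %s", len(unavailable), unavailable)
    if audit is not None:
        audit["aap_atc_inference"] = {
            "inferred": n_inferred,
            "unavailable": len(unavailable),
            "unavailable_drugs": unavailable,
        }
    return aap


def frequency_class(frequency: float) -> str:
    """Class of a per-prescription rate; bins are left-closed/right-open
    at 1e-4, 1e-3, 1e-2, 1e-1."""
    if frequency < 0:
        raise RangeError("frequency must be non-negative")
    # rates within 1e-9 (relative) below an edge belong to the edge's bin,
    # so estimates like 24/(0.06*50000*8) land on 1e-3 despite float noise
    idx = int(np.searchsorted(FREQUENCY_EDGES, frequency * (1 + 1e-9), side="right"))
    return FREQUENCY_CLASSES[idx]


def estimate_frequency(
    n_reports: int,
    grade: Grade,
    aap: float,
    yr: float = 8.0,
    urr: Optional[URRConfig] = None,
) -> FrequencyResult:
    """Frequency of one drug-ADR pair with underreporting correction.

    Estimates above 1 are clamped to 1 with a warning (the corrected
    count estimator is not probability-bounded).
    """
    urr = urr or URRConfig()
    if aap is None or not np.isfinite(aap) or aap <= 0:
        raise ConfigError("AAP unavailable: frequency cannot be estimated")
    if yr <= 0:
        raise ConfigError("yr must be positive")
    if n_reports < 0:
        raise RangeError("report count must be non-negative")
    u = urr.for_grade(grade)
    freq = n_reports / ((1.0 - u) * aap * yr)
    if freq > 1.0:
        logger.warning("frequency %.3g clamped to 1", freq)
        freq = 1.0
    return FrequencyResult(frequency=freq, freq_class=frequency_class(freq), urr_used=u)


def add_frequency(
    pairs: pd.DataFrame,
    aap: pd.DataFrame,
    yr: float = 8.0,
    urr: Optional[URRConfig] = None,
    audit: Optional[dict] = None,
) -> pd.DataFrame:
    """Append aap, urr_used, frequency, freq_class to a graded pair
    table. Pairs of drugs with unavailable AAP are dropped with an
    audited count (no frequency can be assigned)."""
    urr = urr or URRConfig()
    pairs = pairs.merge(aap[["drug_id", "aap", "source"]], on="drug_id", how="left")
    available = pairs["aap"].notna() & (pairs["source"] != "unavailable")
    dropped = int((~available).sum())
    pairs = pairs[available].reset_index(drop=True)

    u = pairs["severity_grade"].map(
        lambda g: urr.for_grade(Grade(g))
    ).to_numpy(dtype=float)
    freq = pairs["n_reports"].to_numpy(dtype=float) / (
        (1.0 - u) * pairs["aap"].to_numpy(dtype=float) * yr
    )
    n_clamped = int((freq > 1.0).sum())
    if n_clamped:
        logger.warning("%d frequencies clamped to 1", n_clamped)
    freq = np.minimum(freq, 1.0)
    pairs["urr_used"] = u
    pairs["frequency"] = freq
    pairs["freq_class"] = [frequency_class(f) for f in freq]
    if audit is not None:
        audit["frequency"] = {
            "pairs_without_aap": dropped,
            "pairs_with_frequency": int(len(pairs)),
            "clamped": n_clamped,
        }
    return pairs
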