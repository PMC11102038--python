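"""Drug-ADR-target association analysis.

Scored drug-ADR pairs are crossed with each drug's therapeutic targets
to give distinct drug-ADR-target entries. Singleton entries — an ADR
linked to exactly one target, or a target linked to exactly one ADR
(on the pre-exclusion counts, one pass) — are removed. Association
strength between an ADR (or the fatal-grade ADR group) and a target is
the odds ratio over entries:

    a = entries with the ADR and the target      b = target, other ADRs
    c = ADR, other targets                       d = neither

with the Woolf 95% CI; significance is two-sided (CI excludes 1).
Entries are placed in four mechanism zones by OR and ADR frequency
(high-OR/low-frequency on-target dose-controlled ADRs through
low-OR/high-frequency off-target ones), and targets enriched among
fatal-grade ADRs beyond an OR threshold are screened out as fatal-risk
targets.
"""
from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .disproportionality import ror_stats
from .errors import ConfigError
from .vocab import FATAL_GRADES

logger = logging.getLogger(__name__)

ENTRY_COLUMNS = ["drug_id", "adr_id", "target_id", "grade", "frequency"]

#: Zone thresholds (OR, frequency). The zone architecture is defined
#: graphically in the source analysis; these numeric defaults are this
#: package's own and should be set explicitly for real analyses.
DEFAULT_ZONE_THRESHOLDS = (2.0, 1e-3)


class ORResult(BaseModel):
    or_value: float
    ci_low: float
    ci_high: float
    significant: bool


def build_entries(
    pairs: pd.DataFrame,
    target_map: Mapping[str, Sequence[str]],
    audit: Optional[dict] = None,
) -> pd.DataFrame:
    """Cross pairs with their drugs' targets; drop singleton entries.

    Singleton exclusion runs once on the initial entry set: ADRs
    associated with exactly one distinct target, and targets associated
    with exactly one distinct ADR, are removed.
    """
    rows = []
    for row in pairs.itertuples(index=False):
        for t in target_map.get(row.drug_id, ()):
            rows.append(
                {
                    "drug_id": row.drug_id,
                    "adr_id": row.adr_id,
                    "target_id": t,
                    "grade": getattr(row, "severity_grade", None),
                    "frequency": getattr(row, "frequency", np.nan),
                }
            )
    entries = pd.DataFrame(rows, columns=ENTRY_COLUMNS).drop_duplicates(
        subset=["drug_id", "adr_id", "target_id"]
    )
    n_initial = len(entries)
    if n_initial:
        targets_per_adr = entries.groupby("adr_id")["target_id"].nunique()
        adrs_per_target = entries.groupby("target_id")["adr_id"].nunique()
        singleton_adrs = set(targets_per_adr.index[targets_per_adr == 1])
        singleton_targets = set(adrs_per_target.index[adrs_per_target == 1])
        keep = ~(
            entries["adr_id"].isin(singleton_adrs)
            | entries["target_id"].isin(singleton_targets)
        )
        entries = entries[keep]
    entries = entries.reset_index(drop=True)
    if audit is not None:
        audit["entries"] = {
            "initial": n_initial,
            "after_singleton_exclusion": int(len(entries)),
        }
    return entries


def _entry_contingency(
    entries: pd.DataFrame, adr_mask: np.ndarray, target_id: str
) -> tuple[int, int, int, int]:
    t_mask = (entries["target_id"] == target_id).to_numpy()
    a = int((adr_mask & t_mask).sum())
    b = int((~adr_mask & t_mask).sum())
    c = int((adr_mask & ~t_mask).sum())
    d = int((~adr_mask & ~t_mask).sum())
    return a, b, c, d


def _adr_mask(entries: pd.DataFrame, adr_selector: str) -> np.ndarray:
    """Entries matching a single ADR id, or the fatal-grade group for
    the selector ``"fatal"``."""
    if adr_selector == "fatal":
        fatal = {g.value for g in FATAL_GRADES}
        return entries["grade"].isin(fatal).to_numpy()
    return (entries["adr_id"] == adr_selector).to_numpy()


def target_or(
    entries: pd.DataFrame, adr_selector: str, target_id: str, alpha: float = 0.05
) -> ORResult:
    """Odds ratio between an ADR (or the fatal group) and one target."""
    a, b, c, d = _entry_contingency(entries, _adr_mask(entries, adr_selector), target_id)
    out = ror_stats(a, b, c, d, zero_correction=True, alpha=alpha)
    return ORResult(
        or_value=float(out["ror"]),
        ci_low=float(out["ci_low"]),
        ci_high=float(out["ci_high"]),
        significant=bool(out["significant_two_sided"]),
    )


def all_target_ors(entries: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """OR for every observed (ADR, target) combination, vectorized."""
    n = len(entries)
    if n == 0:
        return pd.DataFrame(
            columns=["adr_id", "target_id", "or_value", "ci_low", "ci_high",
                     "significant"]
        )
    n_at = entries.groupby(["adr_id", "target_id"]).size().rename("a").reset_index()
    n_a = entries.groupby("adr_id").size()
    n_t = entries.groupby("target_id").size()
    a = n_at["a"].to_numpy()
    b = n_t.loc[n_at["target_id"]].to_numpy() - a
    c = n_a.loc[n_at["adr_id"]].to_numpy() - a
    d = n - a - b - c
    out = ror_stats(a, b, c, d, zero_correction=True, alpha=alpha)
    n_at["or_value"] = out["ror"]
    n_at["ci_low"] = out["ci_low"]
    n_at["ci_high"] = out["ci_high"]
    n_at["significant"] = out["significant_two_sided"]
    return n_at.drop(columns="a")


def zone_assign(
    or_value: float,
    frequency: float,
    thresholds: tuple[float, float] = DEFAULT_ZONE_THRESHOLDS,
) -> int:
    """Mechanism zone of an ADR-target relation.

    zone 1: OR >= or_t, frequency < freq_t (on-target, dose-controlled)
    zone 2: OR >= or_t, frequency >= freq_t (dose-dependent)
    zone 3: OR < or_t, frequency < freq_t
    zone 4: OR < or_t, frequency >= freq_t (off-target)
    """
    or_t, freq_t = thresholds
    if or_t <= 0 or freq_t <= 0:
        raise ConfigError("zone thresholds must be positive")
    high_or = or_value >= or_t
    high_freq = frequency >= freq_t
    if high_or:
        return 2 if high_freq else 1
    return 4 if high_freq else 3


def fatal_risk_targets(
    entries: pd.DataFrame,
    or_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Targets whose OR against the fatal-ADR group (grades
    life-threatening or death) exceeds the threshold.

    Returns one row per flagged target with its OR, CI, significance
    and the drugs carrying it, sorted by OR descending (ties broken by
    target id). No fatal-grade entries yields an empty result with a
    logged notice.
    """
    cols = ["target_id", "or_value", "ci_low", "ci_high", "significant", "drugs"]
    fatal_mask = _adr_mask(entries, "fatal")
    if len(entries) == 0 or not fatal_mask.any():
        logger.info("no fatal-grade entries: no fatal-risk targets")
        return pd.DataFrame(columns=cols)

    n = len(entries)
    t_fatal = entries[fatal_mask].groupby("target_id").size()
    t_all = entries.groupby("target_id").size()
    n_fatal = int(fatal_mask.sum())
    targets = t_all.index.to_numpy()
    a = t_fatal.reindex(targets, fill_value=0).to_numpy()
    b = t_all.to_numpy() - a
    c = n_fatal - a
    d = n - a - b - c
    out = ror_stats(a, b, c, d, zero_correction=True, alpha=alpha)

    df = pd.DataFrame(
        {
            "target_id": targets,
            "or_value": out["ror"],
            "ci_low": out["ci_low"],
            "ci_high": out["ci_high"],
            "significant": out["significant_two_sided"],
        }
    )
    df = df[df["or_value"] > or_threshold]
    drug_lists = (
        entries[fatal_mask].groupby("target_id")["drug_id"].agg(lambda s: sorted(set(s)))
    )
    df["drugs"] = df["target_id"].map(drug_lists)
    df = df.sort_values(
        ["or_value", "target_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return df[cols]
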