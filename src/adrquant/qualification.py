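"""Report qualification, identity normalization and pair-table building.

Raw spontaneous reports are filtered to "qualified" reports: duplicate
report ids dropped, nonprofessional reporters excluded, adverse-event
mentions under non-drug-induced system organ classes removed (the whole
report only when no mention survives), and reports restricted to
single-ingredient small-molecule drugs. Drug mentions are resolved to
canonical ids through the dictionary's three routes and ADR terms to
preferred-term ids through the ontology. Qualified, normalized reports
are then aggregated into one row per observed drug-ADR pair with
outcome tallies and the report-level 2x2 contingency cells.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, Field

from .records import ADEReport, ADROntology, DrugDictionary
from .vocab import DEFAULT_EXCLUDED_SOCS, OUTCOMES

logger = logging.getLogger(__name__)

PAIR_COLUMNS = [
    "drug_id", "adr_id", "n_reports",
    "o1", "o2", "o3", "o4", "o5",
    "a", "b", "c", "d",
]


class QualificationRules(BaseModel):
    """Filters applied to raw reports and to the aggregated pair table."""

    excluded_socs: frozenset[str] = DEFAULT_EXCLUDED_SOCS
    professional_only: bool = True
    single_ingredient_small_molecule_only: bool = True
    min_adr_reports: int = Field(default=2, ge=0)
    min_drug_reports: int = Field(default=26, ge=0)
    min_pair_reports: int = Field(default=2, ge=0)


def qualify_reports(
    reports: Iterable[ADEReport],
    rules: Optional[QualificationRules] = None,
    audit: Optional[dict] = None,
) -> list[ADEReport]:
    """Filter raw reports down to qualified reports.

    Idempotent: applying the filter to its own output is the identity.
    Per-rule attrition counts are logged and, when ``audit`` is given,
    recorded under ``audit["qualification"]``.
    """
    rules = rules or QualificationRules()
    counts = Counter()
    seen_ids: set[str] = set()
    out: list[ADEReport] = []

    for rep in reports:
        counts["input"] += 1
        if rep.report_id in seen_ids:
            counts["duplicate_id"] += 1
            continue
        seen_ids.add(rep.report_id)
        if rules.professional_only and rep.reporter_class != "professional":
            counts["nonprofessional"] += 1
            continue
        kept_adrs = [
            m for m in rep.adrs
            if m.soc is None or m.soc.casefold() not in rules.excluded_socs
        ]
        n_soc_dropped = len(rep.adrs) - len(kept_adrs)
        if not kept_adrs:
            counts["excluded_soc_only"] += 1
            continue
        if rules.single_ingredient_small_molecule_only and any(
            not (d.single_ingredient and d.small_molecule) for d in rep.drugs
        ):
            counts["non_single_ingredient_small_molecule"] += 1
            continue
        counts["soc_mentions_dropped"] += n_soc_dropped
        if n_soc_dropped:
            rep = rep.model_copy(update={"adrs": kept_adrs})
        out.append(rep)
        counts["qualified"] += 1

    logger.info("qualification attrition: %s", dict(counts))
    if audit is not None:
        audit["qualification"] = dict(counts)
    return out


def normalize_drugs(
    reports: Iterable[ADEReport],
    dictionary: DrugDictionary,
    audit: Optional[dict] = None,
) -> list[ADEReport]:
    """Resolve drug mentions to canonical ids.

    Resolution order: product-code lookup, exact synonym match, cleaned-
    name match. Unresolved mentions are flagged with a reason (including
    ambiguous cleaned-name hits) and retained for audit, never dropped.
    """
    counts = Counter()
    out: list[ADEReport] = []
    for rep in reports:
        new_drugs = []
        for m in rep.drugs:
            res = dictionary.resolve(m.name, m.product_code)
            new_drugs.append(
                m.model_copy(update={
                    "drug_id": res.drug_id,
                    "resolution": res.route,
                    "unresolved_reason": res.reason,
                })
            )
            counts[res.route or "unresolved"] += 1
        out.append(rep.model_copy(update={"drugs": new_drugs}))
    logger.info("drug normalization routes: %s", dict(counts))
    if audit is not None:
        audit["drug_normalization"] = dict(counts)
    return out


def normalize_adrs(
    reports: Iterable[ADEReport],
    ontology: ADROntology,
    audit: Optional[dict] = None,
) -> list[ADEReport]:
    """Resolve ADR terms to preferred-term ids (case-insensitive)."""
    counts = Counter()
    out: list[ADEReport] = []
    for rep in reports:
        new_adrs = []
        for m in rep.adrs:
            pt = ontology.resolve(m.term)
            new_adrs.append(
                m.model_copy(update={
                    "pt_id": pt,
                    "unresolved_reason": None if pt else "no ontology match",
                })
            )
            counts["resolved" if pt else "unresolved"] += 1
        out.append(rep.model_copy(update={"adrs": new_adrs}))
    logger.info("ADR normalization: %s", dict(counts))
    if audit is not None:
        audit["adr_normalization"] = dict(counts)
    return out


def build_pair_table(reports: list[ADEReport]) -> pd.DataFrame:
    """Aggregate normalized reports into one row per drug-ADR pair.

    Counting is at report granularity: a report mentioning a drug and an
    ADR contributes once to that pair's ``a`` cell however many times
    either is listed; a multi-ADR report contributes to every pair it
    supports. Outcomes are tallied from the per-ADR outcome codes of the
    contributing reports (a missing outcome still counts in ``a``). For
    each pair, a + b + c + d equals the number of qualified reports.
    """
    n_total = len(reports)
    pair_reports: dict[tuple[str, str], int] = Counter()
    pair_outcomes: dict[tuple[str, str], Counter] = defaultdict(Counter)
    drug_reports: Counter = Counter()
    adr_reports: Counter = Counter()

    for rep in reports:
        drugs = {m.drug_id for m in rep.drugs if m.drug_id}
        # one outcome per (report, PT): first non-missing code wins
        adr_outcome: dict[str, Optional[str]] = {}
        for m in rep.adrs:
            if not m.pt_id:
                continue
            if m.pt_id not in adr_outcome or (
                adr_outcome[m.pt_id] is None and m.outcome is not None
            ):
                adr_outcome[m.pt_id] = m.outcome.value if m.outcome else None
        for d in drugs:
            drug_reports[d] += 1
        for a in adr_outcome:
            adr_reports[a] += 1
        for d in drugs:
            for a, oc in adr_outcome.items():
                pair_reports[(d, a)] += 1
                if oc is not None:
                    pair_outcomes[(d, a)][oc] += 1

    rows = []
    for (d, adr), n in sorted(pair_reports.items()):
        oc = pair_outcomes[(d, adr)]
        a_cell = n
        b_cell = drug_reports[d] - n
        c_cell = adr_reports[adr] - n
        d_cell = n_total - a_cell - b_cell - c_cell
        rows.append({
            "drug_id": d,
            "adr_id": adr,
            "n_reports": n,
            **{f"o{k + 1}": oc.get(OUTCOMES[k].value, 0) for k in range(5)},
            "a": a_cell,
            "b": b_cell,
            "c": c_cell,
            "d": d_cell,
        })
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def filter_by_support(
    pairs: pd.DataFrame,
    rules: Optional[QualificationRules] = None,
    audit: Optional[dict] = None,
) -> pd.DataFrame:
    """Discard sparsely supported rows: keep pairs whose ADR has at
    least ``min_adr_reports`` reports in total, whose drug has at least
    ``min_drug_reports``, and with at least ``min_pair_reports`` for the
    pair itself (>= semantics: a pair reported exactly twice survives
    the default threshold of 2). All totals are the pre-filter ones, so
    the outcome is independent of filter order."""
    rules = rules or QualificationRules()
    if pairs.empty:
        return pairs.copy()
    drug_totals = pairs["a"] + pairs["b"]  # reports mentioning the drug
    adr_totals = pairs["a"] + pairs["c"]  # reports mentioning the ADR
    keep = (
        (adr_totals >= rules.min_adr_reports)
        & (drug_totals >= rules.min_drug_reports)
        & (pairs["n_reports"] >= rules.min_pair_reports)
    )
    kept = pairs[keep].reset_index(drop=True)
    if audit is not None:
        audit["support_filter"] = {
            "input_pairs": int(len(pairs)),
            "retained": int(len(kept)),
            "removed": int(len(pairs) - len(kept)),
        }
    return kept
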