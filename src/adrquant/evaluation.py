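"""Consistency evaluation of model grades against an expert grade table.

An ADR preferred term may carry several model grades (one per drug it
is paired with) and several expert grades. On the terms shared by both
tables, each term is placed in exactly one of three states:

* consistent — the expert grades are fully matched or covered by the
  model grades (expert set is a subset of the model set);
* partially consistent — the sets overlap but the expert set is not
  covered;
* inconsistent — the sets are mutually exclusive.
"""
from __future__ import annotations

from enum import Enum
from typing import Mapping, Optional

import pandas as pd

from .vocab import Grade


class ConsistencyState(str, Enum):
    CONSISTENT = "consistent"
    PARTIALLY_CONSISTENT = "partially_consistent"
    INCONSISTENT = "inconsistent"


def mutual_terms(
    model_grades: Mapping[str, set],
    expert_grades: Mapping[str, set],
    audit: Optional[dict] = None,
) -> list[str]:
    """Preferred terms present in both grading tables (sorted)."""
    shared = sorted(set(model_grades) & set(expert_grades))
    if audit is not None:
        audit["mutual_terms"] = {
            "model_terms": len(model_grades),
            "expert_terms": len(expert_grades),
            "mutual": len(shared),
            "model_only": len(set(model_grades) - set(expert_grades)),
            "expert_only": len(set(expert_grades) - set(model_grades)),
        }
    return shared


def consistency_state(model: set, expert: set) -> ConsistencyState:
    """State of one term given its model and expert grade sets."""
    if not model or not expert:
        raise ValueError("grade sets must be non-empty")
    if not (model <= set(Grade)) or not (expert <= set(Grade)):
        raise ValueError("grade sets must draw from the five-grade vocabulary")
    if expert <= model:
        return ConsistencyState.CONSISTENT
    if model & expert:
        return ConsistencyState.PARTIALLY_CONSISTENT
    return ConsistencyState.INCONSISTENT


def model_grade_table(pairs: pd.DataFrame) -> dict[str, set]:
    """Model grading per preferred term: the union of severity grades
    over all its retained drug-ADR pairs."""
    out: dict[str, set] = {}
    for adr, grades in pairs.groupby("adr_id")["severity_grade"]:
        out[adr] = {Grade(g) for g in grades}
    return out


def evaluate(
    model_grades: Mapping[str, set],
    expert_grades: Mapping[str, set],
    audit: Optional[dict] = None,
) -> tuple[dict, pd.DataFrame]:
    """Summarize grade consistency over the mutual terms.

    Returns a summary (counts and percentages, 2 dp, per state; strict
    set equality is reported separately) and a per-term detail table.
    Zero mutual terms yields an explicit empty summary.
    """
    shared = mutual_terms(model_grades, expert_grades, audit=audit)
    rows = []
    for pt in shared:
        m, e = set(model_grades[pt]), set(expert_grades[pt])
        rows.append(
            {
                "pt_id": pt,
                "model_grades": ",".join(sorted(g.value for g in m)),
                "expert_grades": ",".join(sorted(g.value for g in e)),
                "state": consistency_state(m, e).value,
                "identical": m == e,
            }
        )
    detail = pd.DataFrame(
        rows, columns=["pt_id", "model_grades", "expert_grades", "state", "identical"]
    )
    n = len(detail)
    counts = {s.value: 0 for s in ConsistencyState}
    if n:
        counts.update(detail["state"].value_counts().to_dict())
    summary = {
        "mutual_terms": n,
        "counts": counts,
        "percentages": {
            s: (round(100.0 * c / n, 2) if n else 0.0) for s, c in counts.items()
        },
        "identical_sets": int(detail["identical"].sum()) if n else 0,
    }
    return summary, detail
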