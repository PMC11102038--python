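"""Penalized, outcome-weighted ADR severity scoring and grading.

For a drug-ADR pair with conditional treatment-outcome distribution
p = (p1..p5) over O1..O5 (recovered, recovering, not recovered,
resolved with sequelae, fatal), the severity score is

    score = sigma(ROR) * sum_k  w_k * p_k / log2(penalty_k + 1)

with penalties (5,4,3,2,1) — benign outcomes penalized hardest in a
reciprocal (logarithmic) manner — weights (1,2,3,4,5) emphasizing severe
outcomes, and sigma(ROR) = 1 / (1 + exp(-log2 ROR)) mapping the
association strength into (0.5, 1].

The five pure-outcome extreme cases (p_k = 1, sigma -> 1) yield the
analytic grade boundaries: 1/log2 6, 2/log2 5, 3/log2 4, 4/log2 3 and
5/log2 2, i.e. 0.387 / 0.861 / 1.500 / 2.524 / 5.000 at three decimals,
delimiting the mild, moderate, severe, life-threatening and death zones.
"""
from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigError, RangeError, UndefinedDistributionError
from .vocab import GRADES, Grade

N_OUTCOMES = 5
OUTCOME_COLUMNS = ["o1", "o2", "o3", "o4", "o5"]

#: Decimal precision at which scores and boundaries are compared; grade
#: boundary values are printed (and zone membership decided) at 3 dp.
BOUNDARY_DECIMALS = 3


class SeverityParams(BaseModel):
    """Penalty and weight vectors of the severity model (indexed O1..O5)."""

    penalty: tuple[int, int, int, int, int] = (5, 4, 3, 2, 1)
    weight: tuple[int, int, int, int, int] = (1, 2, 3, 4, 5)

    @field_validator("penalty", "weight")
    @classmethod
    def _positive(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("penalty and weight entries must be strictly positive")
        return v

    def unit_scores(self) -> np.ndarray:
        """Score of each pure-outcome extreme at sigma = 1."""
        pen = np.asarray(self.penalty, dtype=float)
        w = np.asarray(self.weight, dtype=float)
        return w / np.log2(pen + 1.0)


class GradeBoundaries(BaseModel):
    """Six ascending edges delimiting the five severity grades.

    Zone membership is decided on values rounded to ``decimals`` places
    (matching the printed three-decimal boundaries); intervals are
    lower-open/upper-closed, with 0 belonging to the mild zone.
    """

    edges: tuple[float, float, float, float, float, float]
    decimals: int = BOUNDARY_DECIMALS

    @model_validator(mode="after")
    def _ascending(self):
        e = self.edges
        if e[0] != 0.0:
            raise ValueError("lowest edge must be 0")
        if any(e[i] >= e[i + 1] for i in range(5)):
            raise ValueError("edges must be strictly increasing")
        return self

    def rounded(self) -> np.ndarray:
        return np.round(np.asarray(self.edges), self.decimals)

    def grade_of(self, score: float) -> Grade:
        edges = self.rounded()
        s = round(float(score), self.decimals)
        if s < edges[0] or s > edges[5]:
            raise RangeError(
                f"score {score} outside [{edges[0]}, {edges[5]}]"
            )
        if s == 0.0:
            return Grade.MILD
        idx = int(np.searchsorted(edges[1:5], s, side="left"))
        return GRADES[idx]


def association_factor(ror) -> float | np.ndarray:
    """Sigmoid-normalized association strength.

    sigma = 1 / (1 + exp(-log2 ROR)): 0.5 at ROR = 1, approaching 1 as
    ROR grows. Raises for non-positive ROR.
    """
    arr = np.asarray(ror, dtype=float)
    if np.any(arr <= 0):
        raise RangeError("association factor requires ROR > 0")
    with np.errstate(over="ignore"):
        sigma = 1.0 / (1.0 + np.exp(-np.log2(arr)))
    if np.ndim(ror) == 0:
        return float(sigma)
    return sigma


def outcome_distribution(counts) -> np.ndarray:
    """Conditional outcome probabilities p_k = n_k / sum(n).

    ``counts`` are the five outcome tallies at the chosen scope (one
    pair's reports, or all reports of the ADR pooled over drugs).
    Raises :class:`UndefinedDistributionError` when no outcome-bearing
    report exists.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (N_OUTCOMES,):
        raise ConfigError(f"expected {N_OUTCOMES} outcome counts, got {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("outcome counts must be non-negative")
    total = arr.sum()
    if total == 0:
        raise UndefinedDistributionError("no outcome-bearing reports")
    return arr / total


def severity_score(
    dist, sigma: float, params: Optional[SeverityParams] = None
) -> float:
    """Severity score for one outcome distribution and association factor."""
    params = params or SeverityParams()
    p = np.asarray(dist, dtype=float)
    if p.shape != (N_OUTCOMES,):
        raise ConfigError(f"expected {N_OUTCOMES} probabilities, got {p.shape}")
    if np.any(p < 0) or not math.isclose(float(p.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("outcome distribution must be non-negative and sum to 1")
    return float(sigma * (params.unit_scores() @ p))


def grade_boundaries(params: Optional[SeverityParams] = None) -> GradeBoundaries:
    """Derive the grade boundaries from the pure-outcome extreme cases.

    With the defaults this reproduces the printed 0.387 / 0.861 / 1.500 /
    2.524 / 5.000 edges. Parameterizations whose pure-outcome scores are
    not strictly increasing in outcome order are rejected: the grades
    would be ill-ordered.
    """
    params = params or SeverityParams()
    pure = params.unit_scores()
    if np.any(np.diff(pure) <= 0):
        raise ConfigError(
            "pure-outcome scores must increase strictly from recovered to fatal"
        )
    return GradeBoundaries(edges=(0.0, *map(float, pure)))


def assign_grade(score: float, boundaries: GradeBoundaries) -> Grade:
    """Grade of a score: the zone (edges[g-1], edges[g]] it falls in."""
    return boundaries.grade_of(score)


def score_pairs(
    pairs: pd.DataFrame,
    params: Optional[SeverityParams] = None,
    scope: Literal["per_pair", "per_adr"] = "per_pair",
    audit: Optional[dict] = None,
) -> pd.DataFrame:
    """Score a pair table: append sigma, severity_score, severity_grade.

    ``scope`` selects the conditioning of P(O_k | ADR): ``per_pair``
    uses only the pair's own reports (default), ``per_adr`` pools
    outcome counts over every drug of the ADR in the table. Pairs with
    no outcome-bearing reports cannot be scored and are dropped with an
    audited reason.
    """
    params = params or SeverityParams()
    if scope not in ("per_pair", "per_adr"):
        raise ConfigError(f"unknown scope {scope!r}")
    bounds = grade_boundaries(params)

    counts = pairs[OUTCOME_COLUMNS].to_numpy(dtype=float)
    if scope == "per_adr":
        pooled = pairs.groupby("adr_id")[OUTCOME_COLUMNS].transform("sum")
        counts = pooled.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    scorable = totals > 0

    pairs = pairs.copy()
    pairs["n_outcomes"] = totals.astype(int)
    unscorable = pairs[~scorable]
    pairs = pairs[scorable].reset_index(drop=True)
    counts = counts[scorable]
    p = counts / counts.sum(axis=1, keepdims=True)

    sigma = association_factor(pairs["ror"].to_numpy())
    base = p @ params.unit_scores()
    scores = sigma * base
    pairs["sigma"] = sigma
    pairs["severity_score"] = scores
    pairs["severity_grade"] = [bounds.grade_of(s).value for s in scores]
    if audit is not None:
        audit["severity"] = {
            "input_pairs": int(scorable.size),
            "scored": int(len(pairs)),
            "unscorable_no_outcomes": int(len(unscorable)),
            "scope": scope,
        }
    return pairs
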