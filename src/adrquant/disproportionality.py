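"""Reporting odds ratio (ROR) disproportionality statistics.

For a drug-ADR pair the 2x2 contingency table over qualified reports is

    a = reports with the drug and the ADR
    b = reports with the drug and other ADRs
    c = reports with other drugs and the ADR
    d = reports with other drugs and other ADRs

ROR = ad/bc; the confidence interval uses the Woolf log-normal
approximation exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).

A pair is flagged as a signal when ROR > 1 with a one-sided P < .05
against ROR <= 1 (z-test on ln ROR). The two-sided 95% CI is reported
alongside. With the Haldane-Anscombe correction enabled (default), 0.5
is added to every cell whenever any cell is zero.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel
from scipy import stats

from .errors import UndefinedResultError

Z_95 = float(stats.norm.ppf(0.975))  # 1.959964


class RORResult(BaseModel):
    ror: float
    ci_low: float
    ci_high: float
    p_value: float  # one-sided, H1: ROR > 1
    significant: bool


def ror_stats(
    a, b, c, d, zero_correction: bool = True, alpha: float = 0.05
) -> dict[str, np.ndarray]:
    """Vectorized ROR, Woolf 95% CI and one-/two-sided p-values.

    Accepts scalars or arrays of non-negative cell counts; NaN is
    returned where the point estimate is undefined (b*c == 0 with the
    correction disabled).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any((a < 0) | (b < 0) | (c < 0) | (d < 0)):
        raise ValueError("contingency cells must be non-negative")

    if zero_correction:
        zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        a = a + 0.5 * zero
        b = b + 0.5 * zero
        c = c + 0.5 * zero
        d = d + 0.5 * zero

    with np.errstate(divide="ignore", invalid="ignore"):
        ror = (a * d) / (b * c)
        log_ror = np.log(ror)
        se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
        ci_low = np.exp(log_ror - Z_95 * se)
        ci_high = np.exp(log_ror + Z_95 * se)
        z = log_ror / se
    undefined = ~np.isfinite(ror)
    ror = np.where(undefined, np.nan, ror)
    p_one = stats.norm.sf(z)  # H1: ROR > 1
    p_two = 2.0 * stats.norm.sf(np.abs(z))
    sig_one = (ror > 1.0) & (p_one < alpha)
    sig_two = p_two < alpha
    return {
        "ror": ror,
        "ci_low": np.where(undefined, np.nan, ci_low),
        "ci_high": np.where(undefined, np.nan, ci_high),
        "p_one": np.where(undefined, np.nan, p_one),
        "p_two": np.where(undefined, np.nan, p_two),
        "significant_one_sided": sig_one & ~undefined,
        "significant_two_sided": sig_two & ~undefined,
    }


def ror(
    contingency: tuple[float, float, float, float],
    zero_correction: bool = True,
    alpha: float = 0.05,
) -> RORResult:
    """ROR for a single 2x2 table.

    Raises :class:`UndefinedResultError` when b*c = 0 and the zero-cell
    correction is disabled (the point estimate would be infinite or 0/0).
    """
    a, b, c, d = contingency
    out = ror_stats(a, b, c, d, zero_correction=zero_correction, alpha=alpha)
    if not np.isfinite(out["ror"]):
        raise UndefinedResultError(
            "ROR undefined for b*c = 0 without zero-cell correction"
        )
    return RORResult(
        ror=float(out["ror"]),
        ci_low=float(out["ci_low"]),
        ci_high=float(out["ci_high"]),
        p_value=float(out["p_one"]),
        significant=bool(out["significant_one_sided"]),
    )


def add_ror(
    pairs: pd.DataFrame, zero_correction: bool = True, alpha: float = 0.05
) -> pd.DataFrame:
    """Append ror, ci_low, ci_high, p_value, significant columns to a
    pair table carrying contingency columns a, b, c, d."""
    out = ror_stats(
        pairs["a"].to_numpy(),
        pairs["b"].to_numpy(),
        pairs["c"].to_numpy(),
        pairs["d"].to_numpy(),
        zero_correction=zero_correction,
        alpha=alpha,
    )
    pairs = pairs.copy()
    pairs["ror"] = out["ror"]
    pairs["ci_low"] = out["ci_low"]
    pairs["ci_high"] = out["ci_high"]
    pairs["p_value"] = out["p_one"]
    pairs["significant"] = out["significant_one_sided"]
    return pairs


def significance_filter(
    pairs: pd.DataFrame, audit: Optional[dict] = None
) -> pd.DataFrame:
    """Keep pairs flagged as signals (ROR > 1, one-sided P < .05)."""
    kept = pairs[pairs["significant"].fillna(False)].reset_index(drop=True)
    if audit is not None:
        audit["significance_filter"] = {
            "input_pairs": int(len(pairs)),
            "retained": int(len(kept)),
            "removed": int(len(pairs) - len(kept)),
        }
    return kept
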