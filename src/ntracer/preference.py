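"""Relative N-source preference and between-fraction rate comparisons.

Preference expresses a plankton fraction's uptake of one nitrogen form as a
percentage of its summed volumetric uptake over all measured forms. When a
group spans several sampling dates the convention is *ratio of sums*: rates
are summed per form across dates (missing cells contribute zero) and then
normalized, which is the convention that reproduces the multi-date
percentages printed for whole-lake summaries. The mean of per-date ratios is
a different statistic and is deliberately not used.
"""

from __future__ import annotations

import decimal
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "preference_single",
    "preference_pooled",
    "fraction_fold_ratio",
    "round_half_away",
]


def preference_single(rates: Mapping[str, float]) -> dict[str, float]:
    """Percentage allocation of total uptake across N forms for one sample.

    Parameters
    ----------
    rates
        Mapping of N form -> volumetric uptake rate. Missing forms are simply
        absent; rates must be non-negative with at least one positive.
    """
    vals = {k: float(v) for k, v in rates.items() if not pd.isna(v)}
    if any(v < 0 for v in vals.values()):
        raise ValueError("preference requires non-negative rates")
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("all rates are zero: preference undefined")
    return {k: 100.0 * v / total for k, v in vals.items()}


def preference_pooled(
    table: pd.DataFrame,
    group_by: Sequence[str] = ("lake", "fraction"),
    *,
    form_col: str = "form",
    rate_col: str = "v_volumetric",
) -> pd.DataFrame:
    """Pooled preference per group: sum rates per form across dates, then normalize.

    Missing entries (NaN or absent rows) contribute zero to the pooled sums.
    Groups whose rates sum to zero are excluded with a warning. For a group
    with a single date this reduces exactly to :func:`preference_single`.

    Returns a tidy frame with columns ``group_by + [form_col, "preference_pct"]``;
    percentages within each group sum to 100 (full precision — rounding is a
    reporting-layer concern, see :func:`round_half_away`).
    """
    if table.empty:
        raise ValueError("empty rate table")
    group_by = list(group_by)
    work = table.copy()
    work[rate_col] = pd.to_numeric(work[rate_col], errors="coerce").fillna(0.0)
    if (work[rate_col] < 0).any():
        raise ValueError("preference requires non-negative rates")

    sums = (
        work.groupby(group_by + [form_col], sort=False, observed=True)[rate_col]
        .sum()
        .reset_index()
    )
    out = []
    for key, grp in sums.groupby(group_by, sort=False, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        total = grp[rate_col].sum()
        if total <= 0:
            warnings.warn(f"group {key}: all rates zero, excluded from preference table")
            continue
        for _, r in grp.iterrows():
            row = dict(zip(group_by, key))
            row[form_col] = r[form_col]
            row["preference_pct"] = 100.0 * r[rate_col] / total
            out.append(row)
    return pd.DataFrame(out)


def fraction_fold_ratio(
    table: pd.DataFrame,
    num_fraction: str,
    den_fraction: str,
    group_by: Sequence[str] = ("lake",),
    *,
    fraction_col: str = "fraction",
    rate_col: str = "v_volumetric",
) -> pd.Series:
    """Ratio of summed volumetric rates (all forms) between two fractions per group."""
    group_by = list(group_by)
    work = table.copy()
    work[rate_col] = pd.to_numeric(work[rate_col], errors="coerce").fillna(0.0)
    sums = (
        work.groupby(group_by + [fraction_col], sort=False, observed=True)[rate_col]
        .sum()
        .reset_index()
    )
    ratios = {}
    for key, grp in sums.groupby(group_by, sort=False, observed=True):
        frac_sums = grp.set_index(fraction_col)[rate_col]
        if num_fraction not in frac_sums.index or den_fraction not in frac_sums.index:
            continue
        den = frac_sums[den_fraction]
        if den <= 0:
            raise ZeroDivisionError(f"group {key}: denominator fraction sums to zero")
        ratios[key] = frac_sums[num_fraction] / den
    if not ratios:
        raise ValueError("no group contains both requested fractions")
    ser = pd.Series(ratios)
    ser.index.name = group_by[0] if len(group_by) == 1 else None
    return ser


def round_half_away(x: float, digits: int = 0) -> float:
    """Round half away from zero (the convention of the printed percentages)."""
    q = decimal.Decimal(1).scaleb(-digits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))
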