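"""The daily years-of-life-lost disparity (DYLLD) index.

DYLLD for one day is the mean, over the non-reference SES groups, of that
group's daily YLL minus the reference (most advantaged) group's daily YLL:

    DYLLD_d = sum_j (dYLL_jd - dYLL_ref,d) / J

It is a single daily measure of the social disparity in the YLL burden;
negative values (reference group worse off that day) are preserved.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import REFERENCE_TERCILE, TERCILES


def compute_dylld(day_values: Mapping[str, float], reference: str) -> float:
    """Disparity index for one day from per-group daily YLL values."""
    if reference not in day_values:
        raise ValueError(f"reference group {reference!r} not among {sorted(day_values)}")
    others = [g for g in day_values if g != reference]
    if not others:
        raise ValueError("need at least one non-reference group")
    ref = day_values[reference]
    return float(np.mean([day_values[g] - ref for g in others]))


def dylld_series(
    daily: pd.DataFrame, reference: str = REFERENCE_TERCILE
) -> pd.DataFrame:
    """DYLLD for every day of a stratified daily-YLL series.

    ``daily`` is the output of :func:`dylld.lifetable.aggregate_daily`
    (columns ``yll_low``, ``yll_mid``, ``yll_high``).  Returns columns
    (date, dylld, dyll_ref).
    """
    if daily.empty:
        raise ValueError("daily series is empty")
    groups = [t for t in TERCILES if f"yll_{t}" in daily.columns]
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not among {groups}")
    ref = daily[f"yll_{reference}"].to_numpy(dtype=float)
    others = [g for g in groups if g != reference]
    diffs = np.column_stack([daily[f"yll_{g}"].to_numpy(dtype=float) - ref for g in others])
    return pd.DataFrame(
        {"date": daily["date"], "dylld": diffs.mean(axis=1), "dyll_ref": ref}
    )


__all__ = ["compute_dylld", "dylld_series"]
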