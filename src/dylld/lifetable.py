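"""Life tables, years of life lost (YLL), SES terciles, and daily aggregation.

YLL for one death is the remaining life expectancy at the age and sex of
death, read from a single-year-of-age life table ("matching by age and sex").
Daily totals are the sum of individual YLL over all deaths of the day,
stratified by terciles of an area-level SES indicator (% of adults without a
high-school diploma; higher value = lower SES = higher assumed vulnerability).
"""
from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import REFERENCE_TERCILE, TERCILES
from .errors import ConfigurationError, DataError

SEXES = ("female", "male")


class LifeTable:
    """Remaining life expectancy by sex and completed year of age.

    Parameters
    ----------
    values
        Mapping from sex ("female"/"male") to an array of remaining life
        expectancies indexed by completed age 0..max_age.  Values must be
        positive and non-increasing in age within each sex.
    """

    def __init__(self, values: Mapping[str, Sequence[float]]):
        if set(values) != set(SEXES):
            raise ConfigurationError(f"life table must define exactly {SEXES}")
        arrays = {}
        n = None
        for sex in SEXES:
            arr = np.asarray(values[sex], dtype=float)
            if arr.ndim != 1 or arr.size < 2:
                raise ConfigurationError("life table needs ages 0..max_age per sex")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ConfigurationError("both sexes must cover the same age range")
            if np.any(arr <= 0):
                raise ConfigurationError("remaining life expectancy must be positive")
            if np.any(np.diff(arr) > 0):
                raise ConfigurationError(
                    "remaining life expectancy must be non-increasing in age"
                )
            arrays[sex] = arr
        self._values = arrays
        self.max_age = n - 1

    def remaining(self, sex: str, age) -> np.ndarray | float:
        """Remaining life expectancy at (sex, completed age); vectorised in age."""
        if sex not in self._values:
            raise DataError(f"unknown sex {sex!r}")
        age_arr = np.asarray(age)
        if np.any(age_arr < 0) or np.any(age_arr > self.max_age):
            bad = age_arr[(age_arr < 0) | (age_arr > self.max_age)]
            raise DataError(
                f"age(s) {np.unique(bad).tolist()} outside life table range "
                f"0..{self.max_age}"
            )
        out = self._values[sex][age_arr]
        return float(out) if np.isscalar(age) else out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            for a, e in enumerate(self._values[sex]):
                rows.append((sex, a, e))
        return pd.DataFrame(rows, columns=["sex", "age", "remaining_years"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LifeTable":
        required = {"sex", "age", "remaining_years"}
        if not required.issubset(frame.columns):
            raise DataError(f"life table needs columns {sorted(required)}")
        values = {}
        for sex, grp in frame.groupby("sex"):
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy()
            if not np.array_equal(ages, np.arange(ages.size)):
                raise DataError(f"life table ages for {sex} must be 0..max_age")
            values[sex] = grp["remaining_years"].to_numpy()
        return cls(values)


def compute_yll(record: Mapping, table: LifeTable) -> float:
    """YLL for one death record: the life table's remaining years at (sex, age).

    Raises :class:`DataError` naming the record when its age exceeds the
    table's range.
    """
    age = int(record["age"])
    sex = record["sex"]
    try:
        return float(table.remaining(sex, age))
    except DataError as exc:
        raise DataError(f"record {dict(record)!r}: {exc}") from exc


def compute_yll_vector(deaths: pd.DataFrame, table: LifeTable) -> np.ndarray:
    """Vectorised YLL for a death-record frame with 'age' and 'sex' columns."""
    ages = deaths["age"].to_numpy(dtype=int)
    if ages.size and (ages.min() < 0 or ages.max() > table.max_age):
        bad = deaths.loc[(ages < 0) | (ages > table.max_age)].iloc[0]
        raise DataError(
            f"record {bad.to_dict()!r}: age outside life table range 0..{table.max_age}"
        )
    out = np.empty(len(deaths))
    sexes = deaths["sex"].to_numpy()
    for sex in SEXES:
        mask = sexes == sex
        if mask.any():
            out[mask] = table.remaining(sex, ages[mask])
    unknown = ~np.isin(sexes, SEXES)
    if unknown.any():
        raise DataError(f"unknown sex value(s) {set(sexes[unknown])!r}")
    return out


def tercile_cuts(ses_values: Sequence[float]) -> tuple[float, float]:
    """1/3 and 2/3 cut points of the SES indicator over all deaths.

    Uses the inverse-empirical-CDF (type-1) quantile, deaths-weighted (each
    death contributes its area's value once).
    """
    x = np.asarray(ses_values, dtype=float)
    if x.size < 3:
        raise ConfigurationError("need at least 3 records to form terciles")
    if np.all(x == x[0]):
        raise ConfigurationError(
            "terciles undefined: all SES indicator values are identical"
        )
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3], method="inverted_cdf")
    return float(q1), float(q2)


def assign_terciles(
    records: pd.DataFrame, cuts: Optional[tuple[float, float]] = None
) -> pd.DataFrame:
    """Label each death with its SES tercile: 'low', 'mid' or 'high' SES.

    Higher %-without-diploma means lower SES, so values above the upper cut
    are the 'low'-SES (most vulnerable) group and the lowest third is 'high'
    (the reference).  Values equal to a cut go to the lower-vulnerability
    side.  Cut points default to the type-1 terciles of ``ses_value`` over
    all supplied records.
    """
    if "ses_value" not in records.columns:
        raise DataError("records need a 'ses_value' column")
    if cuts is None:
        cuts = tercile_cuts(records["ses_value"])
    q1, q2 = cuts
    x = records["ses_value"].to_numpy(dtype=float)
    labels = np.where(x <= q1, "high", np.where(x <= q2, "mid", "low"))
    out = records.copy()
    out["tercile"] = pd.Categorical(labels, categories=list(TERCILES))
    return out


def aggregate_daily(
    records: pd.DataFrame,
    table: LifeTable,
    calendar: Sequence,
) -> pd.DataFrame:
    """Sum individual YLL by day and SES tercile over a complete calendar.

    Returns one row per calendar day (zero-death days included as zeros) with
    columns ``yll_total``, ``yll_low/mid/high`` and death counts
    ``n_low/mid/high``.  Per-tercile values sum to the total by construction.
    """
    calendar = pd.DatetimeIndex(pd.to_datetime(list(calendar))).normalize()
    if calendar.has_duplicates:
        raise DataError("calendar contains duplicate days")
    records = records.copy()
    records["date"] = pd.to_datetime(records["date"]).dt.normalize()
    outside = ~records["date"].isin(calendar)
    if outside.any():
        bad = records.loc[outside, "date"].iloc[0].date()
        raise DataError(f"death record dated {bad} lies outside the calendar")
    if "tercile" not in records.columns:
        records = assign_terciles(records)
    records["yll"] = compute_yll_vector(records, table)

    out = pd.DataFrame(index=calendar)
    for t in TERCILES:
        sub = records[records["tercile"] == t]
        g = sub.groupby("date")["yll"].agg(["sum", "size"])
        out[f"yll_{t}"] = g["sum"].reindex(calendar).fillna(0.0)
        out[f"n_{t}"] = g["size"].reindex(calendar).fillna(0).astype(int)
    out["yll_total"] = sum(out[f"yll_{t}"] for t in TERCILES)
    out.index.name = "date"
    cols = ["yll_total"] + [f"yll_{t}" for t in TERCILES] + [f"n_{t}" for t in TERCILES]
    return out[cols].reset_index()


__all__ = [
    "LifeTable",
    "SEXES",
    "REFERENCE_TERCILE",
    "compute_yll",
    "compute_yll_vector",
    "tercile_cuts",
    "assign_terciles",
    "aggregate_daily",
]
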