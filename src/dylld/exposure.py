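"""Exposure-response model for DYLLD vs. same-day temperature.

The daily disparity index is regressed on a hockey-stick heat term
``(T_d - tau)+`` with adjustment for season (natural cubic spline of
day-of-summer), a between-year trend, and daily relative humidity, all at
lag 0.  The heat threshold ``tau`` is chosen by profile deviance over a
candidate grid, giving a J-shaped fitted relation: flat below the threshold
and log-linear above it.

The default family is quasi-Poisson with log link (DYLLD treated as a
nonnegative intensity in years; the dispersion is estimated by Pearson X2),
so the relative risk at temperature t is

    RR(t) = exp(beta x max(0, t - tau))

relative to the period-average DYLLD.  A Gaussian identity-link alternative
is available for sensitivity; its RR is predicted/period-mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .config import ModelConfig
from .errors import ConfigurationError, DataError, ModelError


@dataclass
class ExposureResponseFit:
    """Result of the profile-deviance hockey-stick fit."""

    threshold_c: float
    log_rr_per_deg: float  # heat-term coefficient (slope above threshold)
    coef: np.ndarray
    coef_names: list
    coef_covariance: np.ndarray
    heat_index: int  # position of the heat term in coef
    period_mean_dylld: float
    deviance_by_candidate_threshold: pd.DataFrame
    n_days_used: int
    family: str
    dispersion: float
    observed: pd.DataFrame  # date, dylld (response scale), temperature_c
    warnings: list = field(default_factory=list)

    @property
    def slope_se(self) -> float:
        return float(np.sqrt(self.coef_covariance[self.heat_index, self.heat_index]))

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2)
        return (
            self.log_rr_per_deg - z * self.slope_se,
            self.log_rr_per_deg + z * self.slope_se,
        )


@dataclass
class AttributableRate:
    """Summer DYLLD attributable to above-threshold temperatures."""

    rate: float  # years per 100,000 persons per summer
    se: float
    ci_low: float
    ci_high: float
    n_summers: int
    n_days_above: int
    mode: str
    warnings: list = field(default_factory=list)


def _day_of_summer(dates: pd.Series) -> np.ndarray:
    d = pd.to_datetime(dates)
    june1 = pd.to_datetime({"year": d.dt.year, "month": 6, "day": 1})
    return (d - june1).dt.days.to_numpy(dtype=float)


def _build_design(
    df: pd.DataFrame, threshold: float, config: ModelConfig
) -> tuple[np.ndarray, list]:
    """Design matrix: intercept, heat term, season spline, year trend, humidity."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    heat = np.maximum(0.0, df["temperature_c"].to_numpy() - threshold)
    cols.append(heat)
    names.append("heat_excess")
    dos = _day_of_summer(df["date"])
    # the cr basis is a partition of unity; request one extra column and drop
    # it so the basis stays full rank next to the explicit intercept
    spline = patsy.dmatrix(
        "cr(x, df=df_) - 1",
        {"x": dos, "df_": config.season_spline_df + 1},
        return_type="matrix",
    )
    spline = np.asarray(spline)[:, :-1]
    for k in range(spline.shape[1]):
        cols.append(spline[:, k])
        names.append(f"season_{k + 1}")
    years = pd.to_datetime(df["date"]).dt.year.to_numpy()
    if config.year_trend == "linear":
        cols.append((years - years.min()).astype(float))
        names.append("year")
    else:
        for y in np.unique(years)[1:]:
            cols.append((years == y).astype(float))
            names.append(f"year_{y}")
    if config.humidity_term == "linear":
        if "humidity_pct" not in df.columns:
            raise DataError("weather series lacks 'humidity_pct' for the humidity term")
        cols.append(df["humidity_pct"].to_numpy(dtype=float))
        names.append("humidity")
    return np.column_stack(cols), names


def fit(
    dylld: pd.DataFrame,
    weather: pd.DataFrame,
    config: Optional[ModelConfig] = None,
) -> ExposureResponseFit:
    """Profile-deviance hockey-stick GLM of DYLLD on daily temperature.

    For each candidate threshold the GLM is refitted and the deviance
    recorded; the selected threshold minimises the deviance and its fit is
    returned.  Requires at least two summers of merged data.
    """
    config = config or ModelConfig()
    d = dylld.copy()
    d["date"] = pd.to_datetime(d["date"]).dt.normalize()
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"]).dt.normalize()
    df = d.merge(w, on="date", how="left")
    if df["temperature_c"].isna().any():
        missing = df.loc[df["temperature_c"].isna(), "date"].iloc[0].date()
        raise DataError(f"weather series does not cover DYLLD day {missing}")
    if df["date"].dt.year.nunique() < 2:
        raise DataError("need at least 2 summers of data to fit the model")

    y_raw = df["dylld"].to_numpy(dtype=float)
    warnings_list: list[str] = []
    if config.family == "quasi-poisson-log":
        if config.floor_negative_dylld:
            n_neg = int((y_raw < 0).sum())
            if n_neg:
                warnings_list.append(
                    f"floored {n_neg}/{len(y_raw)} negative DYLLD days at 0 "
                    f"({100 * n_neg / len(y_raw):.1f}%)"
                )
            y = np.maximum(y_raw, 0.0)
        elif (y_raw < 0).any():
            raise ConfigurationError(
                "quasi-Poisson family requires nonnegative DYLLD; "
                "set floor_negative_dylld=True or use gaussian-identity"
            )
        else:
            y = y_raw
    else:
        y = y_raw

    t = df["temperature_c"].to_numpy()
    if config.threshold_grid is not None:
        grid = np.asarray(list(config.threshold_grid), dtype=float)
        if grid.min() < t.min() or grid.max() > t.max():
            raise ConfigurationError(
                "threshold_grid must lie within the observed temperature range "
                f"[{t.min():.2f}, {t.max():.2f}]"
            )
    else:
        q50, q98 = np.quantile(t, [0.50, 0.98])
        grid = np.arange(np.ceil(q50), q98 + 1e-9, 1.0)
        if grid.size == 0:
            grid = np.array([q50])

    if config.family == "quasi-poisson-log":
        glm_family = sm.families.Poisson()
    else:
        glm_family = sm.families.Gaussian()

    results = []
    profile = []
    for tau in grid:
        X, names = _build_design(df, float(tau), config)
        try:
            res = sm.GLM(y, X, family=glm_family).fit(
                scale="X2" if config.family == "quasi-poisson-log" else None
            )
            if not np.all(np.isfinite(res.params)):
                raise ValueError("non-finite coefficients")
        except Exception as exc:  # noqa: BLE001 - record and move on
            profile.append((float(tau), np.nan, str(exc)))
            continue
        profile.append((float(tau), float(res.deviance), ""))
        results.append((float(tau), res, names))
    profile_df = pd.DataFrame(profile, columns=["threshold_c", "deviance", "note"])
    if not results:
        raise ModelError(
            "GLM failed to converge at every candidate threshold; "
            f"diagnostics: {profile_df.to_dict('records')}"
        )
    # Threshold selection: candidates whose scaled deviance is not
    # significantly worse than the minimum (chi2_1 at 5%) form a profile
    # confidence set for the threshold; take its median member.  Picking the
    # raw minimum instead selects the most extreme slope when the profile is
    # flat (e.g. under no heat effect) and the naive slope CI undercovers.
    results.sort(key=lambda r: r[0])
    devs = np.array([r[1].deviance for r in results])
    best = int(devs.argmin())
    margin = 3.841458820694124 * results[best][1].scale  # chi2_1(0.95) x phi
    admissible = np.flatnonzero(devs <= devs[best] + margin)
    best_tau, best_res, names = results[admissible[len(admissible) // 2]]
    n_above = int((t > best_tau).sum())
    if n_above < 10:
        warnings_list.append(
            f"only {n_above} days above the selected threshold {best_tau:.1f} degC"
        )
    heat_index = names.index("heat_excess")
    return ExposureResponseFit(
        threshold_c=best_tau,
        log_rr_per_deg=float(best_res.params[heat_index]),
        coef=np.asarray(best_res.params),
        coef_names=names,
        coef_covariance=np.asarray(best_res.cov_params()),
        heat_index=heat_index,
        period_mean_dylld=float(y.mean()),
        deviance_by_candidate_threshold=profile_df,
        n_days_used=len(df),
        family=config.family,
        dispersion=float(best_res.scale),
        observed=pd.DataFrame(
            {"date": df["date"], "dylld": y, "temperature_c": t}
        ),
        warnings=warnings_list,
    )


def rr_from_excess(
    excess: np.ndarray,
    slope,
    family: str,
    period_mean: float,
) -> np.ndarray:
    """RR at given degrees above threshold; broadcasts slope against excess."""
    slope = np.asarray(slope)
    if family == "quasi-poisson-log":
        return np.exp(np.multiply.outer(slope, excess)) if slope.ndim else np.exp(slope * excess)
    rel = np.multiply.outer(slope, excess) if slope.ndim else slope * excess
    return 1.0 + rel / period_mean


def rr_curve(fit_result: ExposureResponseFit, temperatures: Sequence[float]) -> pd.DataFrame:
    """Relative risk vs. temperature; RR = 1 at and below the threshold."""
    temps = np.asarray(temperatures, dtype=float)
    excess = np.maximum(0.0, temps - fit_result.threshold_c)
    rr = rr_from_excess(
        excess, fit_result.log_rr_per_deg, fit_result.family, fit_result.period_mean_dylld
    )
    return pd.DataFrame({"temperature_c": temps, "rr": rr})


def _count_summers(dates: pd.Series) -> int:
    return int(pd.to_datetime(dates).dt.year.nunique())


def draw_slopes(
    fit_result: ExposureResponseFit, n_draws: int, seed: int
) -> np.ndarray:
    """Seeded multivariate-normal coefficient draws, heat-term coordinate."""
    rng = np.random.default_rng([7, seed])
    draws = rng.multivariate_normal(
        fit_result.coef, fit_result.coef_covariance, size=n_draws, method="svd"
    )
    return draws[:, fit_result.heat_index]


def attributable_rate(
    fit_result: ExposureResponseFit,
    weather: pd.DataFrame,
    population: int,
    mode: str = "observed-dylld",
    *,
    dylld: Optional[pd.DataFrame] = None,
    seed: int = 0,
    n_draws: int = 1000,
) -> AttributableRate:
    """Summer DYLLD attributable to heat, per 100,000 persons per summer.

    mode "observed-dylld" (historical analyses): sums, over days with
    T > threshold, the observed DYLLD times the attributable fraction
    (RR - 1)/RR.  mode "constant-baseline" (projections): sums the period
    mean DYLLD times the excess risk (RR - 1), which needs no future
    disparity observations.  The SE comes from seeded multivariate-normal
    coefficient draws (percentile 95% CI).
    """
    if population <= 0:
        raise ValueError("population must be positive")
    if mode not in ("observed-dylld", "constant-baseline"):
        raise ValueError(f"unknown mode {mode!r}")
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"]).dt.normalize()
    n_summers = _count_summers(w["date"])
    t = w["temperature_c"].to_numpy(dtype=float)
    above = t > fit_result.threshold_c
    n_above = int(above.sum())
    scale = 1e5 / (n_summers * population)

    if n_above == 0:
        return AttributableRate(
            rate=0.0, se=0.0, ci_low=0.0, ci_high=0.0, n_summers=n_summers,
            n_days_above=0, mode=mode,
            warnings=["no days above the heat threshold; attributable rate is 0"],
        )

    excess = t[above] - fit_result.threshold_c
    if mode == "observed-dylld":
        source = fit_result.observed if dylld is None else dylld
        src = source.copy()
        src["date"] = pd.to_datetime(src["date"]).dt.normalize()
        y = src.set_index("date")["dylld"].reindex(w.loc[above, "date"])
        if y.isna().any():
            missing = y.index[y.isna()][0].date()
            raise DataError(f"no DYLLD observation for hot day {missing}")
        y = y.to_numpy(dtype=float)
        if fit_result.family == "quasi-poisson-log" and (y < 0).any():
            y = np.maximum(y, 0.0)
    else:
        y = None

    def total(slope) -> np.ndarray:
        rr = rr_from_excess(excess, slope, fit_result.family, fit_result.period_mean_dylld)
        if mode == "observed-dylld":
            return np.sum(y * (rr - 1.0) / rr, axis=-1)
        return fit_result.period_mean_dylld * np.sum(rr - 1.0, axis=-1)

    rate = float(total(fit_result.log_rr_per_deg) * scale)
    slopes = draw_slopes(fit_result, n_draws, seed)
    rates = total(slopes) * scale
    lo, hi = np.percentile(rates, [2.5, 97.5])
    return AttributableRate(
        rate=rate,
        se=float(np.std(rates, ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_summers=n_summers,
        n_days_above=n_above,
        mode=mode,
    )


__all__ = [
    "ExposureResponseFit",
    "AttributableRate",
    "fit",
    "rr_curve",
    "rr_from_excess",
    "attributable_rate",
    "draw_slopes",
]
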