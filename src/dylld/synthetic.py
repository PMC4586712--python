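"""Synthetic city generator: weather, life tables, deaths, climate scenarios.

Every downstream stage of the pipeline is testable against this module's
known ground truth.  The generator emulates a large northern city's summer
mortality: daily death counts are Poisson with a multiplicative heat effect
above a threshold that is strongest in the lowest-SES tercile, ages come
from a truncated Gaussian, and YLL-scale behaviour emerges from aggregation
rather than being imposed directly.

Reproducibility: each output type draws from its own RNG stream derived from
the master seed by a fixed stream id, so e.g. adding scenarios never
perturbs the death series.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import TERCILES, SimulationConfig
from .errors import ConfigurationError, DataError
from .lifetable import SEXES, LifeTable

# fixed RNG stream ids (combined with the master seed)
_STREAM_TEMP = 1
_STREAM_DEATHS = 2
_STREAM_SCENARIO = 3

#: fixed SES-indicator bands (% without diploma) per tercile; the most
#: advantaged ("high" SES) areas have the lowest values.
_SES_BANDS = {"high": (0.0, 100 / 3), "mid": (100 / 3, 200 / 3), "low": (200 / 3, 100.0)}


@dataclass
class GroundTruth:
    """Designed parameters realised by one simulated city."""

    config: SimulationConfig
    #: expected daily YLL per tercile at the reference temperature
    #: (i.e. below threshold), in years: baseline x tercile prob x E[YLL].
    expected_daily_yll_at_reference: dict = field(default_factory=dict)
    mean_yll_per_death: float = float("nan")


@dataclass
class ScenarioEnsemble:
    """A climate-scenario ensemble: per-scenario (historical, future) pairs."""

    pairs: list  # list of (historical DataFrame, future DataFrame)
    warming_delta_c: np.ndarray  # realised warming per scenario
    bias_c: np.ndarray  # scenario-specific additive bias vs. observations

    def __len__(self) -> int:
        return len(self.pairs)


def summer_dates(start_year: int, n_years: int, days_per_summer: int = 92) -> pd.DatetimeIndex:
    """Calendar days of ``n_years`` consecutive summers (June 1 onward)."""
    if n_years < 1 or days_per_summer < 1:
        raise ConfigurationError("n_years and days_per_summer must be >= 1")
    chunks = [
        pd.date_range(f"{start_year + i}-06-01", periods=days_per_summer, freq="D")
        for i in range(n_years)
    ]
    return pd.DatetimeIndex(np.concatenate([c.values for c in chunks]))


def _seasonal_component(dates: pd.DatetimeIndex, amplitude: float) -> np.ndarray:
    """Within-summer sinusoid peaking July 15, centred over the given days."""
    doy = dates.dayofyear.to_numpy(dtype=float)
    raw = amplitude * np.cos(2 * np.pi * (doy - 196.0) / 365.25)
    return raw - raw.mean()


def generate_temperature_series(
    config: SimulationConfig,
    n_days: int,
    seed: Optional[int] = None,
    *,
    mean_offset_c: float = 0.0,
    start_year: Optional[int] = None,
    stream: int = _STREAM_TEMP,
) -> pd.DataFrame:
    """Daily summer weather: date, temperature_c, humidity_pct.

    Temperature is a seasonal sinusoid (peak mid-July) plus stationary AR(1)
    Gaussian noise whose variance is chosen so the series SD matches
    ``config.temp_sd_c``; humidity is i.i.d. Gaussian truncated to [0, 100].
    Deterministic for a fixed (config, seed).
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([stream, seed])
    start = config.start_year if start_year is None else start_year
    n_years = -(-n_days // config.days_per_summer)  # ceil
    dates = summer_dates(start, n_years, config.days_per_summer)[:n_days]

    seasonal = _seasonal_component(dates, config.seasonal_amplitude_c)
    noise_var = max(0.0, config.temp_sd_c**2 - seasonal.var())
    noise_sd = np.sqrt(noise_var)
    rho = config.temp_ar1
    eps = rng.standard_normal(n_days)
    noise = np.empty(n_days)
    if noise_sd == 0.0:
        noise[:] = 0.0
    else:
        noise[0] = noise_sd * eps[0]
        innov_sd = noise_sd * np.sqrt(1.0 - rho**2)
        for i in range(1, n_days):
            noise[i] = rho * noise[i - 1] + innov_sd * eps[i]
    temperature = config.temp_mean_c + mean_offset_c + seasonal + noise

    humidity = rng.normal(config.humidity_mean_pct, config.humidity_sd_pct, n_days)
    humidity = np.clip(humidity, 0.0, 100.0)
    return pd.DataFrame(
        {"date": dates, "temperature_c": temperature, "humidity_pct": humidity}
    )


def generate_life_table(
    max_age: int = 105,
    sex_gap_years: float = 4.0,
    *,
    gompertz_a: float = 3e-5,
    gompertz_c: float = 0.09,
) -> LifeTable:
    """Life table with Gompertz mortality for males; females live longer.

    Male remaining life expectancy at completed age x is the numerical
    integral of the conditional Gompertz survival curve
    S(t | x) = exp(-(a/c) (e^{ct} - e^{cx})).  Female values add a gap of
    ``sex_gap_years`` at age 0, tapering linearly to keep the schedule
    strictly decreasing.
    """
    if max_age < 1:
        raise ValueError("max_age must be >= 1")
    upper = max_age + 40.0  # integrate far enough that the tail is negligible
    grid = np.arange(0.0, upper + 0.05, 0.05)
    log_s = -(gompertz_a / gompertz_c) * (np.exp(gompertz_c * grid) - 1.0)
    surv = np.exp(log_s)
    ages = np.arange(max_age + 1)
    male = np.empty(max_age + 1)
    for x in ages:
        i = int(round(x / 0.05))
        tail = surv[i:] / surv[i]
        male[x] = np.trapezoid(tail, dx=0.05)
    taper = 1.0 - ages / (max_age + 1.0)
    female = male + sex_gap_years * taper
    return LifeTable({"male": male, "female": female})


def _expected_yll_per_death(config: SimulationConfig, table: LifeTable) -> float:
    """E[YLL] under the age/sex draw: truncated-Gaussian ages, equal sexes."""
    lo = (config.age_min - config.age_mean) / config.age_sd
    hi = (config.max_age + 1 - config.age_mean) / config.age_sd
    dist = stats.truncnorm(lo, hi, loc=config.age_mean, scale=config.age_sd)
    ages = np.arange(config.age_min, config.max_age + 1)
    # probability mass of each completed year [a, a+1)
    pmf = dist.cdf(ages + 1) - dist.cdf(ages)
    pmf /= pmf.sum()
    e_by_age = 0.5 * (table.remaining("female", ages) + table.remaining("male", ages))
    return float(np.sum(pmf * e_by_age))


def generate_deaths(
    config: SimulationConfig,
    weather: pd.DataFrame,
    life_table: LifeTable,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate individual death records over the configured summers.

    Daily death counts per SES tercile j are Poisson with mean
    ``baseline x prob_j x exp(log_rr_j x max(0, T_d - threshold))``.  Each
    record carries date, completed age, sex, a continuous SES indicator in
    the tercile's band, and the true tercile label.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([_STREAM_DEATHS, seed])

    expected = summer_dates(config.start_year, config.n_years, config.days_per_summer)
    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"]).dt.normalize()
    temp = weather.set_index("date")["temperature_c"]
    missing = expected.difference(temp.index)
    if len(missing):
        raise DataError(f"weather series is missing simulated day {missing[0].date()}")
    t = temp.reindex(expected).to_numpy()

    truth = GroundTruth(config=config)
    truth.mean_yll_per_death = _expected_yll_per_death(config, life_table)
    for j, terc in enumerate(TERCILES):
        truth.expected_daily_yll_at_reference[terc] = (
            config.baseline_deaths_per_day
            * config.ses_tercile_probs[j]
            * truth.mean_yll_per_death
        )

    if config.baseline_deaths_per_day == 0:
        empty = pd.DataFrame(
            columns=["date", "age", "sex", "ses_value", "tercile_true"]
        )
        return empty, truth

    excess = np.maximum(0.0, t - config.true_threshold_c)
    frames = []
    lo = (config.age_min - config.age_mean) / config.age_sd
    hi = (config.max_age + 1 - config.age_mean) / config.age_sd
    for j, terc in enumerate(TERCILES):
        lam = (
            config.baseline_deaths_per_day
            * config.ses_tercile_probs[j]
            * np.exp(config.group_heat_log_rr[j] * excess)
        )
        counts = rng.poisson(lam)
        n = int(counts.sum())
        if n == 0:
            continue
        dates = np.repeat(expected.values, counts)
        raw_ages = stats.truncnorm.rvs(
            lo, hi, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
        )
        ages = np.floor(raw_ages).astype(int)
        sexes = rng.choice(SEXES, size=n)
        band_lo, band_hi = _SES_BANDS[terc]
        ses = rng.uniform(band_lo, band_hi, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "age": ages,
                    "sex": sexes,
                    "ses_value": ses,
                    "tercile_true": terc,
                }
            )
        )
    if frames:
        deaths = pd.concat(frames, ignore_index=True)
        deaths = deaths.sort_values(["date", "tercile_true", "age"], kind="stable")
        deaths = deaths.reset_index(drop=True)
    else:
        deaths = pd.DataFrame(columns=["date", "age", "sex", "ses_value", "tercile_true"])
    return deaths, truth


def generate_scenario_ensemble(
    config: SimulationConfig, seed: Optional[int] = None
) -> ScenarioEnsemble:
    """Climate-scenario ensemble of (historical, future) daily temperatures.

    Each scenario's historical series comes from the same generator family as
    observed weather but with a scenario-specific additive bias (so quantile
    mapping has real work to do); its future series is an independent draw
    shifted further by a warming delta ~ N(scenario_warming_mean_c,
    scenario_warming_sd_c^2).  Realised deltas and biases are returned.
    """
    if config.n_scenarios < 1:
        raise ConfigurationError("n_scenarios must be >= 1")
    seed = config.seed if seed is None else seed
    meta_rng = np.random.default_rng([_STREAM_SCENARIO, seed])
    biases = meta_rng.normal(0.0, config.scenario_bias_sd_c, config.n_scenarios)
    deltas = meta_rng.normal(
        config.scenario_warming_mean_c, config.scenario_warming_sd_c, config.n_scenarios
    )
    n_days = config.scenario_years * config.days_per_summer
    pairs = []
    for s in range(config.n_scenarios):
        hist = generate_temperature_series(
            config,
            n_days,
            seed=seed,
            mean_offset_c=float(biases[s]),
            start_year=config.scenario_hist_start_year,
            stream=_STREAM_SCENARIO * 1000 + 2 * s,
        )[["date", "temperature_c"]]
        fut = generate_temperature_series(
            config,
            n_days,
            seed=seed,
            mean_offset_c=float(biases[s] + deltas[s]),
            start_year=config.scenario_future_start_year,
            stream=_STREAM_SCENARIO * 1000 + 2 * s + 1,
        )[["date", "temperature_c"]]
        pairs.append((hist, fut))
    return ScenarioEnsemble(pairs=pairs, warming_delta_c=deltas, bias_c=biases)


def simulate_city(
    config: SimulationConfig, seed: Optional[int] = None
) -> dict:
    """Convenience driver: weather, life table, deaths and ensemble for a city."""
    seed = config.seed if seed is None else seed
    n_days = config.n_years * config.days_per_summer
    weather = generate_temperature_series(config, n_days, seed=seed)
    table = generate_life_table(config.max_age, config.sex_gap_years)
    deaths, truth = generate_deaths(config, weather, table, seed=seed)
    ensemble = generate_scenario_ensemble(config, seed=seed)
    return {
        "weather": weather,
        "life_table": table,
        "deaths": deaths,
        "ground_truth": truth,
        "ensemble": ensemble,
    }


__all__ = [
    "GroundTruth",
    "ScenarioEnsemble",
    "summer_dates",
    "generate_temperature_series",
    "generate_life_table",
    "generate_deaths",
    "generate_scenario_ensemble",
    "simulate_city",
]
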