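import numpy as np
import pandas as pd
import pytest

import dylld as d


@pytest.fixture(scope="session")
def life_table():
    return d.generate_life_table(max_age=105, sex_gap_years=4.0)


@pytest.fixture(scope="session")
def small_city():
    """One simulated city, small enough for fast reuse across tests.

    Six summers, ~12 deaths/day, the default vulnerability gradient, and a
    4-member scenario ensemble, with the whole downstream chain precomputed.
    """
    cfg = d.SimulationConfig(
        n_years=6,
        baseline_deaths_per_day=12.0,
        n_scenarios=4,
        scenario_years=6,
        seed=7,
    )
    weather = d.generate_temperature_series(cfg, cfg.n_years * cfg.days_per_summer, seed=7)
    table = d.generate_life_table(cfg.max_age, cfg.sex_gap_years)
    deaths, truth = d.generate_deaths(cfg, weather, table, seed=7)
    labeled = d.assign_terciles(deaths)
    calendar = d.summer_dates(cfg.start_year, cfg.n_years)
    daily = d.aggregate_daily(labeled, table, calendar)
    series = d.dylld_series(daily)
    fit = d.fit(series, weather)
    ensemble = d.generate_scenario_ensemble(cfg, seed=7)
    return {
        "config": cfg,
        "weather": weather,
        "life_table": table,
        "deaths": deaths,
        "ground_truth": truth,
        "daily": daily,
        "dylld": series,
        "fit": fit,
        "ensemble": ensemble,
    }


@pytest.fixture()
def toy_daily():
    """Ten days of stratified daily YLL with known values."""
    dates = pd.date_range("2000-06-01", periods=10, freq="D")
    rng = np.random.default_rng(3)
    return pd.DataFrame(
        {
            "date": dates,
            "yll_low": rng.uniform(50, 150, 10),
            "yll_mid": rng.uniform(50, 150, 10),
            "yll_high": rng.uniform(50, 150, 10),
        }
    )
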