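"""Generator contracts: weather moments, life-table shape, death process."""
import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import dylld as d
from dylld.errors import ConfigurationError, DataError
from dylld.synthetic import _seasonal_component


class TestTemperature:
    def test_zero_noise_reduces_to_deterministic_seasonal_mean(self):
        cfg = d.SimulationConfig(temp_sd_c=0.0, temp_ar1=0.0, seasonal_amplitude_c=2.0)
        w = d.generate_temperature_series(cfg, 184, seed=5)
        dates = pd.DatetimeIndex(w["date"])
        doy = dates.dayofyear.to_numpy(dtype=float)
        raw = 2.0 * np.cos(2 * np.pi * (doy - 196.0) / 365.25)
        expected = cfg.temp_mean_c + raw - raw.mean()
        np.testing.assert_allclose(w["temperature_c"], expected, atol=1e-12)

    def test_sample_moments_match_configuration(self):
        cfg = d.SimulationConfig(temp_mean_c=20.4, temp_sd_c=3.24, temp_ar1=0.6)
        n = 92 * 18
        w = d.generate_temperature_series(cfg, n, seed=11)
        t = w["temperature_c"]
        # AR(1) inflates the SE of the mean by sqrt((1+rho)/(1-rho)) = 2
        se = 3.24 / np.sqrt(n) * 2.0
        assert abs(t.mean() - 20.4) < 3 * se
        assert abs(t.std(ddof=1) - 3.24) / 3.24 < 0.15

    def test_same_seed_identical_different_seed_not(self):
        cfg = d.SimulationConfig()
        a = d.generate_temperature_series(cfg, 200, seed=3)
        b = d.generate_temperature_series(cfg, 200, seed=3)
        c = d.generate_temperature_series(cfg, 200, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["temperature_c"], c["temperature_c"])

    def test_humidity_bounded(self):
        cfg = d.SimulationConfig(humidity_mean_pct=95, humidity_sd_pct=20)
        w = d.generate_temperature_series(cfg, 500, seed=1)
        assert w["humidity_pct"].between(0, 100).all()

    def test_nonpositive_n_days_rejected(self):
        with pytest.raises(ValueError):
            d.generate_temperature_series(d.SimulationConfig(), 0, seed=1)


class TestLifeTable:
    def test_monotone_decreasing_and_positive_terminal(self, life_table):
        assert life_table.remaining("male", 0) > life_table.remaining("male", 1)
        for sex in ("female", "male"):
            vals = [life_table.remaining(sex, a) for a in range(life_table.max_age + 1)]
            assert all(x > y for x, y in zip(vals, vals[1:]))
            assert vals[-1] > 0

    def test_sex_gap_exact_at_birth(self):
        t = d.generate_life_table(max_age=100, sex_gap_years=4.0)
        assert t.remaining("female", 0) - t.remaining("male", 0) == pytest.approx(4.0)

    def test_gompertz_remaining_life_matches_integration_oracle(self):
        a, c = 3e-5, 0.09
        t = d.generate_life_table(max_age=100, sex_gap_years=0.0, gompertz_a=a, gompertz_c=c)

        def surv_ratio(u, x):
            return np.exp(-(a / c) * (np.exp(c * u) - np.exp(c * x)))

        oracle, _ = integrate.quad(surv_ratio, 60, 160, args=(60,), limit=200)
        assert t.remaining("male", 60) == pytest.approx(oracle, abs=0.02)


class TestDeaths:
    def test_zero_baseline_yields_no_records(self, life_table):
        cfg = d.SimulationConfig(n_years=1, baseline_deaths_per_day=0.0)
        w = d.generate_temperature_series(cfg, 92, seed=2)
        deaths, _ = d.generate_deaths(cfg, w, life_table, seed=2)
        assert deaths.empty

    def test_missing_weather_day_raises_with_date(self, life_table):
        cfg = d.SimulationConfig(n_years=1)
        w = d.generate_temperature_series(cfg, 92, seed=2)
        w = w[w["date"] != "1990-07-04"]
        with pytest.raises(DataError, match="1990-07-04"):
            d.generate_deaths(cfg, w, life_table, seed=2)

    def test_city_scale_death_counts(self, life_table):
        """~37 deaths/day gives summer totals near 3,400/year on average."""
        totals = []
        for seed in (1, 2, 3):
            cfg = d.SimulationConfig(n_years=4, baseline_deaths_per_day=37.0, seed=seed)
            w = d.generate_temperature_series(cfg, 4 * 92, seed=seed)
            deaths, _ = d.generate_deaths(cfg, w, life_table, seed=seed)
            totals.append(len(deaths) / 4)
        assert abs(np.mean(totals) - 3400) / 3400 < 0.10

    def test_counts_independent_of_temperature_under_null(self, life_table):
        """Zero designed heat effect: daily counts show no heat slope."""
        nonsig = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = d.SimulationConfig(
                n_years=4,
                baseline_deaths_per_day=10.0,
                group_heat_log_rr=(0.0, 0.0, 0.0),
                seed=seed,
            )
            w = d.generate_temperature_series(cfg, 4 * 92, seed=seed)
            deaths, _ = d.generate_deaths(cfg, w, life_table, seed=seed)
            counts = deaths.groupby("date").size().reindex(w["date"], fill_value=0)
            excess = np.maximum(0.0, w["temperature_c"].to_numpy() - 23.0)
            res = stats.linregress(excess, counts.to_numpy())
            nonsig += res.pvalue > 0.05
        assert nonsig >= 0.90 * n_seeds

    def test_tercile_shares_converge_to_probs(self, life_table):
        probs = (0.5, 0.3, 0.2)
        cfg = d.SimulationConfig(
            n_years=6,
            baseline_deaths_per_day=30.0,
            ses_tercile_probs=probs,
            group_heat_log_rr=(0.0, 0.0, 0.0),
            seed=9,
        )
        w = d.generate_temperature_series(cfg, 6 * 92, seed=9)
        deaths, _ = d.generate_deaths(cfg, w, life_table, seed=9)
        n = len(deaths)
        shares = deaths["tercile_true"].value_counts(normalize=True)
        for p, terc in zip(probs, d.TERCILES):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(shares[terc] - p) < 3 * se

    def test_ses_values_in_unit_percent_range(self, small_city):
        assert small_city["deaths"]["ses_value"].between(0, 100).all()

    def test_deaths_deterministic_for_fixed_seed(self, life_table):
        cfg = d.SimulationConfig(n_years=2, baseline_deaths_per_day=8.0)
        w = d.generate_temperature_series(cfg, 2 * 92, seed=5)
        a, _ = d.generate_deaths(cfg, w, life_table, seed=5)
        b, _ = d.generate_deaths(cfg, w, life_table, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            d.SimulationConfig(ses_tercile_probs=(0.5, 0.5, 0.1))
        with pytest.raises(ConfigurationError):
            d.SimulationConfig(group_heat_log_rr=(0.01, 0.05, 0.02))
        with pytest.raises(ConfigurationError):
            d.SimulationConfig(temp_ar1=1.0)


class TestScenarioEnsemble:
    def test_cardinality(self):
        cfg = d.SimulationConfig(n_scenarios=30, scenario_years=2)
        ens = d.generate_scenario_ensemble(cfg, seed=1)
        assert len(ens) == 30
        assert ens.warming_delta_c.shape == (30,)

    def test_designed_warming_is_recovered(self):
        cfg = d.SimulationConfig(
            n_scenarios=10,
            scenario_years=8,
            scenario_warming_mean_c=1.35,
            scenario_warming_sd_c=0.0,
            scenario_bias_sd_c=0.0,
        )
        ens = d.generate_scenario_ensemble(cfg, seed=2)
        diffs = [
            f["temperature_c"].mean() - h["temperature_c"].mean()
            for h, f in ens.pairs
        ]
        # each period mean has Monte-Carlo error ~0.24 degC (AR(1) n_eff)
        assert np.all(np.abs(np.asarray(diffs) - 1.35) < 1.0)
        assert abs(np.mean(diffs) - 1.35) < 0.3

    def test_null_ensemble_periods_exchangeable(self):
        """No bias, no warming: future vs historical pass a KS test."""
        ok = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = d.SimulationConfig(
                n_scenarios=1,
                scenario_years=4,
                scenario_warming_mean_c=0.0,
                scenario_warming_sd_c=0.0,
                scenario_bias_sd_c=0.0,
                seed=seed,
            )
            hist, fut = d.generate_scenario_ensemble(cfg, seed=seed).pairs[0]
            # thin to every 7th day so the AR(1) dependence (0.6^7 ~ 0.03)
            # does not invalidate the iid assumption of the KS test
            p = stats.ks_2samp(
                hist["temperature_c"][::7], fut["temperature_c"][::7]
            ).pvalue
            ok += p > 0.01
        assert ok >= 27
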