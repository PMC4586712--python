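"""Hockey-stick GLM: IRLS oracle, RR curve, attributable rates."""
import numpy as np
import pandas as pd
import pytest

import dylld as d
from dylld.config import ModelConfig
from dylld.errors import ConfigurationError, DataError
from dylld.exposure import ExposureResponseFit, _build_design


def make_fit(threshold=20.0, slope=0.1, period_mean=100.0, family="quasi-poisson-log",
             observed=None, slope_var=1e-4):
    """Hand-built fit object for closed-form checks."""
    if observed is None:
        observed = pd.DataFrame(
            {"date": pd.to_datetime(["2000-06-01"]), "dylld": [100.0],
             "temperature_c": [threshold + 1.0]}
        )
    return ExposureResponseFit(
        threshold_c=threshold,
        log_rr_per_deg=slope,
        coef=np.array([0.0, slope]),
        coef_names=["intercept", "heat_excess"],
        coef_covariance=np.diag([1e-6, slope_var]),
        heat_index=1,
        period_mean_dylld=period_mean,
        deviance_by_candidate_threshold=pd.DataFrame(),
        n_days_used=len(observed),
        family=family,
        dispersion=1.0,
        observed=observed,
    )


class TestFit:
    def test_quasipoisson_matches_independent_irls(self, small_city):
        """Slope and covariance agree with a hand-written IRLS loop."""
        tau = 23.0
        cfg = ModelConfig(threshold_grid=[tau])
        fit = d.fit(small_city["dylld"], small_city["weather"], cfg)

        merged = small_city["dylld"].merge(small_city["weather"], on="date")
        y = np.maximum(merged["dylld"].to_numpy(), 0.0)
        X, names = _build_design(merged, tau, cfg)
        beta = np.zeros(X.shape[1])
        beta[0] = np.log(y.mean())
        for _ in range(100):
            eta = X @ beta
            mu = np.exp(eta)
            z = eta + (y - mu) / mu
            WX = X * mu[:, None]
            new = np.linalg.solve(X.T @ WX, X.T @ (mu * z))
            if np.max(np.abs(new - beta)) < 1e-12:
                beta = new
                break
            beta = new
        mu = np.exp(X @ beta)
        phi = np.sum((y - mu) ** 2 / mu) / (len(y) - X.shape[1])
        cov = phi * np.linalg.inv(X.T @ (X * mu[:, None]))

        i = names.index("heat_excess")
        assert fit.log_rr_per_deg == pytest.approx(beta[i], rel=1e-6)
        np.testing.assert_allclose(fit.coef, beta, rtol=1e-6)
        np.testing.assert_allclose(fit.coef_covariance, cov, rtol=1e-5)
        assert fit.dispersion == pytest.approx(phi, rel=1e-6)

    def test_deviance_profile_invariant_to_row_order(self, small_city):
        fit1 = small_city["fit"]
        shuffled = small_city["dylld"].sample(frac=1.0, random_state=5)
        fit2 = d.fit(shuffled, small_city["weather"].sample(frac=1.0, random_state=6))
        assert fit2.threshold_c == fit1.threshold_c
        np.testing.assert_allclose(
            fit1.deviance_by_candidate_threshold["deviance"],
            fit2.deviance_by_candidate_threshold["deviance"],
            rtol=1e-8,
        )

    def test_reduced_model_shifts_slope_less_than_one_se(self, small_city):
        """Dropping humidity/trend barely moves the slope on data without them."""
        full = small_city["fit"]
        reduced = d.fit(
            small_city["dylld"],
            small_city["weather"],
            ModelConfig(humidity_term="none", threshold_grid=[full.threshold_c]),
        )
        assert abs(reduced.log_rr_per_deg - full.log_rr_per_deg) < full.slope_se

    def test_gaussian_identity_family(self, small_city):
        fit = d.fit(small_city["dylld"], small_city["weather"],
                    ModelConfig(family="gaussian-identity"))
        curve = d.rr_curve(fit, [fit.threshold_c - 1, fit.threshold_c])
        np.testing.assert_allclose(curve["rr"], 1.0)

    def test_single_summer_rejected(self, small_city):
        one = small_city["dylld"].head(92)
        with pytest.raises(DataError, match="summers"):
            d.fit(one, small_city["weather"])

    def test_threshold_grid_outside_range_rejected(self, small_city):
        with pytest.raises(ConfigurationError, match="threshold_grid"):
            d.fit(small_city["dylld"], small_city["weather"],
                  ModelConfig(threshold_grid=[60.0]))

    def test_negative_dylld_without_floor_rejected(self, small_city):
        with pytest.raises(ConfigurationError, match="floor"):
            d.fit(small_city["dylld"], small_city["weather"],
                  ModelConfig(floor_negative_dylld=False))

    def test_missing_weather_day_rejected(self, small_city):
        with pytest.raises(DataError, match="cover"):
            d.fit(small_city["dylld"], small_city["weather"].iloc[1:])


class TestRRCurve:
    def test_threshold_identity_and_closed_form(self):
        fit = make_fit(threshold=20.0, slope=0.05)
        curve = d.rr_curve(fit, [18.0, 20.0, 22.0])
        assert curve["rr"][0] == 1.0
        assert curve["rr"][1] == 1.0
        assert curve["rr"][2] == pytest.approx(np.exp(0.1), rel=1e-12)

    def test_monotone_for_positive_slope(self):
        fit = make_fit(slope=0.03)
        grid = np.linspace(10, 35, 60)
        rr = d.rr_curve(fit, grid)["rr"].to_numpy()
        assert np.all(np.diff(rr) >= 0)


class TestAttributableRate:
    def test_zero_slope_gives_zero_rate(self):
        fit = make_fit(slope=0.0, slope_var=1e-12)
        weather = pd.DataFrame(
            {"date": pd.date_range("2000-06-01", periods=5),
             "temperature_c": [18, 19, 22, 25, 21]}
        )
        dylld = pd.DataFrame({"date": weather["date"], "dylld": 100.0})
        r = d.attributable_rate(fit, weather, 100_000, dylld=dylld, seed=1)
        assert r.rate == pytest.approx(0.0, abs=1e-9)

    def test_single_hot_day_closed_form(self):
        slope = np.log(1.25)  # RR = 1.25 one degree above threshold
        fit = make_fit(threshold=24.0, slope=slope)
        weather = pd.DataFrame(
            {"date": pd.to_datetime(["2000-06-01", "2000-06-02"]),
             "temperature_c": [20.0, 25.0]}
        )
        dylld = pd.DataFrame({"date": weather["date"], "dylld": [50.0, 100.0]})
        r = d.attributable_rate(fit, weather, 100_000, dylld=dylld, seed=1)
        assert r.rate == pytest.approx(100 * 0.25 / 1.25, rel=1e-12)  # 20.0
        assert r.n_days_above == 1 and r.n_summers == 1

    def test_doubling_population_halves_rate(self, small_city):
        fit = small_city["fit"]
        r1 = d.attributable_rate(fit, small_city["weather"], 1_000_000, seed=3)
        r2 = d.attributable_rate(fit, small_city["weather"], 2_000_000, seed=3)
        assert r2.rate == pytest.approx(r1.rate / 2, rel=1e-12)

    def test_no_hot_days_returns_zero_with_warning(self):
        fit = make_fit(threshold=40.0)
        weather = pd.DataFrame(
            {"date": pd.date_range("2000-06-01", periods=3),
             "temperature_c": [20.0, 21.0, 22.0]}
        )
        r = d.attributable_rate(fit, weather, 100_000, "constant-baseline", seed=1)
        assert r.rate == 0.0 and r.se == 0.0 and r.warnings

    def test_constant_baseline_closed_form(self):
        fit = make_fit(threshold=24.0, slope=np.log(1.25), period_mean=80.0)
        weather = pd.DataFrame(
            {"date": pd.to_datetime(["2000-06-01", "2000-06-02"]),
             "temperature_c": [25.0, 26.0]}
        )
        r = d.attributable_rate(fit, weather, 100_000, "constant-baseline", seed=1)
        expected = 80.0 * ((1.25 - 1) + (1.25**2 - 1))
        assert r.rate == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_when_slope_positive(self, small_city):
        fit = small_city["fit"]
        assert fit.log_rr_per_deg > 0
        r = d.attributable_rate(fit, small_city["weather"], 1_000_000, seed=2)
        assert r.rate >= 0


class TestTruthRecovery:
    def test_rate_recovers_generator_truth_on_average(self, life_table):
        """With the true threshold, the attributable-rate estimator is
        unbiased for the expected floored-DYLLD excess computed day by day
        from the generator's own parameters (Monte-Carlo oracle)."""
        n_seeds, pop = 12, 1_800_000
        diffs = []
        oracle_rng = np.random.default_rng(999)

        def floored_mean(x, cfg, e_yll, n=4000):
            lam = [
                cfg.baseline_deaths_per_day * p * np.exp(b * x)
                for p, b in zip(cfg.ses_tercile_probs, cfg.group_heat_log_rr)
            ]
            counts = [oracle_rng.poisson(l, size=n) for l in lam]
            dy = e_yll * ((counts[0] - counts[2]) + (counts[1] - counts[2])) / 2
            return np.maximum(0.0, dy).mean()

        for seed in range(1, n_seeds + 1):
            cfg = d.SimulationConfig(n_years=10, baseline_deaths_per_day=37.0, seed=seed)
            w = d.generate_temperature_series(cfg, 10 * 92, seed=seed)
            deaths, truth = d.generate_deaths(cfg, w, life_table, seed=seed)
            daily = d.aggregate_daily(
                d.assign_terciles(deaths), life_table,
                d.summer_dates(cfg.start_year, cfg.n_years),
            )
            fit = d.fit(d.dylld_series(daily), w, ModelConfig(threshold_grid=[23.0]))
            est = d.attributable_rate(fit, w, pop, seed=seed).rate
            excess = np.maximum(0.0, w["temperature_c"].to_numpy() - 23.0)
            e_yll = truth.mean_yll_per_death
            base = floored_mean(0.0, cfg, e_yll, n=20000)
            total = sum(floored_mean(x, cfg, e_yll) - base for x in excess[excess > 0])
            truth_rate = total / cfg.n_years / pop * 1e5
            diffs.append(est - truth_rate)
        diffs = np.asarray(diffs)
        sem = diffs.std(ddof=1) / np.sqrt(n_seeds)
        assert abs(diffs.mean()) < 3 * sem
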