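"""End-to-end driver: simulate -> yll -> dylld -> fit -> project -> meta.

Runs every stage for each configured city, then the cross-city meta stage,
writing each stage's output as headered plain text and a final manifest
listing every artifact with its SHA-256 hash.  Deterministic for a fixed
(config, seed): running twice yields byte-identical artifacts.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ModelConfig, SimulationConfig, config_hash
from .disparity import dylld_series
from .errors import ConfigurationError
from .exposure import attributable_rate, fit
from .io import write_fit, write_keyvalue, write_table
from .lifetable import aggregate_daily, assign_terciles
from .meta import compare_pooled, meta_regress, pool
from .projection import scenario_impacts, temperature_shift
from .synthetic import simulate_city, summer_dates

log = logging.getLogger("dylld.pipeline")


def default_demo_config() -> dict:
    """Two-city demo configuration, scaled down for a quick run.

    City A emulates a cooler-baseline city with the stronger designed
    vulnerability gradient; city B a warmer-threshold-at-22 city with a
    weaker gradient and less scenario warming.
    """
    return {
        "cities": [
            {
                "name": "city_a",
                "population": 1_812_723,
                "simulation": {
                    "n_years": 10,
                    "baseline_deaths_per_day": 37.0,
                    "true_threshold_c": 23.0,
                    "temp_mean_c": 20.4,
                    "temp_sd_c": 3.24,
                    "group_heat_log_rr": [0.09, 0.05, 0.02],
                    "n_scenarios": 8,
                    "scenario_years": 8,
                    "scenario_warming_mean_c": 1.35,
                },
            },
            {
                "name": "city_b",
                "population": 2_234_105,
                "simulation": {
                    "n_years": 6,
                    "baseline_deaths_per_day": 35.2,
                    "true_threshold_c": 22.0,
                    "temp_mean_c": 19.63,
                    "temp_sd_c": 3.21,
                    "group_heat_log_rr": [0.06, 0.035, 0.015],
                    "n_scenarios": 8,
                    "scenario_years": 8,
                    "scenario_warming_mean_c": 1.12,
                },
            },
        ],
        "model": {},
    }


def validate_config(config: dict) -> None:
    """Fail fast: structural checks before any stage runs."""
    if "cities" not in config or not config["cities"]:
        raise ConfigurationError("pipeline config needs a non-empty 'cities' list")
    for city in config["cities"]:
        if "name" not in city:
            raise ConfigurationError("every city needs a 'name'")
        if "population" not in city or city["population"] <= 0:
            raise ConfigurationError(f"city {city.get('name')}: positive 'population' required")
        SimulationConfig.from_mapping(city.get("simulation", {}))
        for key in ("deaths_path", "lifetable_path", "weather_path"):
            if key in city and not Path(city[key]).exists():
                raise ConfigurationError(f"city {city['name']}: {key} {city[key]} not found")
    ModelConfig.from_mapping(config.get("model", {}))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir, seed: int = 0) -> dict:
    """Run every stage for each city plus the cross-city meta stage.

    Returns the manifest mapping relative artifact paths to SHA-256 hashes;
    also written to ``<outdir>/manifest.json``.
    """
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model_config = ModelConfig.from_mapping(config.get("model", {}))
    chash = config_hash(config)
    artifacts: list[Path] = []
    per_city: dict[str, dict] = {}

    for i, city in enumerate(config["cities"]):
        name = city["name"]
        city_seed = seed + 1000 * i
        meta_hdr = {"config_hash": chash, "seed": city_seed, "city": name}
        cdir = outdir / name
        sim_cfg = SimulationConfig.from_mapping(
            {**city.get("simulation", {}), "seed": city_seed}
        )

        log.info("[%s/simulate] generating synthetic city", name)
        sim = simulate_city(sim_cfg, seed=city_seed)
        weather, deaths, table = sim["weather"], sim["deaths"], sim["life_table"]
        write_table(weather, cdir / "weather.csv", meta_hdr)
        write_table(deaths, cdir / "deaths.csv", meta_hdr)
        write_table(table.to_frame(), cdir / "lifetable.csv", meta_hdr)
        truth = sim["ground_truth"]
        write_keyvalue(
            {
                "config": sim_cfg.to_mapping(),
                "expected_daily_yll_at_reference": truth.expected_daily_yll_at_reference,
                "mean_yll_per_death": truth.mean_yll_per_death,
                "scenario_warming_delta_c": sim["ensemble"].warming_delta_c,
                "scenario_bias_c": sim["ensemble"].bias_c,
            },
            cdir / "ground_truth.txt",
            meta_hdr,
        )
        for sid, (hist, fut) in enumerate(sim["ensemble"].pairs):
            combined = pd.concat(
                [hist.assign(period="historical"), fut.assign(period="future")],
                ignore_index=True,
            )
            write_table(combined, cdir / "ensemble" / f"scenario_{sid:02d}.csv", meta_hdr)
        artifacts += [cdir / "weather.csv", cdir / "deaths.csv", cdir / "lifetable.csv",
                      cdir / "ground_truth.txt"]
        artifacts += sorted((cdir / "ensemble").glob("scenario_*.csv"))

        log.info("[%s/yll] aggregating daily YLL by tercile", name)
        min_age = city.get("min_age")
        if min_age is not None:
            deaths = deaths[deaths["age"] >= min_age].reset_index(drop=True)
        labeled = assign_terciles(deaths)
        calendar = summer_dates(sim_cfg.start_year, sim_cfg.n_years, sim_cfg.days_per_summer)
        daily = aggregate_daily(labeled, table, calendar)
        write_table(daily, cdir / "daily_yll.csv", meta_hdr)
        artifacts.append(cdir / "daily_yll.csv")

        log.info("[%s/dylld] computing the disparity index", name)
        dser = dylld_series(daily)
        write_table(dser, cdir / "dylld.csv", meta_hdr)
        artifacts.append(cdir / "dylld.csv")

        log.info("[%s/fit] fitting the exposure-response model", name)
        fit_result = fit(dser, weather, model_config)
        write_fit(fit_result, cdir / "fit.txt", meta_hdr)
        artifacts.append(cdir / "fit.txt")

        log.info("[%s/attribute] historical attributable rate", name)
        rate = attributable_rate(
            fit_result, weather, city["population"], "observed-dylld", seed=city_seed
        )
        write_table(
            pd.DataFrame(
                [{
                    "rate_per_100k": rate.rate, "se": rate.se,
                    "ci_low": rate.ci_low, "ci_high": rate.ci_high,
                    "n_summers": rate.n_summers, "n_days_above": rate.n_days_above,
                    "mode": rate.mode,
                }]
            ),
            cdir / "attributable.csv",
            meta_hdr,
        )
        artifacts.append(cdir / "attributable.csv")

        log.info("[%s/project] scenario impacts (ICC)", name)
        impacts = scenario_impacts(
            fit_result, sim["ensemble"], weather, city["population"], seed=city_seed
        )
        write_table(impacts, cdir / "impacts.csv", meta_hdr)
        shifts = temperature_shift(sim["ensemble"])
        write_table(shifts, cdir / "temperature_shift.csv", meta_hdr)
        artifacts += [cdir / "impacts.csv", cdir / "temperature_shift.csv"]

        per_city[name] = {
            "impacts": impacts,
            "shifts": shifts,
            "fit": fit_result,
            "historical_rate": rate,
        }

    log.info("[meta] pooling across scenarios and comparing cities")
    summary = meta_summary(per_city)
    write_keyvalue(summary, outdir / "meta" / "summary.txt", {"config_hash": chash, "seed": seed})
    artifacts.append(outdir / "meta" / "summary.txt")

    manifest = {
        "dylld_version": __version__,
        "config_hash": chash,
        "seed": seed,
        "artifacts": {
            str(p.relative_to(outdir)): _sha256(p) for p in artifacts
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def meta_summary(per_city: dict) -> dict:
    """Cross-city meta stage: pooled ICC / warming per city, city contrasts."""
    summary: dict = {"per_city": {}, "note": (
        "standard errors of rates and ICC come from seeded multivariate-normal "
        "coefficient draws, not an analytic formula"
    )}
    pooled_icc = {}
    pooled_shift = {}
    for name, res in per_city.items():
        imp = res["impacts"]
        ok = imp[~imp["excluded"]]
        icc_pool = pool(ok["icc"], ok["log_icc_se"], log_scale=True)
        shift_pool = pool(res["shifts"]["delta_c"], res["shifts"]["se"])
        pooled_icc[name] = icc_pool
        pooled_shift[name] = shift_pool
        summary["per_city"][name] = {
            "pooled_icc": icc_pool.value,
            "pooled_icc_ci": [icc_pool.ci_low, icc_pool.ci_high],
            "icc_tau_squared": icc_pool.tau_squared,
            "pooled_warming_c": shift_pool.value,
            "pooled_warming_ci": [shift_pool.ci_low, shift_pool.ci_high],
            "historical_rate_per_100k": res["historical_rate"].rate,
            "historical_rate_ci": [res["historical_rate"].ci_low, res["historical_rate"].ci_high],
            "threshold_c": res["fit"].threshold_c,
            "n_scenarios_pooled": int(icc_pool.k),
        }
    names = list(per_city)
    if len(names) == 2:
        a, b = names
        icc_cmp = compare_pooled(pooled_icc[a], pooled_icc[b])
        shift_cmp = compare_pooled(pooled_shift[a], pooled_shift[b])
        def usable(name):
            imp = per_city[name]["impacts"]
            return imp[(~imp["excluded"]) & (imp["future_rate"] > 0)
                       & (imp["future_rate_se"] > 0)]

        imp_a, imp_b = usable(a), usable(b)
        if imp_a.empty or imp_b.empty:
            summary["city_comparison"] = {
                "error": "a city has no scenario with a positive attributable rate"
            }
            return summary
        values = np.concatenate([imp_a["icc"], imp_b["icc"]])
        ses = np.concatenate([imp_a["log_icc_se"] * imp_a["icc"],
                              imp_b["log_icc_se"] * imp_b["icc"]])
        covariate = np.concatenate([np.ones(len(imp_a)), np.zeros(len(imp_b))])
        mr_icc = meta_regress(values, ses, covariate)
        fut = np.concatenate([imp_a["future_rate"], imp_b["future_rate"]])
        fut_se = np.concatenate([imp_a["log_future_rate_se"], imp_b["log_future_rate_se"]])
        mr_ln_rate = meta_regress(fut, fut_se, covariate, log_scale=True)
        fut_se_id = np.concatenate([imp_a["future_rate_se"], imp_b["future_rate_se"]])
        mr_rate = meta_regress(fut, fut_se_id, covariate)
        summary["city_comparison"] = {
            "cities": {"coded_1": a, "coded_0": b},
            "icc_difference": icc_cmp.difference,
            "icc_difference_p": icc_cmp.p_value,
            "warming_difference_c": shift_cmp.difference,
            "warming_difference_p": shift_cmp.p_value,
            "meta_regression_icc_beta": mr_icc.beta_city,
            "meta_regression_icc_ci": [mr_icc.ci_low, mr_icc.ci_high],
            "meta_regression_icc_p": mr_icc.p_value,
            "meta_regression_ln_future_rate_beta": mr_ln_rate.beta_city,
            "meta_regression_ln_future_rate_p": mr_ln_rate.p_value,
            "meta_regression_future_rate_beta": mr_rate.beta_city,
            "meta_regression_future_rate_ci": [mr_rate.ci_low, mr_rate.ci_high],
            "meta_regression_future_rate_p": mr_rate.p_value,
        }
    return summary


__all__ = ["default_demo_config", "validate_config", "run_pipeline", "meta_summary"]
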