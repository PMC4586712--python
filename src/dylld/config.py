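"""Configuration objects for the simulator and the exposure-response model.

Both configs are plain dataclasses so they can be round-tripped through YAML
(`from_mapping` / `to_mapping`) and hashed for output provenance.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .errors import ConfigurationError

#: SES tercile labels, from most to least vulnerable. "low" means low
#: socioeconomic status (high % without a high-school diploma).
TERCILES = ("low", "mid", "high")

#: The most-advantaged tercile, used as the disparity reference group.
REFERENCE_TERCILE = "high"


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic city.

    The defaults emulate a large northern city: ~3,400 non-accidental deaths
    per summer, summer daily mean temperature ~20.4 degC (SD ~3.2), a heat
    effect on death counts that switches on above ``true_threshold_c`` and is
    strongest in the lowest-SES tercile, and a 30-member climate-scenario
    ensemble warming by ~1.35 degC on average between its historical and
    future periods.
    """

    n_years: int = 18
    days_per_summer: int = 92  # June-August
    start_year: int = 1990
    baseline_deaths_per_day: float = 37.0
    ses_tercile_probs: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)
    #: log relative risk on death counts per degC above threshold, ordered
    #: (low SES, mid, high SES); the designed vulnerability gradient.
    group_heat_log_rr: Sequence[float] = (0.09, 0.05, 0.02)
    true_threshold_c: float = 23.0
    temp_mean_c: float = 20.4
    temp_sd_c: float = 3.24
    temp_ar1: float = 0.6
    seasonal_amplitude_c: float = 2.0
    humidity_mean_pct: float = 65.0
    humidity_sd_pct: float = 12.0
    # age-at-death distribution: truncated Gaussian on completed years
    age_mean: float = 78.0
    age_sd: float = 12.0
    age_min: int = 35
    max_age: int = 105
    sex_gap_years: float = 4.0
    # climate-scenario ensemble
    n_scenarios: int = 30
    scenario_years: int = 30  # summers per period (historical and future)
    scenario_hist_start_year: int = 1981
    scenario_future_start_year: int = 2021
    scenario_warming_mean_c: float = 1.35
    scenario_warming_sd_c: float = 0.3
    scenario_bias_sd_c: float = 1.0
    population: int = 1_800_000
    seed: int = 0

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.ses_tercile_probs)
        if len(probs) != 3 or any(p <= 0 for p in probs):
            raise ConfigurationError("ses_tercile_probs must be 3 positive values")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ConfigurationError("ses_tercile_probs must sum to 1 within 1e-12")
        self.ses_tercile_probs = probs
        rr = tuple(float(r) for r in self.group_heat_log_rr)
        if len(rr) != 3:
            raise ConfigurationError("group_heat_log_rr must have 3 values")
        if rr[0] < max(rr):
            raise ConfigurationError(
                "group_heat_log_rr must give the lowest-SES tercile the largest value"
            )
        self.group_heat_log_rr = rr
        if not (0.0 <= self.temp_ar1 < 1.0):
            raise ConfigurationError("temp_ar1 must lie in [0, 1)")
        if self.n_years < 1 or self.days_per_summer < 1:
            raise ConfigurationError("n_years and days_per_summer must be >= 1")

    @classmethod
    def from_mapping(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**data)

    def to_mapping(self) -> dict:
        out = dataclasses.asdict(self)
        out["ses_tercile_probs"] = list(self.ses_tercile_probs)
        out["group_heat_log_rr"] = list(self.group_heat_log_rr)
        return out


@dataclass
class ModelConfig:
    """Settings for the DYLLD-temperature exposure-response model."""

    season_spline_df: int = 3
    year_trend: str = "linear"  # or "factor"
    humidity_term: str = "linear"  # or "none"
    #: candidate heat thresholds (degC). None = 1 degC grid between the 50th
    #: and 98th percentile of observed temperature.
    threshold_grid: Optional[Sequence[float]] = None
    family: str = "quasi-poisson-log"  # or "gaussian-identity"
    floor_negative_dylld: bool = True
    n_coef_draws: int = 1000

    def __post_init__(self) -> None:
        if self.year_trend not in ("linear", "factor"):
            raise ConfigurationError("year_trend must be 'linear' or 'factor'")
        if self.humidity_term not in ("linear", "none"):
            raise ConfigurationError("humidity_term must be 'linear' or 'none'")
        if self.family not in ("quasi-poisson-log", "gaussian-identity"):
            raise ConfigurationError(
                "family must be 'quasi-poisson-log' or 'gaussian-identity'"
            )
        if self.season_spline_df < 2:
            raise ConfigurationError("season_spline_df must be >= 2")

    @classmethod
    def from_mapping(cls, data: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown model config keys: {sorted(unknown)}")
        return cls(**data)

    def to_mapping(self) -> dict:
        out = dataclasses.asdict(self)
        if out["threshold_grid"] is not None:
            out["threshold_grid"] = [float(t) for t in out["threshold_grid"]]
        return out


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return data


def config_hash(mapping: dict) -> str:
    """Short stable hash of a config mapping, for output provenance."""
    blob = json.dumps(mapping, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
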