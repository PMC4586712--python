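"""Plain-text I/O: metadata-headered CSV tables and structured documents.

Every file written by the pipeline starts with ``# key: value`` comment
lines carrying the package version, config hash and seed, so any artifact
can be traced back to the run that produced it.  Readers skip those lines.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .exposure import ExposureResponseFit


def write_table(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# dylld_version: {__version__}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_table(path, parse_dates: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if parse_dates and "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    return df


def read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("# "):
                break
            key, _, value = line[2:].strip().partition(": ")
            meta[key] = value
    return meta


def write_keyvalue(data: dict, path, meta: Optional[dict] = None) -> None:
    """Structured key/value text document (JSON body under a comment header)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# dylld_version: {__version__}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        json.dump(data, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_keyvalue(path) -> dict:
    lines = [l for l in open(path) if not l.startswith("#")]
    return json.loads("".join(lines))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_fit(fit_result: ExposureResponseFit, path, meta: Optional[dict] = None) -> None:
    """Serialise an exposure-response fit as a structured text document."""
    obs = fit_result.observed
    data = {
        "threshold_c": fit_result.threshold_c,
        "log_rr_per_deg": fit_result.log_rr_per_deg,
        "coef": fit_result.coef,
        "coef_names": fit_result.coef_names,
        "coef_covariance": fit_result.coef_covariance,
        "heat_index": fit_result.heat_index,
        "period_mean_dylld": fit_result.period_mean_dylld,
        "deviance_by_candidate_threshold": fit_result.deviance_by_candidate_threshold.to_dict(
            "list"
        ),
        "n_days_used": fit_result.n_days_used,
        "family": fit_result.family,
        "dispersion": fit_result.dispersion,
        "observed": {
            "date": obs["date"].dt.strftime("%Y-%m-%d").tolist(),
            "dylld": obs["dylld"].tolist(),
            "temperature_c": obs["temperature_c"].tolist(),
        },
        "warnings": fit_result.warnings,
    }
    write_keyvalue(data, path, meta)


def read_fit(path) -> ExposureResponseFit:
    data = read_keyvalue(path)
    obs = pd.DataFrame(data["observed"])
    obs["date"] = pd.to_datetime(obs["date"])
    return ExposureResponseFit(
        threshold_c=data["threshold_c"],
        log_rr_per_deg=data["log_rr_per_deg"],
        coef=np.asarray(data["coef"]),
        coef_names=list(data["coef_names"]),
        coef_covariance=np.asarray(data["coef_covariance"]),
        heat_index=data["heat_index"],
        period_mean_dylld=data["period_mean_dylld"],
        deviance_by_candidate_threshold=pd.DataFrame(
            data["deviance_by_candidate_threshold"]
        ),
        n_days_used=data["n_days_used"],
        family=data["family"],
        dispersion=data["dispersion"],
        observed=obs,
        warnings=list(data["warnings"]),
    )


__all__ = [
    "write_table",
    "read_table",
    "read_meta",
    "write_keyvalue",
    "read_keyvalue",
    "write_fit",
    "read_fit",
]
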