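"""Small figure helpers: the RR curve and per-scenario DYLLD rates.

matplotlib is imported lazily so the rest of the package works without it.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .exposure import ExposureResponseFit, rr_curve


def plot_rr_curve(fit_result: ExposureResponseFit, ax=None, n_points: int = 100):
    """Fitted relative-risk curve over the observed temperature range."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = fit_result.observed["temperature_c"]
    grid = np.linspace(t.min(), t.max(), n_points)
    curve = rr_curve(fit_result, grid)
    ax.plot(curve["temperature_c"], curve["rr"])
    ax.axvline(fit_result.threshold_c, linestyle="--", color="grey")
    ax.set_xlabel("daily mean temperature (degC)")
    ax.set_ylabel("RR of DYLLD vs. period mean")
    return ax


def plot_scenario_rates(impacts: pd.DataFrame, ax=None):
    """Historical vs. future attributable rates across the scenario ensemble."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = impacts[~impacts["excluded"]]
    ax.scatter(ok["historical_rate"], ok["future_rate"], s=15)
    lim = max(ok["historical_rate"].max(), ok["future_rate"].max()) * 1.05
    ax.plot([0, lim], [0, lim], linestyle=":", color="grey")
    ax.set_xlabel("historical attributable DYLLD per 100,000")
    ax.set_ylabel("future attributable DYLLD per 100,000")
    return ax


__all__ = ["plot_rr_curve", "plot_scenario_rates"]
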