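"""Random-effects meta-analysis across climate scenarios, and between cities.

Per-scenario estimates (ICC ratios, attributable rates, warming deltas) are
pooled by DerSimonian-Laird random-effects meta-analysis: the
between-scenario variance tau^2 comes from the method of moments (floored at
zero), weights are 1/(SE^2 + tau^2), and confidence intervals are
normal-theory (z = 1.96).  Ratios (ICC) are pooled on the log scale and
exponentiated.  Two pooled estimates are compared by a Welch-style z test,
and a binary city covariate is assessed by method-of-moments random-effects
meta-regression.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PooledEstimate:
    value: float
    ci_low: float
    ci_high: float
    se: float  # on the reporting scale (delta method for log-pooled ratios)
    tau_squared: float
    k: int
    weights: np.ndarray  # normalised, sum to 1
    log_scale: bool

    def __post_init__(self) -> None:
        assert self.ci_low <= self.value <= self.ci_high


@dataclass
class ComparisonResult:
    difference: float
    se: float
    z: float
    p_value: float


@dataclass
class MetaRegressionResult:
    beta_city: float
    ci_low: float
    ci_high: float
    p_value: float
    k: int
    residual_tau_squared: float
    intercept: float


_Z = 1.959963984540054  # two-sided 95% normal quantile


def _check(values, ses) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(values, dtype=float)
    s = np.asarray(ses, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("values and SEs must be 1-d arrays of equal length")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    return y, s


def pool(values, ses, log_scale: bool = False) -> PooledEstimate:
    """DerSimonian-Laird random-effects pooled estimate.

    With ``log_scale=True`` the values are ratios whose SEs are already on
    the log scale; pooling happens on log values and the pooled estimate and
    CI are exponentiated (SE reported via the delta method).
    """
    y, s = _check(values, ses)
    k = y.size
    if k < 2:
        raise ValueError("need at least 2 estimates to pool")
    if log_scale:
        if np.any(y <= 0):
            raise ValueError("log-scale pooling requires positive values")
        y = np.log(y)
    w = 1.0 / s**2
    ybar_fe = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - ybar_fe) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (s**2 + tau2)
    pooled = np.sum(w_re * y) / np.sum(w_re)
    se_pooled = np.sqrt(1.0 / np.sum(w_re))
    lo, hi = pooled - _Z * se_pooled, pooled + _Z * se_pooled
    if log_scale:
        value = float(np.exp(pooled))
        return PooledEstimate(
            value=value,
            ci_low=float(np.exp(lo)),
            ci_high=float(np.exp(hi)),
            se=float(value * se_pooled),
            tau_squared=float(tau2),
            k=k,
            weights=w_re / w_re.sum(),
            log_scale=True,
        )
    return PooledEstimate(
        value=float(pooled),
        ci_low=float(lo),
        ci_high=float(hi),
        se=float(se_pooled),
        tau_squared=float(tau2),
        k=k,
        weights=w_re / w_re.sum(),
        log_scale=False,
    )


def compare_pooled(a: PooledEstimate, b: PooledEstimate) -> ComparisonResult:
    """Welch-style z comparison of two pooled estimates on the reporting scale."""
    if a.log_scale != b.log_scale:
        raise ValueError("pooled estimates are on different scales")
    diff = a.value - b.value
    se = np.sqrt(a.se**2 + b.se**2)
    if diff == 0.0:
        return ComparisonResult(difference=0.0, se=float(se), z=0.0, p_value=1.0)
    z = diff / se
    p = 2.0 * stats.norm.sf(abs(z))
    return ComparisonResult(difference=float(diff), se=float(se), z=float(z), p_value=float(p))


def meta_regress(values, ses, covariate, log_scale: bool = False) -> MetaRegressionResult:
    """Random-effects meta-regression of estimates on a binary city indicator.

    Residual tau^2 by the method of moments; coefficients by weighted least
    squares with weights 1/(SE^2 + tau^2).  ``covariate`` codes the cities 0
    and 1; beta_city is the fitted difference (level 1 minus level 0).
    """
    y, s = _check(values, ses)
    x = np.asarray(covariate, dtype=float)
    if x.shape != y.shape:
        raise ValueError("covariate must match the estimates in length")
    levels = np.unique(x)
    if levels.size < 2:
        raise ValueError("covariate must have both levels present")
    k = y.size
    if k < 4:
        raise ValueError("need at least 4 estimates for meta-regression")
    if log_scale:
        if np.any(y <= 0):
            raise ValueError("log-scale regression requires positive values")
        y = np.log(y)

    X = np.column_stack([np.ones(k), x])
    p = X.shape[1]
    w = 1.0 / s**2
    W = np.diag(w)
    xtwx_inv = np.linalg.inv(X.T @ W @ X)
    beta_fe = xtwx_inv @ X.T @ W @ y
    resid = y - X @ beta_fe
    q_e = float(np.sum(w * resid**2))
    trace_p = float(np.sum(w) - np.trace(xtwx_inv @ (X.T @ np.diag(w**2) @ X)))
    tau2 = max(0.0, (q_e - (k - p)) / trace_p) if trace_p > 0 else 0.0

    w_re = 1.0 / (s**2 + tau2)
    W_re = np.diag(w_re)
    cov = np.linalg.inv(X.T @ W_re @ X)
    beta = cov @ X.T @ W_re @ y
    se_beta = float(np.sqrt(cov[1, 1]))
    b = float(beta[1])
    z = b / se_beta
    return MetaRegressionResult(
        beta_city=b,
        ci_low=b - _Z * se_beta,
        ci_high=b + _Z * se_beta,
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        k=k,
        residual_tau_squared=float(tau2),
        intercept=float(beta[0]),
    )


__all__ = [
    "PooledEstimate",
    "ComparisonResult",
    "MetaRegressionResult",
    "pool",
    "compare_pooled",
    "meta_regress",
]
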