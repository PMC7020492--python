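"""Model-adequacy statistics for paired observed/predicted series.

Implements the usual agreement suite for biological simulation models:
mean bias, R^2, Pearson r, mean prediction error (RMSE as a percent of the
observed mean; <5 % is conventionally "excellent"), modelling efficiency
(1 means perfect, <0 worse than predicting the observed mean), the variance
ratio, Lin's bias-correction factor Cb and the concordance correlation
coefficient CCC = r * Cb, plus plain RMSE/MAE, response ratios for
effect-size comparisons, and an OLS test of the limited-homeothermy slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm


@dataclass
class EvalStats:
    mean_obs: float
    mean_pred: float
    mean_bias: float  # observed minus predicted: over-prediction is negative
    r2: float
    r: float
    mpe: float  # % of observed mean
    mef: float
    variance_ratio: float  # sd_obs / sd_pred
    cb: float
    ccc: float
    rmse: float
    mae: float
    n: int


def _as_paired(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have the same length")
    return obs, pred


def error_stats(observed, predicted) -> tuple[float, float]:
    """Root mean square error and mean absolute error."""
    obs, pred = _as_paired(observed, predicted)
    if obs.size == 0:
        raise ValueError("empty series")
    resid = obs - pred
    return float(np.sqrt(np.mean(resid**2))), float(np.mean(np.abs(resid)))


def adequacy_stats(observed, predicted) -> EvalStats:
    """Full agreement suite for a paired series (n >= 3).

    Mean bias is observed minus predicted, so a model that over-predicts
    shows a negative bias.  Cb uses sample standard deviations with
    ``u = (mean_obs - mean_pred)/sqrt(sd_obs * sd_pred)`` and
    ``Cb = 2/(v + 1/v + u^2)`` where ``v = sd_obs/sd_pred``.
    """
    obs, pred = _as_paired(observed, predicted)
    n = obs.size
    if n < 3:
        raise ValueError("need at least 3 paired points")
    sd_obs = float(np.std(obs, ddof=1))
    sd_pred = float(np.std(pred, ddof=1))
    if sd_obs == 0.0 or sd_pred == 0.0:
        raise ValueError("degenerate input: zero variance in a series")

    mean_obs = float(np.mean(obs))
    mean_pred = float(np.mean(pred))
    rmse, mae = error_stats(obs, pred)
    r = float(np.corrcoef(obs, pred)[0, 1])
    mef = 1.0 - float(np.sum((obs - pred) ** 2) / np.sum((obs - mean_obs) ** 2))
    v = sd_obs / sd_pred
    u = (mean_obs - mean_pred) / np.sqrt(sd_obs * sd_pred)
    cb = 2.0 / (v + 1.0 / v + u**2)
    if mean_obs == 0.0:
        raise ValueError("MPE undefined for zero observed mean")
    return EvalStats(
        mean_obs=mean_obs,
        mean_pred=mean_pred,
        mean_bias=mean_obs - mean_pred,
        r2=r**2,
        r=r,
        mpe=100.0 * rmse / mean_obs,
        mef=mef,
        variance_ratio=v,
        cb=cb,
        ccc=r * cb,
        rmse=rmse,
        mae=mae,
        n=int(n),
    )


def response_ratio(series, control_series) -> np.ndarray:
    """Elementwise treatment/control ratio (effect size on each day).

    A control series divided by itself is 1 everywhere.  Days with a zero
    control value are returned as NaN with a warning.
    """
    treat, control = _as_paired(series, control_series)
    zero = control == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero control value(s): response ratio set to NaN",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = treat / control
    rr[zero] = np.nan
    return rr


def homeothermy_test(t_air, t_leaf) -> dict[str, float]:
    """OLS of leaf on air temperature with slope tests against 0 and 1.

    A slope strictly between 0 and 1 indicates limited homeothermy: leaves
    buffer the swings of their aerial environment.  Returns slope,
    intercept, r2 and two-sided p-values for slope = 0 and slope = 1.
    """
    x, y = _as_paired(t_air, t_leaf)
    if x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.std(x) == 0.0:
        raise ValueError("air temperature series is constant")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    p_vs_1 = float(fit.t_test("x1 = 1").pvalue)
    return {
        "slope": slope,
        "intercept": float(fit.params[0]),
        "r2": float(fit.rsquared),
        "p_vs_0": float(fit.pvalues[1]),
        "p_vs_1": p_vs_1,
        "slope_se": float(fit.bse[1]),
        "n": int(x.size),
    }
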