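"""Model comparison: information criteria, predictive agreement, holdout.

WAIC is computed from the pointwise posterior log-likelihood matrix
(samples x observations):

    lppd   = sum_obs log( mean_samples exp(loglik) )     (log-sum-exp)
    p_waic = sum_obs var_samples(loglik)                 (ddof = 1)
    WAIC   = -2 (lppd - p_waic)

Pointwise contributions are retained so that differences between models can
be reported with a paired standard error, and models whose WAIC
distribution overlaps the best one can be flagged.

Predictive agreement uses R^2 from a regression constrained through the
origin: slope b = sum(x y)/sum(x^2) with x = predicted, and
R^2 = 1 - sum((y - b x)^2) / sum(y^2) (uncentred total sum of squares).
Algebraically R^2 = (sum xy)^2 / (sum x^2 sum y^2), the squared uncentred
correlation: invariant to common rescaling and symmetric in its arguments,
although the fitted slope is not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .connectome import TransportOperator
from .inference import (LikelihoodEvaluator, ObservationSet, PosteriorSamples,
                        Prior, fit, map_estimate)

__all__ = [
    "FitMetrics",
    "waic",
    "aic_bic_mse",
    "r2_origin",
    "per_timepoint_agreement",
    "delta_table",
    "leave_one_timepoint_out",
    "n_free_parameters",
    "evaluate_fit",
]

logger = logging.getLogger(__name__)


@dataclass
class FitMetrics:
    """Container for the comparison metrics of one fitted model."""

    waic: float = np.nan
    waic_pointwise: np.ndarray | None = None
    lppd: float = np.nan
    p_waic: float = np.nan
    aic: float = np.nan
    bic: float = np.nan
    mse: float = np.nan
    n_params: int = 0
    n_obs: int = 0


def waic(log_lik_pointwise: np.ndarray) -> FitMetrics:
    """Widely Applicable Information Criterion from pointwise log-likelihoods.

    ``log_lik_pointwise`` is (samples, observations).  Pointwise WAIC
    contributions ``-2 (lppd_i - p_waic_i)`` are returned so that paired
    standard errors of WAIC differences can be formed.
    """
    ll = np.asarray(log_lik_pointwise, dtype=float)
    if ll.ndim != 2 or ll.shape[1] < 1:
        raise ValueError("need a 2-D (samples, observations) array")
    S = ll.shape[0]
    if S < 2:
        raise ValueError("WAIC needs >= 2 posterior samples (variance undefined)")
    lppd_i = logsumexp(ll, axis=0) - math.log(S)
    p_i = ll.var(axis=0, ddof=1)
    pointwise = -2.0 * (lppd_i - p_i)
    return FitMetrics(
        waic=float(pointwise.sum()),
        waic_pointwise=pointwise,
        lppd=float(lppd_i.sum()),
        p_waic=float(p_i.sum()),
        n_obs=ll.shape[1],
    )


def aic_bic_mse(
    map_loglik: float, n_params: int, n_obs: int, residuals: Sequence[float]
) -> FitMetrics:
    """AIC = 2k - 2 loglik; BIC = k ln(n) - 2 loglik; MSE of MAP residuals."""
    if n_obs < 1:
        raise ValueError("need at least one observation")
    r = np.asarray(residuals, dtype=float)
    return FitMetrics(
        aic=2.0 * n_params - 2.0 * map_loglik,
        bic=n_params * math.log(n_obs) - 2.0 * map_loglik,
        mse=float(np.mean(r**2)) if r.size else np.nan,
        n_params=int(n_params),
        n_obs=int(n_obs),
    )


def n_free_parameters(model: str, n_regions: int, bidirectional: bool = False) -> int:
    """Count of free sampled parameters per model class."""
    extra = 1 if bidirectional else 0
    if model == "diff":
        return 3 + extra  # rho, u0, sigma
    if model == "diff_r":
        return 4 + extra + n_regions  # + alpha + beta_i
    if model == "diff_rf":
        return 4 + extra + 2 * n_regions  # + gamma_i
    raise ValueError(f"unknown model {model!r}")


def r2_origin(predicted: Sequence[float], observed: Sequence[float]) -> tuple[float, float]:
    """R^2 and slope of the through-origin regression of observed on predicted."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("predicted and observed must be equal-length vectors (>= 2)")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all-zero predictions: through-origin slope undefined")
    b = float(np.sum(x * y)) / sxx
    syy = float(np.sum(y * y))
    if syy == 0:
        return (1.0 if np.allclose(y, b * x) else -np.inf), b
    r2 = 1.0 - float(np.sum((y - b * x) ** 2)) / syy
    return r2, b


def per_timepoint_agreement(
    predicted: np.ndarray,
    obs: ObservationSet,
    log_space: bool = False,
) -> pd.DataFrame:
    """Through-origin R^2 at each timepoint, optionally in log10-log10 space.

    ``predicted`` is the region x time solution matrix on ``obs.times``.
    In log space, pairs where either value is non-positive are dropped and
    the drop count reported.  Timepoints with fewer than two surviving
    pairs get a null R^2 with a logged reason.
    """
    predicted = np.asarray(predicted, dtype=float)
    rows = []
    for t in range(obs.times.size):
        m = obs.time_idx == t
        x = predicted[obs.region_idx[m], obs.time_idx[m]]
        y = obs.value[m]
        dropped = 0
        if log_space:
            ok = (x > 0) & (y > 0)
            dropped = int((~ok).sum())
            x, y = np.log10(x[ok]), np.log10(y[ok])
        r2 = slope = None
        if x.size >= 2 and np.sum(x * x) > 0:
            r2, slope = r2_origin(x, y)
        else:
            logger.info("timepoint %g: %d surviving pairs, R^2 undefined",
                        obs.times[t], x.size)
        rows.append({"time_months": obs.times[t], "r2": r2, "slope": slope,
                     "n_pairs": int(x.size), "n_dropped": dropped})
    return pd.DataFrame(rows)


def delta_table(metrics: dict[str, FitMetrics]) -> pd.DataFrame:
    """Relative comparison table across models.

    Per criterion the minimum is subtracted; for WAIC the paired standard
    error of the difference to the best model is computed from pointwise
    contributions, and models within 2 paired SEs are flagged as
    overlapping the best.
    """
    if len(metrics) < 2:
        raise ValueError("need at least two models to compare")
    names = list(metrics)
    n_obs = {m.n_obs for m in metrics.values() if m.waic_pointwise is not None}
    if len(n_obs) > 1:
        raise ValueError(f"models scored on different observation counts: {n_obs}")
    best = {
        crit: min(getattr(m, crit) for m in metrics.values())
        for crit in ("waic", "aic", "bic", "mse")
    }
    best_model = min(names, key=lambda k: metrics[k].waic)
    rows = []
    for name in names:
        m = metrics[name]
        row = {"model": name}
        for crit in ("waic", "aic", "bic", "mse"):
            row[f"d{crit}"] = getattr(m, crit) - best[crit]
        if m.waic_pointwise is not None:
            d = m.waic_pointwise - metrics[best_model].waic_pointwise
            se = float(np.sqrt(d.size * d.var(ddof=1))) if d.size > 1 else 0.0
            row["dwaic_se"] = se
            row["overlaps_best"] = bool(name == best_model or row["dwaic"] <= 2 * se)
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_fit(
    post: PosteriorSamples,
    transport: TransportOperator,
    obs: ObservationSet,
) -> FitMetrics:
    """All comparison metrics for one posterior: WAIC plus MAP-based AIC/BIC/MSE."""
    fm = waic(post.pointwise_matrix())
    params = map_estimate(post)
    ev = LikelihoodEvaluator(post.space, transport, obs,
                             rtol=post.settings.get("rtol", 1e-6),
                             atol=post.settings.get("atol", 1e-9))
    x = post.space.pack(params)
    u = ev.forward(x)
    resid = obs.value - u[obs.region_idx, obs.time_idx]
    map_ll = float(ev.pointwise(x).sum())
    k = n_free_parameters(params.model, transport.n_regions,
                          bidirectional=post.space.bidirectional)
    fm2 = aic_bic_mse(map_ll, k, obs.n_obs, resid)
    fm.aic, fm.bic, fm.mse = fm2.aic, fm2.bic, fm2.mse
    fm.n_params, fm.n_obs = fm2.n_params, obs.n_obs
    return fm


def leave_one_timepoint_out(
    model: str,
    transport: TransportOperator,
    obs: ObservationSet,
    priors: dict[str, Prior] | None = None,
    holdout_index: int | None = None,
    rng_seed: int = 0,
    **fit_kwargs,
) -> dict:
    """Refit without one timepoint (default: the final one) and score it.

    Returns the held-out predictions plus through-origin R^2 (a) over all
    observations including the held-out ones and (b) on the held-out
    timepoint only, along with the posterior of the reduced fit.
    """
    if obs.times.size < 3:
        raise ValueError("leave-one-timepoint-out needs >= 3 timepoints")
    if holdout_index is None:
        holdout_index = obs.times.size - 1
    kept, held = obs.drop_timepoint(holdout_index)
    post = fit(model, transport, kept, priors=priors, rng_seed=rng_seed, **fit_kwargs)
    params = map_estimate(post)
    ev = LikelihoodEvaluator(post.space, transport, obs)
    u = ev.forward(post.space.pack(params))
    pred_all = u[obs.region_idx, obs.time_idx]
    r2_all, _ = r2_origin(pred_all, obs.value)
    pred_held = u[held.region_idx, held.time_idx]
    r2_held, _ = r2_origin(pred_held, held.value)
    return {
        "posterior": post,
        "map_params": params,
        "holdout_index": int(holdout_index),
        "holdout_time": float(obs.times[holdout_index]),
        "predicted_heldout": pred_held,
        "observed_heldout": held.value,
        "r2_all": r2_all,
        "r2_heldout": r2_held,
    }
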