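"""Bayesian estimation of spreading-model parameters.

The measurement model is a Gaussian with shared noise across regions,
timepoints and replicates:

    y_ijt ~ Normal(u_i(t, theta), sigma^2)

where ``u_i(t, theta)`` is the deterministic ODE solution.  Priors follow
the weakly-informative defaults in :func:`default_priors` (half-normals for
positivity-constrained parameters; a wide real normal for the DIFF-R rise
parameters, which may be negative).

Sampling strategy
-----------------
Positivity-constrained parameters are log-transformed, the posterior mode is
located with multi-start L-BFGS in the transformed space, and an affine
invariant / differential-evolution ensemble sampler (emcee) is then run from
a tight ball around the mode.  Walker trajectories are grouped into
pseudo-chains for the split Gelman-Rubin diagnostic.  ``target_accept`` is
accepted for interface parity with gradient-based (NUTS) samplers and is
ignored by the ensemble sampler.

Pointwise log-likelihoods for every retained draw are recomputed and stored,
which is what WAIC and the model-comparison layer consume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import warnings

import emcee
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.integrate import ODEintWarning, odeint

from .connectome import TransportOperator
from .dynamics import (MODEL_KINDS, ModelParameters, _rhs_diff, _rhs_diff_r,
                       _rhs_diff_rf)

__all__ = [
    "Prior",
    "default_priors",
    "empirical_prior",
    "ObservationSet",
    "PosteriorSamples",
    "log_likelihood",
    "fit",
    "map_estimate",
    "gelman_rubin",
    "posterior_updated",
]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Prior:
    """Normal or positive-truncated normal prior, N(mu, sigma) / N+(mu, sigma)."""

    kind: str  # "normal" | "truncnorm"
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "truncnorm"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.sigma <= 0:
            raise ValueError("prior scale must be positive")

    def _frozen(self):
        if self.kind == "normal":
            return stats.norm(self.mu, self.sigma)
        a = (0.0 - self.mu) / self.sigma
        return stats.truncnorm(a, np.inf, loc=self.mu, scale=self.sigma)

    def logpdf(self, x):
        if self.kind == "normal":
            return stats.norm.logpdf(x, self.mu, self.sigma)
        x = np.asarray(x, dtype=float)
        out = np.where(
            x > 0,
            stats.norm.logpdf(x, self.mu, self.sigma)
            - stats.norm.logsf(0.0, self.mu, self.sigma),
            -np.inf,
        )
        return out if out.ndim else float(out)

    def cdf(self, x):
        return self._frozen().cdf(x)

    def rvs(self, size=None, rng=None):
        return self._frozen().rvs(size=size, random_state=rng)

    def mean(self) -> float:
        return float(self._frozen().mean())

    @property
    def positive(self) -> bool:
        return self.kind == "truncnorm"


def default_priors(
    model: str, transport_mode: str = "retrograde", scale: float = 0.1
) -> dict[str, Prior]:
    """Weakly-informative defaults per model class.

    Regional entries (``beta``, ``gamma``) are shared across regions.  The
    DIFF initial-condition prior is considerably wider than in DIFF-R/RF
    because mass-conserving diffusion has to start with all the mass it will
    ever distribute.

    ``scale`` is the half-normal scale of the rate parameters (transport,
    aggregation, fall, and the DIFF-RF rise block); the default 0.1 is the
    canonical weakly-informative choice.  Parameter-recovery studies pass a
    scale commensurate with the planted truth so that the test isolates the
    likelihood and sampler rather than prior shrinkage.
    """
    if model not in MODEL_KINDS:
        raise ValueError(f"model must be one of {MODEL_KINDS}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    pos = lambda mu, s: Prior("truncnorm", mu, s)  # noqa: E731
    if model == "diff":
        priors = {"rho": pos(50.0, 10.0), "u0": pos(0.0, 50.0)}
    elif model == "diff_r":
        priors = {
            "rho": pos(0.0, scale),
            "alpha": pos(0.0, scale),
            "beta": Prior("normal", 0.0, 1.0),
            "u0": pos(0.0, 1.0),
        }
    else:
        priors = {
            "rho": pos(0.0, scale),
            "alpha": pos(0.0, scale),
            "beta": pos(0.0, scale),
            "gamma": pos(0.0, scale),
            "u0": pos(0.0, 1.0),
        }
    priors["sigma"] = pos(0.0, 0.1)
    if transport_mode == "bidirectional":
        priors["rho_secondary"] = priors["rho"]
    return priors


def empirical_prior(draws: np.ndarray, positive: bool = True) -> Prior:
    """Moment-matched (trunc)normal prior from posterior draws.

    Used to carry global-parameter posteriors from one dataset forward as
    priors for another (e.g. refitting a second seeding experiment).  For a
    positive-truncated normal the (mu, sigma) are solved so the truncated
    distribution matches the sample mean and s.d.
    """
    draws = np.asarray(draws, dtype=float)
    m, s = float(draws.mean()), float(draws.std(ddof=1))
    if s <= 0:
        raise ValueError("cannot moment-match a constant sample")
    if not positive:
        return Prior("normal", m, s)

    def moments(x):
        mu, log_sig = x
        sig = math.exp(log_sig)
        a = -mu / sig
        tn = stats.truncnorm(a, np.inf, loc=mu, scale=sig)
        return [tn.mean() - m, tn.std() - s]

    sol = optimize.fsolve(moments, [m, math.log(s)], full_output=False)
    mu, sig = float(sol[0]), float(math.exp(sol[1]))
    return Prior("truncnorm", mu, sig)


# --------------------------------------------------------------------------
# observations
# --------------------------------------------------------------------------

@dataclass
class ObservationSet:
    """Replicate-level pathology observations on a timepoint grid.

    Long-format records (region, timepoint, replicate, value); replicate
    counts may differ across timepoints.  Missing (NaN) values are dropped
    at construction.
    """

    region_ids: Sequence[str]
    times: np.ndarray
    region_idx: np.ndarray
    time_idx: np.ndarray
    replicate: np.ndarray
    value: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.region_idx = np.asarray(self.region_idx, dtype=int)
        self.time_idx = np.asarray(self.time_idx, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        if self.region_idx.max(initial=-1) >= len(self.region_ids):
            raise ValueError("region index out of range")
        if self.time_idx.max(initial=-1) >= self.times.size:
            raise ValueError("time index out of range")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, region_ids: Sequence[str]) -> "ObservationSet":
        """Build from a long table with columns region, time_months, replicate, value."""
        required = {"region", "time_months", "replicate", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"observations table missing columns: {sorted(missing)}")
        lut = {r: i for i, r in enumerate(region_ids)}
        unknown = sorted(set(df["region"]) - set(lut))
        if unknown:
            raise ValueError(f"unknown region labels in observations: {unknown[:5]}")
        keep = df["value"].notna()
        n_dropped = int((~keep).sum())
        df = df[keep]
        times = np.sort(df["time_months"].unique().astype(float))
        tidx = {t: i for i, t in enumerate(times)}
        return cls(
            region_ids=list(region_ids),
            times=times,
            region_idx=df["region"].map(lut).to_numpy(),
            time_idx=df["time_months"].astype(float).map(tidx).to_numpy(),
            replicate=df["replicate"].to_numpy(),
            value=df["value"].to_numpy(dtype=float),
            n_dropped=n_dropped,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": [self.region_ids[i] for i in self.region_idx],
                "time_months": self.times[self.time_idx],
                "replicate": self.replicate,
                "value": self.value,
            }
        )

    @property
    def n_obs(self) -> int:
        return int(self.value.size)

    def drop_timepoint(self, holdout_index: int) -> tuple["ObservationSet", "ObservationSet"]:
        """Split into (kept, held-out) sets around one timepoint index."""
        if not 0 <= holdout_index < self.times.size:
            raise IndexError(
                f"holdout index {holdout_index} out of range for {self.times.size} timepoints"
            )
        mask = self.time_idx != holdout_index
        return self._subset(mask), self._subset(~mask)

    def _subset(self, mask: np.ndarray) -> "ObservationSet":
        # the timepoint grid is kept intact so indices stay comparable
        return ObservationSet(
            region_ids=list(self.region_ids),
            times=self.times.copy(),
            region_idx=self.region_idx[mask],
            time_idx=self.time_idx[mask],
            replicate=self.replicate[mask],
            value=self.value[mask],
        )


# --------------------------------------------------------------------------
# parameter space: packing, transforms, priors
# --------------------------------------------------------------------------

class ParameterSpace:
    """Maps between flat sample vectors and :class:`ModelParameters`.

    Vector layout: globals (rho[, rho_secondary][, alpha], u0, sigma) then
    regional blocks (beta, then gamma for DIFF-RF).  Positive parameters are
    log-transformed for optimization and sampling; the Jacobian of the
    transform is included in the sampled density.
    """

    def __init__(
        self,
        model: str,
        n_regions: int,
        seeds: Sequence[int],
        priors: dict[str, Prior],
        bidirectional: bool = False,
    ):
        if model not in MODEL_KINDS:
            raise ValueError(f"model must be one of {MODEL_KINDS}")
        self.model = model
        self.n_regions = int(n_regions)
        self.seeds = [int(s) for s in seeds]
        self.bidirectional = bool(bidirectional)
        names: list[str] = ["rho"]
        if bidirectional:
            names.append("rho_secondary")
        if model in ("diff_r", "diff_rf"):
            names.append("alpha")
        names += ["u0", "sigma"]
        if model in ("diff_r", "diff_rf"):
            names += [f"beta[{i}]" for i in range(n_regions)]
        if model == "diff_rf":
            names += [f"gamma[{i}]" for i in range(n_regions)]
        self.names = names
        self.ndim = len(names)
        self.priors = [priors[_base_name(n)] for n in names]
        self.positive = np.array([p.positive for p in self.priors], dtype=bool)
        missing = {_base_name(n) for n in names} - set(priors)
        if missing:
            raise ValueError(f"priors missing for parameters: {sorted(missing)}")
        # vectorised prior evaluation (called once per MCMC proposal)
        self._mu = np.array([p.mu for p in self.priors])
        self._sig = np.array([p.sigma for p in self.priors])
        # per-parameter normalisation: -log sigma - log(2 pi)/2, and for
        # truncated entries the renormalisation -log P(X > 0)
        self._norm = -np.log(self._sig) - 0.5 * _LOG_2PI - np.where(
            self.positive,
            stats.norm.logsf(0.0, self._mu, self._sig),
            0.0,
        )

    # -- natural <-> transformed ------------------------------------------
    def to_unconstrained(self, x: np.ndarray) -> np.ndarray:
        z = np.array(x, dtype=float)
        z[self.positive] = np.log(z[self.positive])
        return z

    def to_natural(self, z: np.ndarray) -> np.ndarray:
        x = np.array(z, dtype=float)
        x[self.positive] = np.exp(x[self.positive])
        return x

    def log_jacobian(self, z: np.ndarray) -> float:
        # d(exp z)/dz = exp z
        return float(np.sum(z[self.positive]))

    def log_prior(self, x: np.ndarray) -> float:
        if np.any(x[self.positive] <= 0):
            return -np.inf
        r = (x - self._mu) / self._sig
        return float(np.sum(self._norm - 0.5 * r * r))

    def unpack(self, x: np.ndarray) -> ModelParameters:
        d = dict(zip(self.names, x))
        beta = gamma = None
        if self.model in ("diff_r", "diff_rf"):
            beta = np.array([d[f"beta[{i}]"] for i in range(self.n_regions)])
        if self.model == "diff_rf":
            gamma = np.array([d[f"gamma[{i}]"] for i in range(self.n_regions)])
        return ModelParameters(
            model=self.model,
            rho=float(d["rho"]),
            rho_secondary=float(d["rho_secondary"]) if self.bidirectional else None,
            alpha=float(d.get("alpha", 0.0)),
            beta=beta,
            gamma=gamma,
            u0=float(d["u0"]),
            sigma=float(d["sigma"]),
            seeds=self.seeds,
        )

    def pack(self, params: ModelParameters) -> np.ndarray:
        vals = [params.rho]
        if self.bidirectional:
            vals.append(params.rho_secondary)
        if self.model in ("diff_r", "diff_rf"):
            vals.append(params.alpha)
        vals += [params.u0, params.sigma]
        if self.model in ("diff_r", "diff_rf"):
            vals += list(params.beta)
        if self.model == "diff_rf":
            vals += list(params.gamma)
        return np.asarray(vals, dtype=float)

    def prior_draw(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([p.rvs(rng=rng) for p in self.priors])

    def prior_means(self) -> np.ndarray:
        return np.array([p.mean() for p in self.priors])


def _base_name(name: str) -> str:
    return name.split("[")[0]


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------

class LikelihoodEvaluator:
    """Caches everything needed for fast repeated likelihood evaluation."""

    def __init__(
        self,
        space: ParameterSpace,
        transport: TransportOperator,
        obs: ObservationSet,
        rtol: float = 1e-6,
        atol: float = 1e-9,
    ):
        self.space = space
        self.obs = obs
        self.rtol, self.atol = rtol, atol
        self.L = np.ascontiguousarray(transport.L_primary)
        if transport.L_secondary is not None:
            self.L2 = np.ascontiguousarray(transport.L_secondary)
            self._has_secondary = True
        else:
            self.L2 = np.zeros_like(self.L)
            self._has_secondary = False
        t = np.asarray(obs.times, dtype=float)
        self._prepend = t[0] > 0
        self.grid = np.concatenate([[0.0], t]) if self._prepend else t
        self.n = self.L.shape[0]

    def forward(self, x: np.ndarray, grid: np.ndarray | None = None) -> np.ndarray:
        """Region-by-time solution matrix for a natural parameter vector."""
        sp = self.space
        grid = self.grid if grid is None else grid
        d = x  # positional decoding, mirrors ParameterSpace layout
        k = 0
        rho = d[k]; k += 1
        if sp.bidirectional:
            rho2 = d[k]; k += 1
        else:
            rho2 = rho if self._has_secondary else 0.0
        alpha = 0.0
        if sp.model in ("diff_r", "diff_rf"):
            alpha = d[k]; k += 1
        u0 = d[k]; k += 1
        k += 1  # sigma
        u_init = np.zeros(self.n)
        u_init[sp.seeds] = u0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ODEintWarning)
            if sp.model == "diff":
                sol, info = odeint(_rhs_diff, u_init, grid,
                                   args=(self.L, self.L2, rho, rho2),
                                   rtol=self.rtol, atol=self.atol, full_output=True)
            elif sp.model == "diff_r":
                beta = np.ascontiguousarray(d[k : k + self.n])
                sol, info = odeint(_rhs_diff_r, u_init, grid,
                                   args=(self.L, self.L2, rho, rho2, alpha, beta),
                                   rtol=self.rtol, atol=self.atol, full_output=True)
            else:
                beta = np.ascontiguousarray(d[k : k + self.n])
                gamma = np.ascontiguousarray(d[k + self.n : k + 2 * self.n])
                y0 = np.concatenate([u_init, beta])
                sol, info = odeint(_rhs_diff_rf, y0, grid,
                                   args=(self.L, self.L2, rho, rho2, alpha, gamma, self.n),
                                   rtol=self.rtol, atol=self.atol, full_output=True)
        if info["message"] != "Integration successful.":
            raise FloatingPointError(f"integration failed: {info['message']}")
        if self._prepend:
            sol = sol[1:]
        return sol[:, : self.n].T

    def pointwise(self, x: np.ndarray) -> np.ndarray:
        """Per-observation Gaussian log-densities at natural vector ``x``."""
        sigma = x[self.space.names.index("sigma")]
        with np.errstate(over="ignore", invalid="ignore"):
            u = self.forward(x)
        if not np.all(np.isfinite(u)):
            raise FloatingPointError("non-finite trajectory")
        mu = u[self.obs.region_idx, self.obs.time_idx]
        r = (self.obs.value - mu) / sigma
        return -0.5 * _LOG_2PI - math.log(sigma) - 0.5 * r * r

    def total(self, x: np.ndarray) -> float:
        try:
            return float(self.pointwise(x).sum())
        except (FloatingPointError, RuntimeError) as exc:
            logger.debug("likelihood evaluation failed: %s", exc)
            return -np.inf


def log_likelihood(
    params: ModelParameters,
    transport: TransportOperator,
    obs: ObservationSet,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> tuple[float, np.ndarray]:
    """Total and per-record Gaussian log-likelihood of ``obs`` under ``params``."""
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    priors = default_priors(params.model, transport.mode)
    space = ParameterSpace(
        params.model, transport.n_regions, params.seeds, priors,
        bidirectional=transport.mode == "bidirectional",
    )
    ev = LikelihoodEvaluator(space, transport, obs, rtol=rtol, atol=atol)
    try:
        pw = ev.pointwise(space.pack(params))
    except (FloatingPointError, RuntimeError) as exc:
        logger.warning("integration failure in log_likelihood: %s", exc)
        return -np.inf, np.full(obs.n_obs, -np.inf)
    return float(pw.sum()), pw


# --------------------------------------------------------------------------
# posterior container and diagnostics
# --------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus per-draw diagnostics.

    ``draws`` is (chains, iterations, parameters) in natural (constrained)
    space.  ``log_likelihood_pointwise`` is (chains, iterations, n_obs);
    ``log_posterior`` is log-prior + log-likelihood per draw (the quantity
    maximised by :func:`map_estimate`).
    """

    draws: np.ndarray
    names: list[str]
    rhat: np.ndarray
    log_likelihood_pointwise: np.ndarray
    log_posterior: np.ndarray
    space: ParameterSpace
    priors: dict[str, Prior]
    opt_map: np.ndarray | None = None
    settings: dict = field(default_factory=dict)

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.flat, columns=self.names)

    def marginal(self, name: str) -> np.ndarray:
        return self.flat[:, self.names.index(name)]

    def pointwise_matrix(self) -> np.ndarray:
        """(total draws) x (observations) log-likelihood matrix for WAIC."""
        s = self.log_likelihood_pointwise.shape
        return self.log_likelihood_pointwise.reshape(s[0] * s[1], s[2])


def gelman_rubin(chains: np.ndarray) -> float:
    """Split Gelman-Rubin statistic for one parameter.

    ``chains`` is (n_chains, n_draws).  Each chain is split in half, the
    between- and within-chain variances are compared, and values near 1
    indicate agreement between chains.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D (chains, draws) array with >= 2 chains")
    if x.shape[1] < 10:
        raise ValueError("need >= 10 draws per chain")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    n = splits.shape[1]
    chain_means = splits.mean(axis=1)
    chain_vars = splits.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    # identical chains give sqrt((n-1)/n) < 1; floor at 1 by convention
    return float(max(np.sqrt(var_plus / W), 1.0))


def posterior_updated(
    draws: np.ndarray,
    prior: Prior,
    alpha: float = 0.001,
    n_effective: float | None = None,
) -> tuple[bool, float]:
    """Has the posterior moved away from the prior?

    One-sample Kolmogorov-Smirnov test of the pooled posterior draws
    against the analytic prior CDF; ``updated`` iff p < alpha.  MCMC draws
    are autocorrelated, so when ``n_effective`` is given the p-value is
    evaluated at that effective sample size rather than the nominal draw
    count (otherwise the test is anti-conservative and flags parameters
    the data never touched).
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("no posterior draws supplied")
    res = stats.ks_1samp(draws, prior.cdf)
    if n_effective is None:
        return bool(res.pvalue < alpha), float(res.pvalue)
    n_eff = int(max(min(n_effective, draws.size), 2))
    pvalue = float(stats.kstwo.sf(res.statistic, n_eff))
    return bool(pvalue < alpha), pvalue


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _neg_log_posterior(ev: LikelihoodEvaluator) -> Callable[[np.ndarray], float]:
    space = ev.space

    def nlp(z: np.ndarray) -> float:
        x = space.to_natural(z)
        lp = space.log_prior(x)
        if not np.isfinite(lp):
            return 1e100
        ll = ev.total(x)
        if not np.isfinite(ll):
            return 1e100
        return -(lp + ll + space.log_jacobian(z))

    return nlp


def _data_informed_start(ev: LikelihoodEvaluator) -> np.ndarray:
    """Heuristic natural-space start built from the observed burden field.

    Regional carrying capacities start at the per-region peak of the
    replicate-mean burden (the saturation level a logistic fit would see);
    fall rates start small but nonzero where the final burden sits well
    below the peak; the rise timescale starts at one per month, i.e. rise
    resolvable inside the sampling window.
    """
    obs, sp, n = ev.obs, ev.space, ev.n
    nt = obs.times.size
    sums = np.zeros((n, nt))
    cnts = np.zeros((n, nt))
    np.add.at(sums, (obs.region_idx, obs.time_idx), obs.value)
    np.add.at(cnts, (obs.region_idx, obs.time_idx), 1.0)
    with np.errstate(invalid="ignore"):
        mean_ut = np.where(cnts > 0, sums / np.maximum(cnts, 1), 0.0)
    peak = mean_ut.max(axis=1)
    final = mean_ut[:, -1]
    scale = max(peak.max(), 1e-3)

    x = np.empty(sp.ndim)
    d = dict.fromkeys(sp.names)
    d["rho"] = 0.1
    if sp.bidirectional:
        d["rho_secondary"] = 0.1
    if sp.model == "diff":
        # mass-conserving: all eventual burden must start at the seeds
        d["rho"] = max(sp.priors[0].mu, 0.1)
        d["u0"] = max(mean_ut[:, -1].sum(), 1e-2)
    else:
        d["alpha"] = 1.0
        d["u0"] = max(float(peak[sp.seeds].max()), 0.05 * scale, 1e-3)
    d["sigma"] = max(0.1 * scale, 1e-3)
    if sp.model in ("diff_r", "diff_rf"):
        floor = 0.02 * scale
        for i in range(n):
            d[f"beta[{i}]"] = max(float(peak[i]), floor)
    if sp.model == "diff_rf":
        for i in range(n):
            falling = peak[i] > 0.05 * scale and final[i] < 0.7 * peak[i]
            d[f"gamma[{i}]"] = 0.2 if falling else 0.01
    for j, name in enumerate(sp.names):
        x[j] = d[name]
    return x


def _find_map(
    ev: LikelihoodEvaluator,
    rng: np.random.Generator,
    n_starts: int = 2,
    maxiter: int = 400,
) -> np.ndarray:
    """Staged multi-start L-BFGS mode search in the unconstrained space.

    Starts: a data-informed initial vector (regional peaks as carrying
    capacities) and the prior means, plus optional prior draws.  For each
    start the global parameters are optimized first with the regional
    block frozen, then all dimensions jointly.
    """
    space = ev.space
    nlp = _neg_log_posterior(ev)
    global_idx = np.array(["[" not in n for n in space.names])

    starts = [_data_informed_start(ev),
              np.maximum(space.prior_means(), 1e-3)]
    for _ in range(max(n_starts - 2, 0)):
        draw = space.prior_draw(rng)
        draw[space.positive] = np.maximum(draw[space.positive], 1e-4)
        starts.append(draw)

    best_z, best_f = None, np.inf
    for x0 in starts:
        z0 = space.to_unconstrained(x0)
        # stage 1: globals only
        z = z0.copy()

        def nlp_globals(zg):
            zz = z.copy()
            zz[global_idx] = zg
            return nlp(zz)

        res_g = optimize.minimize(
            nlp_globals, z0[global_idx], method="L-BFGS-B",
            options={"maxiter": 200, "maxfun": 2000},
        )
        z[global_idx] = res_g.x
        # stage 2: joint refinement
        res = optimize.minimize(
            nlp, z, method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": maxiter * (space.ndim + 5)},
        )
        if res.fun < best_f:
            best_z, best_f = res.x, res.fun
    if best_z is None or not np.isfinite(best_f):
        raise RuntimeError("MAP optimization failed for every start")
    return best_z


def _fd_hessian(f: Callable[[np.ndarray], float], z0: np.ndarray,
                step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian (symmetrised)."""
    d = z0.size
    h = step * (1.0 + np.abs(z0))
    H = np.empty((d, d))
    f0 = f(z0)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        zp, zm = z0.copy(), z0.copy()
        zp[i] += h[i]
        zm[i] -= h[i]
        fp[i], fm[i] = f(zp), f(zm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            zpp = z0.copy(); zpp[i] += h[i]; zpp[j] += h[j]
            fpp = f(zpp)
            # one-sided cross term from already-computed axis values
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / (h[i] * h[j])
    return 0.5 * (H + H.T)


def _whitening_matrix(H: np.ndarray) -> np.ndarray:
    """C with C C^T ~ H^{-1}; eigenvalues clipped to keep C finite and PD.

    The relative floor bounds the dynamic range of the initial proposal
    geometry; data-free directions must be able to relax to the full prior
    width (order 1 in the transformed space), so the range is generous —
    after warmup the differential-evolution moves adapt to the realised
    ensemble spread anyway.
    """
    evals, evecs = np.linalg.eigh(H)
    floor = max(evals.max(), 1.0) * 1e-8
    evals = np.clip(evals, floor, None)
    return evecs @ np.diag(evals**-0.5)


def fit(
    model: str,
    transport: TransportOperator,
    obs: ObservationSet,
    priors: dict[str, Prior] | None = None,
    seeds: Sequence[int] | Sequence[str] = (0,),
    chains: int = 4,
    warmup: int = 1000,
    samples: int = 1000,
    target_accept: float = 0.65,
    rng_seed: int = 0,
    n_walkers: int | None = None,
    rhat_threshold: float = 1.05,
    map_starts: int = 2,
    map_maxiter: int = 400,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> PosteriorSamples:
    """Sample the posterior of one model class on one transport operator.

    ``chains``/``warmup``/``samples`` follow the usual MCMC convention
    (defaults 4/1000/1000); the ensemble sampler realises them as walker
    groups and retained ensemble iterations so that ``chains * samples``
    draws are kept in total.  Per-chain seeds derive deterministically from
    ``rng_seed``.  Any parameter with split-R-hat above ``rhat_threshold``
    triggers a convergence warning naming the parameters.
    """
    if obs.n_obs == 0:
        raise ValueError("observation set is empty")
    if priors is None:
        priors = default_priors(model, transport.mode)
    if len(seeds) and isinstance(list(seeds)[0], str):
        lut = {r: i for i, r in enumerate(transport.region_ids)}
        seeds = [lut[s] for s in seeds]
    space = ParameterSpace(
        model, transport.n_regions, seeds, priors,
        bidirectional=transport.mode == "bidirectional",
    )
    ev = LikelihoodEvaluator(space, transport, obs, rtol=rtol, atol=atol)
    rng = np.random.default_rng(rng_seed)

    z_map = _find_map(ev, rng, n_starts=map_starts, maxiter=map_maxiter)

    ndim = space.ndim
    if n_walkers is None:
        n_walkers = max(2 * ndim + 2, 2 * chains)
    n_walkers += n_walkers % 2

    def log_prob_z(z):
        x = space.to_natural(z)
        lp = space.log_prior(x)
        if not np.isfinite(lp):
            return -np.inf
        ll = ev.total(x)
        if not np.isfinite(ll):
            return -np.inf
        return lp + ll + space.log_jacobian(z)

    # Laplace preconditioning: sample in whitened coordinates
    # z = z_map + C y with C C^T ~ (Hessian at the mode)^{-1}, in which the
    # near-Gaussian posterior is close to isotropic and the ensemble moves
    # decorrelate in few steps.  The linear map has constant Jacobian, so
    # no density correction is needed.
    nlp = _neg_log_posterior(ev)
    H = _fd_hessian(nlp, z_map)
    C = _whitening_matrix(H)

    def log_prob(y):
        return log_prob_z(z_map + C @ y)

    # start the ensemble at the Laplace approximation itself (unit scale in
    # whitened coordinates), so the walkers already span the posterior's
    # soft directions instead of having to diffuse outward during warmup
    p0 = rng.standard_normal((n_walkers, ndim))
    # shrink any walker that starts where the posterior is -inf toward the
    # mode, so no walker is permanently stuck at zero density
    for w in range(n_walkers):
        tries = 0
        while not np.isfinite(log_prob(p0[w])) and tries < 30:
            p0[w] *= 0.5
            tries += 1
    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, log_prob,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler._random = np.random.RandomState(
        np.random.SeedSequence(rng_seed).spawn(1)[0].generate_state(1)[0] % (2**31)
    )
    keep_steps = max(int(np.ceil(chains * samples / n_walkers)), 100)
    with warnings.catch_warnings():
        # -inf log-probabilities at rejected proposals are expected
        warnings.simplefilter("ignore", RuntimeWarning)
        state = sampler.run_mcmc(p0, warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, keep_steps, progress=False)

    chain_y = sampler.get_chain()  # (steps, walkers, ndim)
    chain_z = np.einsum("swj,ij->swi", chain_y, C) + z_map
    chain_x = chain_z
    chain_x[:, :, space.positive] = np.exp(chain_x[:, :, space.positive])

    # Pseudo-chains for diagnostics and storage: walkers are split into
    # `chains` disjoint groups; each group's post-warmup draws, ordered by
    # ensemble step, form one chain.  Split-R-hat across groups then
    # contrasts disjoint parts of the ensemble over the first and second
    # halves of the retained phase.
    g_size = n_walkers // chains
    grouped = chain_x[:, : g_size * chains, :].reshape(
        keep_steps, chains, g_size, ndim
    )
    # (chains, steps*g_size, ndim), step-major within each group
    grouped = np.swapaxes(grouped, 0, 1).reshape(chains, -1, ndim)
    rhat = np.array(
        [gelman_rubin(grouped[:, :, j]) for j in range(ndim)]
    )
    bad = [space.names[j] for j in np.nonzero(rhat > rhat_threshold)[0]]
    if bad:
        logger.warning(
            "convergence warning: R-hat > %.3g for %d parameter(s): %s",
            rhat_threshold, len(bad), ", ".join(bad[:10]),
        )

    # retain chains*samples draws: per group, the last `samples` draws
    total = chains * samples
    if grouped.shape[1] < samples:
        raise RuntimeError("fewer retained draws than requested")
    draws = grouped[:, -samples:, :]
    flat = draws.reshape(total, ndim)

    pw = np.empty((total, obs.n_obs))
    lp_draws = np.empty(total)
    for i, x in enumerate(flat):
        try:
            p = ev.pointwise(x)
        except (FloatingPointError, RuntimeError):
            p = np.full(obs.n_obs, -np.inf)
        pw[i] = p
        lp_draws[i] = space.log_prior(x) + p.sum()

    return PosteriorSamples(
        draws=draws,
        names=list(space.names),
        rhat=rhat,
        log_likelihood_pointwise=pw.reshape(chains, samples, obs.n_obs),
        log_posterior=lp_draws.reshape(chains, samples),
        space=space,
        priors=priors,
        opt_map=space.to_natural(z_map),
        settings={
            "chains": chains, "warmup": warmup, "samples": samples,
            "n_walkers": n_walkers, "target_accept": target_accept,
            "rng_seed": rng_seed, "rtol": rtol, "atol": atol,
        },
    )


def map_estimate(post: PosteriorSamples) -> ModelParameters:
    """Maximum a posteriori parameters, taken over the retained draws."""
    lp = post.log_posterior.ravel()
    if lp.size == 0:
        raise ValueError("no draws")
    best = int(np.argmax(lp))
    return post.space.unpack(post.flat[best])


def updated_flags(
    post: PosteriorSamples, alpha: float = 0.001
) -> pd.DataFrame:
    """KS posterior-update filter applied to every parameter.

    The KS p-value for each parameter is evaluated at its effective sample
    size (chains x draws corrected for autocorrelation) so that weakly
    mixed or data-free directions are not spuriously flagged as updated.
    Returns a table (parameter, p_value, ess, updated).
    """
    import arviz as az

    rows = []
    for j, name in enumerate(post.names):
        prior = post.priors[_base_name(name)]
        ess = float(az.ess(np.asarray(post.draws[:, :, j])))
        upd, p = posterior_updated(post.flat[:, j], prior, alpha=alpha,
                                   n_effective=ess)
        rows.append({"parameter": name, "p_value": p, "ess": ess,
                     "updated": upd})
    return pd.DataFrame(rows)
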