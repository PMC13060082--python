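"""Forward simulation of the nested spreading models.

Three deterministic ODE systems on a transport Laplacian ``L`` describe
regional pathology burden ``u_i(t)`` (arbitrary load units, time in months):

DIFF      pure network diffusion,
              du_i/dt = -rho * sum_j L_ij u_j
DIFF-R    diffusion plus Fisher-KPP logistic growth with a regional
          carrying capacity ("rise parameter") beta_i,
              du_i/dt = -rho * sum_j L_ij u_j + alpha u_i (beta_i - u_i)
DIFF-RF   additionally the carrying capacity is consumed by local burden
          ("fall parameter" gamma_i >= 0), producing rise-and-fall
          trajectories,
              du_i/dt = -rho * sum_j L_ij u_j + alpha u_i (beta_i(t) - u_i)
              dbeta_i/dt = -gamma_i u_i

In DIFF-RF ``beta_i`` denotes the initial condition ``beta_i(0)`` of the
state variable; ``beta_i(t)`` may go negative, which is what drives the
terminal decay of burden.  With ``gamma = 0`` DIFF-RF reduces exactly to
DIFF-R; with ``alpha = 0`` both reduce to DIFF.

The logistic growth term is itself the large-healthy-pool limit of the
heterodimer model of prion-like conversion (healthy pool p, misfolded pool
p~ with production k0, clearances k1, k3 and conversion k2): when p >> p~,
p~ follows FKPP dynamics with alpha = k0 k2^2 / k1^2 and
beta = (k0 k2 - k1 k3) / (alpha k1)... see :func:`simulate_heterodimer`,
which exists to document and test that reduction.

Integration uses LSODA (adaptive step, switches to BDF when stiff) with a
numba-compiled right-hand side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numba
import numpy as np
from scipy.integrate import odeint

from .connectome import TransportOperator

__all__ = [
    "MODEL_KINDS",
    "ModelParameters",
    "TrajectorySet",
    "simulate",
    "classify_trajectory",
    "simulate_heterodimer",
]

logger = logging.getLogger(__name__)

MODEL_KINDS = ("diff", "diff_r", "diff_rf")


@dataclass
class ModelParameters:
    """Global and regional parameters of one model instance.

    ``beta``/``gamma`` are per-region vectors; ``seeds`` are region indices
    that start at the shared initial burden ``u0`` (all other regions start
    at zero).  ``sigma`` is the shared observation-noise s.d. of the
    Gaussian measurement model and plays no role in the dynamics.
    """

    model: str
    rho: float
    u0: float
    sigma: float
    seeds: Sequence[int]
    alpha: float = 0.0
    beta: np.ndarray | None = None
    gamma: np.ndarray | None = None
    rho_secondary: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODEL_KINDS:
            raise ValueError(f"model must be one of {MODEL_KINDS}, got {self.model!r}")
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        if self.u0 <= 0:
            raise ValueError("u0 must be positive")
        if self.model in ("diff_r", "diff_rf"):
            if self.beta is None:
                raise ValueError(f"{self.model} requires a beta vector")
            self.beta = np.asarray(self.beta, dtype=float)
        if self.model == "diff_rf":
            if self.gamma is None:
                raise ValueError("diff_rf requires a gamma vector")
            self.gamma = np.asarray(self.gamma, dtype=float)
            if np.any(self.gamma < 0):
                raise ValueError("gamma must be nonnegative")
        elif self.gamma is not None:
            raise ValueError(f"gamma is only a parameter of diff_rf, not {self.model}")
        self.seeds = [int(s) for s in self.seeds]

    @property
    def n_regions(self) -> int | None:
        return None if self.beta is None else int(self.beta.size)


@dataclass
class TrajectorySet:
    """Solution of one forward simulation on a timepoint grid."""

    times: np.ndarray
    u: np.ndarray  # regions x times
    beta_t: np.ndarray | None = None  # regions x times (DIFF-RF only)
    region_ids: Sequence[str] = field(default_factory=list)


# --- numba right-hand sides -------------------------------------------------
# Signatures: y is the packed state, L/L2 dense Laplacians.  A second
# Laplacian with rate rho2 implements bidirectional transport; passing a
# zero matrix with rho2 = 0 disables it.

@numba.njit(cache=True)
def _rhs_diff(y, t, L, L2, rho, rho2):
    return -rho * (L @ y) - rho2 * (L2 @ y)


@numba.njit(cache=True)
def _rhs_diff_r(y, t, L, L2, rho, rho2, alpha, beta):
    du = -rho * (L @ y) - rho2 * (L2 @ y)
    return du + alpha * y * (beta - y)


@numba.njit(cache=True)
def _rhs_diff_rf(y, t, L, L2, rho, rho2, alpha, gamma, n):
    u = y[:n]
    b = y[n:]
    du = -rho * (L @ u) - rho2 * (L2 @ u)
    out = np.empty(2 * n)
    out[:n] = du + alpha * u * (b - u)
    out[n:] = -gamma * u
    return out


def _initial_state(params: ModelParameters, n: int) -> np.ndarray:
    u0 = np.zeros(n)
    u0[np.asarray(params.seeds, dtype=int)] = params.u0
    return u0


def simulate(
    params: ModelParameters,
    transport: TransportOperator,
    times: Sequence[float],
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> TrajectorySet:
    """Integrate the model from t=0 and return it on the requested grid.

    ``times`` must be strictly increasing; a leading t=0 is added internally
    when absent so the seed initial condition is always applied at zero.
    Negative excursions beyond ``-10*atol`` are logged as warnings but not
    clipped (the equations are smooth; clipping would bias the likelihood).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid")
    n = transport.n_regions
    prepend = times[0] > 0
    grid = np.concatenate([[0.0], times]) if prepend else times

    L = np.ascontiguousarray(transport.L_primary)
    if transport.L_secondary is not None:
        L2 = np.ascontiguousarray(transport.L_secondary)
        rho2 = float(params.rho_secondary if params.rho_secondary is not None else params.rho)
    else:
        L2 = np.zeros_like(L)
        rho2 = 0.0

    u_init = _initial_state(params, n)
    kw = dict(rtol=rtol, atol=atol, full_output=True)
    if params.model == "diff":
        sol, info = odeint(_rhs_diff, u_init, grid,
                           args=(L, L2, params.rho, rho2), **kw)
    elif params.model == "diff_r":
        sol, info = odeint(_rhs_diff_r, u_init, grid,
                           args=(L, L2, params.rho, rho2, params.alpha, params.beta),
                           **kw)
    else:
        y0 = np.concatenate([u_init, params.beta])
        sol, info = odeint(_rhs_diff_rf, y0, grid,
                           args=(L, L2, params.rho, rho2, params.alpha, params.gamma, n),
                           **kw)
    if info["message"] != "Integration successful.":
        raise RuntimeError(
            f"ODE integration failed ({info['message']}) for params: "
            f"model={params.model} rho={params.rho} alpha={params.alpha}"
        )
    if prepend:
        sol = sol[1:]
    u = sol[:, :n].T
    beta_t = sol[:, n:].T if params.model == "diff_rf" else None
    if u.min() < -10 * atol:
        logger.warning(
            "negative pathology excursion %.3e exceeds -10*atol", u.min()
        )
    return TrajectorySet(times=times, u=u, beta_t=beta_t,
                         region_ids=list(transport.region_ids))


def classify_trajectory(series: Sequence[float], tolerance: float = 1e-6) -> str:
    """Label one regional time series.

    ``flat`` if the total range is below ``tolerance``; ``rise_and_fall`` if
    an interior maximum exceeds both endpoints by more than ``tolerance``;
    otherwise ``monotone_rise``.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or s.size < 3:
        raise ValueError("need a 1-D series of length >= 3")
    if not np.all(np.isfinite(s)):
        raise ValueError("series contains non-finite values")
    if s.max() - s.min() < tolerance:
        return "flat"
    interior_max = s[1:-1].max()
    if interior_max > s[0] + tolerance and interior_max > s[-1] + tolerance:
        return "rise_and_fall"
    return "monotone_rise"


def simulate_heterodimer(
    k0: float,
    k1: float,
    k2: float,
    k3: float,
    p_tilde0: float,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> np.ndarray:
    """Single-region heterodimer kinetics; returns the misfolded pool.

    dp/dt  = k0 - k1 p - k2 p p~        (healthy protein)
    dp~/dt = -k3 p~ + k2 p p~           (misfolded protein)

    started from the healthy steady state p(0) = k0/k1.  When p stays large
    relative to p~ the misfolded pool follows FKPP logistic dynamics with
    alpha = k0 k2^2 / k1^2 and beta = (k0 k2 - k1 k3) k1 / (k0 k2^2); this
    helper exists so tests can verify that reduction numerically.
    """

    def rhs(y, t):
        p, pt = y
        return [k0 - k1 * p - k2 * p * pt, -k3 * pt + k2 * p * pt]

    times = np.asarray(times, dtype=float)
    grid = np.concatenate([[0.0], times]) if times[0] > 0 else times
    sol = odeint(rhs, [k0 / k1, p_tilde0], grid, rtol=rtol, atol=atol)
    if times[0] > 0:
        sol = sol[1:]
    return sol[:, 1]
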