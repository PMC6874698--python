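"""Density dynamics: cyclic replicator system and nonlocal logistic family.

Two model families generate the density fields that the ranking and fitness
machinery consumes:

* a three-strategy replicator system with cyclic payoff, whose ranking order
  depends on which strategies are initially present (faces of the simplex
  are invariant);
* a nonlocal logistic integro-differential family on a strategy grid,

      d rho(v,t)/dt = k(v,t) rho - r(v) rho * C(rho, t),

  where the competition term ``C`` couples all strategies through a
  quadrature over the grid.  Supported couplings: ``"k_rho"`` (integral of
  k*rho, the time-dependent reproduction case), ``"rho"`` (integral of rho,
  the trade-off case with strategy-dependent competition weight r(v)) and
  ``"eta_r"`` (dynamics written for the generalised density eta = rho^(1/r),
  coupled through the integral of eta^r).

The logistic family is integrated in log-density space for the strategies
with positive initial density: per-capita growth rates stay well defined
through many decades of decay, which is exactly the regime the ranking
limits probe.  Strategies starting at zero density stay at zero (strong
inheritance: the dynamics cannot create strategies that are absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .grid import DensityField, StrategyGrid

__all__ = [
    "replicator_rhs",
    "simulate_replicator",
    "NonlocalLogisticModel",
    "simulate_nonlocal_logistic",
    "example2_g",
    "example2_closed_form",
    "time_dependent_reproduction_model",
    "tradeoff_model",
]

_LOG_MAX = 700.0  # exp overflow guard for float64


# ---------------------------------------------------------------------------
# Replicator system
# ---------------------------------------------------------------------------

def _check_simplex(mu: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (3,):
        raise ValueError("state must be a 3-vector of frequencies")
    if np.any(mu < -tol):
        raise ValueError("frequencies must be nonnegative")
    if abs(mu.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    return np.clip(mu, 0.0, None)


def replicator_rhs(mu) -> np.ndarray:
    """Cyclic replicator right-hand side.

    d mu_i/dt = mu_i mu_{i+1} - mu_i (mu_1 mu_2 + mu_2 mu_3 + mu_3 mu_1),
    indices cyclic (mu_4 = mu_1).  The components sum to zero, so the simplex
    is invariant.
    """
    mu = _check_simplex(mu)
    q = mu[0] * mu[1] + mu[1] * mu[2] + mu[2] * mu[0]
    nxt = np.roll(mu, -1)
    return mu * nxt - mu * q


@dataclass
class ReplicatorTrajectory:
    times: np.ndarray
    states: np.ndarray  # shape (3, n_times)

    @property
    def final(self) -> np.ndarray:
        return self.states[:, -1]


def simulate_replicator(
    mu0,
    horizon: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    n_out: int = 400,
    method: str = "LSODA",
) -> ReplicatorTrajectory:
    """Integrate the cyclic replicator system from a simplex state.

    Faces of the simplex are invariant: a coordinate starting at exactly 0 is
    pinned to 0 so that floating drift cannot resurrect an absent strategy.
    """
    mu0 = _check_simplex(np.asarray(mu0, dtype=float))
    absent = mu0 == 0.0

    def rhs(t, mu):
        mu = np.where(absent, 0.0, np.clip(mu, 0.0, None))
        q = mu[0] * mu[1] + mu[1] * mu[2] + mu[2] * mu[0]
        d = mu * np.roll(mu, -1) - mu * q
        d[absent] = 0.0
        return d

    t_eval = np.linspace(0.0, horizon, n_out)
    sol = solve_ivp(
        rhs, (0.0, horizon), mu0, method=method, rtol=rtol, atol=atol, t_eval=t_eval
    )
    if not sol.success:
        raise RuntimeError(
            f"replicator integration failed at t={sol.t[-1] if sol.t.size else 0}: "
            f"{sol.message}; last state {sol.y[:, -1] if sol.t.size else mu0}"
        )
    states = np.clip(sol.y, 0.0, None)
    states[absent, :] = 0.0
    return ReplicatorTrajectory(sol.t, states)


# ---------------------------------------------------------------------------
# Nonlocal logistic family
# ---------------------------------------------------------------------------

@dataclass
class NonlocalLogisticModel:
    """Nonlocal logistic competition model on a strategy grid.

    ``k(v, t)`` is the reproduction coefficient (callable, vectorised in v),
    ``r(v)`` the competition weight (positive), ``coupling`` selects the
    integral term, ``rho0`` the initial density over the grid.
    """

    grid: StrategyGrid
    k: Callable[[np.ndarray, float], np.ndarray]
    r: Callable[[np.ndarray], np.ndarray] | None = None
    coupling: str = "rho"
    rho0: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coupling not in ("k_rho", "rho", "eta_r"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.rho0 is None:
            self.rho0 = np.ones(self.grid.n_nodes)
        self.rho0 = np.asarray(self.rho0, dtype=float)
        if self.rho0.shape != (self.grid.n_nodes,):
            raise ValueError("rho0 must be defined on the grid")
        if np.any(self.rho0 < 0):
            raise ValueError("initial density must be nonnegative")

    def r_values(self) -> np.ndarray:
        if self.r is None:
            return np.ones(self.grid.n_nodes)
        rv = np.asarray(self.r(self.grid.nodes), dtype=float)
        rv = np.broadcast_to(rv, (self.grid.n_nodes,)).astype(float)
        if np.any(rv <= 0):
            raise ValueError("competition weight r(v) must be positive")
        return rv

    def k_values(self, t: float) -> np.ndarray:
        kv = np.asarray(self.k(self.grid.nodes, t), dtype=float)
        return np.broadcast_to(kv, (self.grid.n_nodes,)).astype(float)


def simulate_nonlocal_logistic(
    model: NonlocalLogisticModel,
    horizon: float,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-10,
    n_out: int = 201,
    t_eval=None,
    method: str = "DOP853",
    bound: float | None = None,
) -> DensityField:
    """Integrate the nonlocal logistic dynamics, returning a density field.

    Integration is carried out in log density for the strategies with
    positive initial density; the integral coupling uses the same quadrature
    weights as the measure of sets, so continuum conservation identities hold
    discretely.  A density exceeding the overflow guard aborts with a
    blow-up diagnostic.
    """
    grid = model.grid
    pos = model.rho0 > 0
    w = grid.weights
    rv = model.r_values()
    L0 = np.log(model.rho0[pos])

    def rhs(t, L):
        if np.any(L > _LOG_MAX):
            raise OverflowError(
                f"density blow-up at t={t:.4g}: log-density exceeded {_LOG_MAX}"
            )
        rho = np.zeros(grid.n_nodes)
        rho[pos] = np.exp(np.clip(L, -745.0, _LOG_MAX))
        if model.coupling == "k_rho":
            kv = model.k_values(t)
            c = float(w @ (kv * rho))
            return kv[pos] - c
        if model.coupling == "rho":
            kv = model.k_values(t)
            c = float(w @ rho)
            return kv[pos] - rv[pos] * c
        # eta_r: state is log eta, coupling integral of eta^r
        c = float(w @ np.power(rho, rv))
        kv = model.k_values(t)
        return kv[pos] / rv[pos] - c

    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, n_out)
    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(
        rhs, (0.0, horizon), L0, method=method, rtol=rtol, atol=atol, t_eval=t_eval
    )
    if not sol.success:
        raise RuntimeError(f"nonlocal logistic integration failed: {sol.message}")
    log_values = np.full((grid.n_nodes, t_eval.size), -np.inf)
    log_values[pos, :] = sol.y
    with np.errstate(over="ignore"):
        values = np.where(np.isneginf(log_values), 0.0, np.exp(np.minimum(log_values, _LOG_MAX)))
    return DensityField(
        grid, t_eval, values, log_values=log_values, bound=bound,
        meta={"coupling": model.coupling},
    )


# ---------------------------------------------------------------------------
# Closed form for the time-dependent reproduction example
# ---------------------------------------------------------------------------

def example2_g(v, t):
    """Auxiliary function g(v,t) = exp(-t e^{-vt} + (1 - e^{-vt})/v).

    At v=0 the second exponent term has the analytic limit t (series limit,
    not an epsilon offset), hence g(0,t) = exp(-t + t) = 1 exactly.
    Evaluated in log space to stay finite for small v at large t.
    """
    v = np.asarray(v, dtype=float)
    t = np.asarray(t, dtype=float)
    v, t = np.broadcast_arrays(v, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        ev = np.exp(-v * t)
        frac = np.where(v > 0, -np.expm1(-v * t) / np.where(v > 0, v, 1.0), t)
    log_g = -t * ev + frac
    return np.exp(np.minimum(log_g, _LOG_MAX)) if np.any(log_g > _LOG_MAX) else np.exp(log_g)


def _log_g(v: np.ndarray, t: float) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    ev = np.exp(-v * t)
    frac = np.where(v > 0, -np.expm1(-v * t) / np.where(v > 0, v, 1.0), t)
    return -t * ev + frac


def example2_closed_form(v, t, grid: StrategyGrid | None = None):
    """Closed-form density rho(v,t) = g(v,t) / integral_0^1 g(w,t) dw.

    The normalising integral is evaluated by quadrature on ``grid`` (default:
    a 2001-node uniform grid on [0,1]) with a log-sum-exp shift so the result
    stays finite even when g itself overflows.
    """
    if grid is None:
        grid = StrategyGrid.uniform(2001)
    t = float(t)
    log_g_nodes = _log_g(grid.nodes, t)
    shift = log_g_nodes.max()
    denom = float(grid.weights @ np.exp(log_g_nodes - shift))
    log_rho = _log_g(np.asarray(v, dtype=float), t) - shift - np.log(denom)
    return np.exp(log_rho)


# ---------------------------------------------------------------------------
# Canonical model builders
# ---------------------------------------------------------------------------

def time_dependent_reproduction_model(grid: StrategyGrid) -> NonlocalLogisticModel:
    """Logistic model with k(v,t) = v t e^{-vt}, rho0 = 1, coupling int(k rho).

    The pointwise density of this model decays to zero at every strategy
    while the total measure of [0,1] is conserved at 1 — the canonical
    demonstration that pointwise density decay does not imply measure decay.
    """
    return NonlocalLogisticModel(
        grid=grid,
        k=lambda v, t: v * t * np.exp(-v * t),
        coupling="k_rho",
        rho0=np.ones(grid.n_nodes),
        meta={"name": "time_dependent_reproduction"},
    )


def tradeoff_model(
    grid: StrategyGrid,
    k: Callable[[np.ndarray], np.ndarray],
    r: Callable[[np.ndarray], np.ndarray] | None = None,
    rho0=None,
) -> NonlocalLogisticModel:
    """Logistic trade-off model d rho/dt = k(v) rho - r(v) rho * int rho dv.

    The ratio k(v)/r(v) is an evolutionary fitness for this family: the
    strategy maximising it outgrows every other in generalised density
    eta = rho^(1/r).
    """
    return NonlocalLogisticModel(
        grid=grid,
        k=lambda v, t, _k=k: _k(v),
        r=r,
        coupling="rho",
        rho0=np.ones(grid.n_nodes) if rho0 is None else rho0,
        meta={"name": "tradeoff"},
    )
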