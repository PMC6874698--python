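"""Stage-structured population models and their analytic fitness.

Each strategy ``v`` carries a vector z(v,t) of stage densities obeying

    dz/dt = L(v) z - R(v) y(t) z,

where ``L(v)`` is the stage matrix assembled from reproduction coefficients
b_i(v) (stages i >= 2 reproduce into stage 1), stage-transition rates p_i(v)
and natural mortalities a_i(v):

    q_11 = -p_1 - a_1,   q_1i = b_i,   q_{i,i-1} = p_{i-1},
    q_ii = -p_i - a_i    (p_n = 0),

and ``y(t) = f(z, t)`` is a growth-limitation factor shared by all
strategies (default: total density over strategies and stages), scaled per
strategy by the limitation sensitivity R(v) > 0.

Because the limitation enters as a common scalar mortality, stage
*frequencies* obey an autonomous replicator-like equation whose equilibria
are eigenvectors of L, and the per-capita growth statistic
F(v,t) = sum_i (L xi)_i converges to the dominant eigenvalue lambda_1(v).
The analytic fitness landscape is

    J(v) = lambda_1(v) / R(v),

independent of initial conditions; it predicts the winner of the simulated
nonlinear competition through the generalised density eta = Z^(1/R).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .grid import DensityField, StrategyGrid

__all__ = [
    "StageModel",
    "SpectralResult",
    "build_stage_matrix",
    "dominant_eigenvalue",
    "stage_fitness",
    "simulate_stage_system",
    "frequency_trajectory",
    "frequency_solution_check",
    "long_term_F",
]


def _as_vec_fn(coef, n: int) -> Callable[[float], np.ndarray]:
    """Normalise a coefficient declaration to a callable v -> (n,) array."""
    if callable(coef):
        def fn(v, _c=coef):
            out = np.asarray(_c(v), dtype=float)
            return np.broadcast_to(out, (n,)).astype(float)
        return fn
    arr = np.broadcast_to(np.asarray(coef, dtype=float), (n,)).astype(float)
    return lambda v, _a=arr: _a


def total_density_limitation(z: np.ndarray, grid: StrategyGrid, t: float) -> float:
    """Default limitation functional: total density over strategies and stages."""
    return float(grid.weights @ z.sum(axis=1))


@dataclass
class StageModel:
    """Life-history model with ``n`` developmental stages on a strategy grid.

    ``b``, ``a``, ``p`` are callables of ``v`` (or constant arrays) returning
    per-stage vectors; ``b[0]`` must be zero (newborns do not reproduce) and
    ``p[n-1]`` is ignored (no transition out of the last stage).  ``R`` maps
    ``v`` to the positive limitation sensitivity.
    """

    n: int
    b: Callable | np.ndarray
    a: Callable | np.ndarray
    p: Callable | np.ndarray
    R: Callable | float
    grid: StrategyGrid = None
    limitation: Callable = total_density_limitation
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a stage model needs at least 2 stages")
        if self.grid is None:
            self.grid = StrategyGrid.atoms([0.0])
        self._b = _as_vec_fn(self.b, self.n)
        self._a = _as_vec_fn(self.a, self.n)
        self._p = _as_vec_fn(self.p, self.n)
        R = self.R
        if callable(R):
            self._R = lambda v, _R=R: float(_R(v))
        else:
            self._R = lambda v, _R=float(R): _R
        for v in self.grid.nodes:
            bv, av, pv = self._b(v), self._a(v), self._p(v)
            if bv[0] != 0.0:
                raise ValueError("b_1 must be zero: newborns do not reproduce")
            if np.any(bv < 0) or np.any(av < 0) or np.any(pv < 0):
                raise ValueError("b, a, p must be nonnegative")
            if self._R(v) <= 0:
                raise ValueError("R(v) must be positive")

    def coefficients(self, v: float):
        return self._b(v), self._a(v), self._p(v), self._R(v)


def build_stage_matrix(model: StageModel, v: float) -> np.ndarray:
    """Assemble the stage matrix L(v) from the life-history coefficients."""
    n = model.n
    b, a, p, _ = model.coefficients(v)
    p = p.copy()
    p[n - 1] = 0.0  # no ageing out of the last stage
    L = np.zeros((n, n))
    L[0, 0] = -p[0] - a[0]
    L[0, 1:] = b[1:]
    for i in range(1, n):
        L[i, i - 1] = p[i - 1]
        L[i, i] += -p[i] - a[i]
    return L


@dataclass
class SpectralResult:
    eigenvalues: np.ndarray  # sorted descending by real part
    dominant_vector: np.ndarray  # unit component-sum normalisation
    eigenvectors: np.ndarray  # columns, max-modulus-component normalisation
    multiplicity_flag: bool
    complex_flag: bool

    @property
    def lambda1(self) -> float:
        return float(self.eigenvalues[0].real)


def dominant_eigenvalue(L: np.ndarray, gap_tol: float = 1e-9) -> SpectralResult:
    """Spectral data of a stage matrix with the dominant eigenvalue first.

    The dominant eigenvector is normalised to unit component sum (meaningful
    for the Perron vector of an irreducible Metzler matrix); the remaining
    eigenvectors are normalised by their maximum-modulus component.  Warnings
    flag a complex or (near-)repeated dominant eigenvalue, which fall outside
    the simple-spectrum hypothesis under which F -> lambda_1 is derived.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("stage matrix must be square")
    vals, vecs = np.linalg.eig(L)
    order = np.lexsort((-vals.imag, -vals.real))
    vals, vecs = vals[order], vecs[:, order]
    complex_flag = bool(abs(vals[0].imag) > gap_tol)
    multiplicity_flag = bool(
        vals.size > 1 and abs(vals[0] - vals[1]) < gap_tol
    ) or complex_flag
    if complex_flag:
        warnings.warn("dominant eigenvalue is complex; using its real part")
    elif multiplicity_flag:
        warnings.warn("dominant eigenvalue is (nearly) repeated")
    norm_vecs = np.empty_like(vecs)
    for j in range(vals.size):
        col = vecs[:, j]
        norm_vecs[:, j] = col / col[np.argmax(np.abs(col))]
    e1 = vecs[:, 0]
    s = e1.sum()
    if abs(s) > 1e-12:
        e1 = e1 / s
    else:  # zero component sum: fall back to max-modulus convention
        e1 = norm_vecs[:, 0]
    if not complex_flag:
        e1 = e1.real
    return SpectralResult(vals, e1, norm_vecs, multiplicity_flag, complex_flag)


def stage_fitness(model: StageModel) -> pd.DataFrame:
    """Analytic fitness landscape J(v) = lambda_1(v) / R(v) over the grid.

    Consumes no initial data: the landscape is a property of the life-history
    coefficients alone.
    """
    rows = []
    for v in model.grid.nodes:
        spec = dominant_eigenvalue(build_stage_matrix(model, v))
        R = model.coefficients(v)[3]
        rows.append((v, spec.lambda1, R, spec.lambda1 / R, spec.multiplicity_flag))
    return pd.DataFrame(rows, columns=["v", "lambda1", "R", "J", "flagged"])


@dataclass
class StageTrajectory:
    model: StageModel
    times: np.ndarray
    z: np.ndarray  # shape (n_nodes, n_stages, n_times)
    y: np.ndarray  # limitation factor trace

    def total_density(self) -> np.ndarray:
        """Z(v,t) = sum_i z_i(v,t), shape (n_nodes, n_times)."""
        return self.z.sum(axis=1)

    def eta_field(self) -> DensityField:
        """Generalised density eta = Z^(1/R) as a DensityField."""
        Z = self.total_density()
        Rv = np.array([self.model.coefficients(v)[3] for v in self.model.grid.nodes])
        with np.errstate(divide="ignore"):
            logZ = np.log(Z)
        log_eta = logZ / Rv[:, None]
        values = np.where(np.isneginf(log_eta), 0.0, np.exp(np.minimum(log_eta, 700.0)))
        return DensityField(
            self.model.grid, self.times, values, log_values=log_eta
        )


def simulate_stage_system(
    model: StageModel,
    z0: np.ndarray,
    horizon: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_out: int = 201,
    method: str = "LSODA",
    bound: float = 1e12,
) -> StageTrajectory:
    """Integrate the nonlinear stage system over all strategies at once.

    ``z0`` has shape (n_nodes, n_stages) and must be nonnegative; strategies
    with zero initial density stay at zero (strong inheritance).  Total
    density exceeding ``bound`` aborts with a blow-up diagnostic.
    """
    grid = model.grid
    n, m = model.n, grid.n_nodes
    z0 = np.asarray(z0, dtype=float)
    if z0.shape != (m, n):
        raise ValueError(f"z0 must have shape ({m}, {n})")
    if np.any(z0 < 0):
        raise ValueError("initial stage densities must be nonnegative")
    Ls = np.stack([build_stage_matrix(model, v) for v in grid.nodes])
    Rv = np.array([model.coefficients(v)[3] for v in grid.nodes])

    def rhs(t, zflat):
        z = np.clip(zflat.reshape(m, n), 0.0, None)
        y = model.limitation(z, grid, t)
        dz = np.einsum("vij,vj->vi", Ls, z) - Rv[:, None] * y * z
        return dz.ravel()

    def blowup(t, zflat):
        return bound - float(grid.weights @ np.clip(zflat.reshape(m, n), 0, None).sum(axis=1))

    blowup.terminal = True
    t_eval = np.linspace(0.0, horizon, n_out)
    sol = solve_ivp(
        rhs, (0.0, horizon), z0.ravel(), method=method, rtol=rtol, atol=atol,
        t_eval=t_eval, events=blowup,
    )
    if sol.status == 1:
        raise OverflowError(
            f"total stage density exceeded the bound {bound:g} at "
            f"t={sol.t_events[0][0]:.4g}"
        )
    if not sol.success:
        raise RuntimeError(f"stage-system integration failed: {sol.message}")
    z = np.clip(sol.y.T.reshape(-1, m, n).transpose(1, 2, 0), 0.0, None)
    y_trace = np.array(
        [model.limitation(z[:, :, j], grid, sol.t[j]) for j in range(sol.t.size)]
    )
    return StageTrajectory(model, sol.t, z, y_trace)


# ---------------------------------------------------------------------------
# Frequency dynamics and the growth statistic F
# ---------------------------------------------------------------------------

def _F_of(L: np.ndarray, xi: np.ndarray) -> float:
    """F = sum of components of L xi (weighted column sums of L)."""
    return float((L @ xi).sum())


def frequency_trajectory(
    L: np.ndarray,
    xi0: np.ndarray,
    horizon: float,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    n_out: int = 401,
):
    """Integrate the nonlinear frequency system d xi/dt = L xi - xi F(xi).

    Returns ``(times, xi, F)`` where F is the per-capita growth statistic
    trace; d(sum xi)/dt = 0 holds exactly for this F convention.
    """
    L = np.asarray(L, dtype=float)
    xi0 = np.asarray(xi0, dtype=float)
    if abs(xi0.sum() - 1.0) > 1e-8:
        raise ValueError("initial frequencies must sum to 1")

    def rhs(t, xi):
        return L @ xi - xi * _F_of(L, xi)

    t_eval = np.linspace(0.0, horizon, n_out)
    sol = solve_ivp(rhs, (0.0, horizon), xi0, method="LSODA", rtol=rtol, atol=atol,
                    t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"frequency integration failed: {sol.message}")
    F = np.array([_F_of(L, sol.y[:, j]) for j in range(sol.t.size)])
    return sol.t, sol.y, F


def frequency_solution_check(
    model: StageModel, v: float, xi0: np.ndarray, horizon: float = 20.0,
    n_out: int = 201,
) -> float:
    """Max deviation between nonlinear frequencies and the linear-system route.

    The nonlinear frequency system and the normalised solution of the linear
    system d zeta/dt = L zeta coincide when started from matched data; the
    returned number is the max over time and components of their difference.
    """
    L = build_stage_matrix(model, v)
    xi0 = np.asarray(xi0, dtype=float)
    times, xi, _ = frequency_trajectory(L, xi0, horizon, n_out=n_out)
    dev = 0.0
    for j, t in enumerate(times):
        zeta = expm(L * t) @ xi0
        s = zeta.sum()
        if abs(s) < 1e-300:
            raise FloatingPointError(
                f"component sum of the linear solution crossed zero at t={t:g}"
            )
        dev = max(dev, float(np.max(np.abs(xi[:, j] - zeta / s))))
    return dev


def long_term_F(
    times: np.ndarray, xi: np.ndarray, L: np.ndarray,
    window: tuple[float, float] | None = None,
) -> float:
    """Window average of F(t) along a frequency trajectory.

    Converges to the dominant eigenvalue of ``L`` as the window end grows.
    """
    times = np.asarray(times, dtype=float)
    L = np.asarray(L, dtype=float)
    F = np.array([_F_of(L, xi[:, j]) for j in range(times.size)])
    if window is None:
        window = (0.9 * times[-1], times[-1])
    T0, T = window
    sel = (times >= T0) & (times <= T)
    if sel.sum() < 2:
        return float(F[-1])
    return float(np.trapezoid(F[sel], times[sel]) / (times[sel][-1] - times[sel][0]))
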