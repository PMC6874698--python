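"""Delay population models: simulation, characteristic roots, fitness.

A strategy ``v`` carries a state vector z(v,t) obeying the delay system

    dz_l/dt = sum_j sum_i q_lji(v) z_j(v, t - tau_i)
                  * exp(-R(v) * int_{t - tau_i}^{t} f(z, s) ds)
            + sum_j r_lj(v) z_j(v, t) - R(v) f(z, t) z_l(v, t),

where f is a shared growth-limitation functional (default: total density)
and the exponential factor is the survival of the delayed cohort through the
limitation experienced since it was produced.  Substituting
zeta = z * exp(R * int_0^t f) removes the limitation entirely and leaves the
linear delay system

    d zeta_l/dt = sum_j sum_i q_lji zeta_j(t - tau_i) + sum_j r_lj zeta_j,

whose exponential solutions e * exp(lambda t) are governed by the
characteristic equation det(H(lambda) - lambda E) = 0 with
h_lj = sum_i q_lji exp(-lambda tau_i) + r_lj.  Ranking strategies through
the generalised density eta = (sum_j z_j)^(1/R) yields the analytic fitness

    J(v) = max_i Re(lambda_i(v)) / R(v),

independent of initial history (as long as the dominant mode is excited).

Root finding localises the rightmost root in a certified half-plane: any
characteristic root is an eigenvalue of H(lambda), so |lambda| <= the
infinity-norm bound M(x) = max_l sum_j (sum_i |q_lji| e^{-x tau_i} + |r_lj|)
whenever Re lambda >= x; the fixed point of M bounds the rightmost real
part, and M evaluated at the search floor bounds the imaginary parts.
Within the search rectangle, roots are enumerated by winding-number
(argument-principle) counting with recursive subdivision and polished by
Newton iteration on the log-determinant (step = -1 / tr(M^-1 M')); a
root-count mismatch raises rather than returning a silent wrong answer.

Simulation uses the method of steps: successive integration over intervals
of length min(tau) with dense (cubic-Hermite-backed) interpolation of the
stored history.  The running limitation integral Phi(t) = int_0^t f is
carried as an auxiliary state, so the delayed survival factor uses stored
values exp(-R (Phi(t) - Phi(t - tau))) and is never re-quadratured; Phi is
extended by 0 before t = 0 (pre-simulation limitation history is taken as
absent).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .grid import DensityField, StrategyGrid

__all__ = [
    "DelayModel",
    "RootSet",
    "char_matrix",
    "characteristic_roots",
    "rightmost_root",
    "delay_fitness",
    "simulate_dde",
    "change_of_variables_check",
    "foerster_to_delay",
    "validate_root",
]


def total_density_limitation(z: np.ndarray, grid: StrategyGrid, t: float) -> float:
    return float(grid.weights @ np.clip(z, 0.0, None).sum(axis=1))


def _as_tensor_fn(coef, shape) -> Callable[[float], np.ndarray]:
    if callable(coef):
        def fn(v, _c=coef):
            return np.asarray(_c(v), dtype=float).reshape(shape)
        return fn
    arr = np.asarray(coef, dtype=float).reshape(shape)
    return lambda v, _a=arr: _a


@dataclass
class DelayModel:
    """Generic delay model on a strategy grid.

    ``q`` maps ``v`` to the (n, n, m) coefficient tensor of the delayed
    terms, ``r`` to the (n, n) matrix of undelayed linear terms, ``R`` to the
    positive limitation sensitivity.  ``f`` is the limitation functional
    (``None`` for the linear model), ``history`` the initial function
    ``(v, t) -> (n,)`` on [-max(tau), 0] (default: constant 1).
    """

    n: int
    tau: np.ndarray
    q: Callable | np.ndarray
    r: Callable | np.ndarray
    R: Callable | float = 1.0
    grid: StrategyGrid = None
    f: Callable | None = None
    history: Callable | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if np.any(self.tau <= 0):
            raise ValueError("all delays must be positive")
        if self.grid is None:
            self.grid = StrategyGrid.atoms([0.0])
        m = self.m
        self._q = _as_tensor_fn(self.q, (self.n, self.n, m)) if m else (
            lambda v: np.zeros((self.n, self.n, 0))
        )
        self._r = _as_tensor_fn(self.r, (self.n, self.n))
        R = self.R
        self._R = (lambda v, _R=R: float(_R(v))) if callable(R) else (
            lambda v, _R=float(R): _R
        )
        if self.history is None:
            self.history = lambda v, t: np.ones(self.n)
        for v in self.grid.nodes:
            if self._R(v) <= 0:
                raise ValueError("R(v) must be positive")

    @property
    def m(self) -> int:
        return self.tau.size

    @property
    def max_delay(self) -> float:
        return float(self.tau.max()) if self.m else 0.0

    def q_values(self, v: float) -> np.ndarray:
        return self._q(v)

    def r_values(self, v: float) -> np.ndarray:
        return self._r(v)

    def R_value(self, v: float) -> float:
        return self._R(v)

    def linearised(self) -> "DelayModel":
        """Copy with the limitation switched off (f = None)."""
        return DelayModel(
            self.n, self.tau.copy(), self.q, self.r, self.R, self.grid,
            None, self.history, dict(self.meta),
        )


# ---------------------------------------------------------------------------
# Characteristic problem
# ---------------------------------------------------------------------------

def char_matrix(model: DelayModel, v: float, lam: complex) -> np.ndarray:
    """H(lambda): h_lj = sum_i q_lji exp(-lambda tau_i) + r_lj."""
    q = model.q_values(v)
    r = model.r_values(v)
    if model.m == 0:
        return r.astype(complex)
    return (q * np.exp(-lam * model.tau)).sum(axis=2) + r


def _char_fns(model: DelayModel, v: float):
    q = model.q_values(v).astype(complex)
    r = model.r_values(v).astype(complex)
    tau = model.tau
    n = model.n
    E = np.eye(n, dtype=complex)

    def M(lam):
        H = (q * np.exp(-lam * tau)).sum(axis=2) + r if tau.size else r
        return H - lam * E

    def Mp(lam):
        dH = -(q * tau * np.exp(-lam * tau)).sum(axis=2) if tau.size else 0.0
        return dH - E

    def det(lam):
        return complex(np.linalg.det(M(lam)))

    return M, Mp, det


def _row_sum_bound(model: DelayModel, v: float, x: float) -> float:
    """M(x): infinity-norm bound on H(lambda) for Re lambda >= x."""
    q = np.abs(model.q_values(v))
    r = np.abs(model.r_values(v))
    if model.m:
        H = (q * np.exp(-x * model.tau)).sum(axis=2) + r
    else:
        H = r
    return float(H.sum(axis=1).max())


def _gershgorin_bound(model: DelayModel, v: float, x: float) -> float:
    """Gershgorin bound on Re of eigenvalues of H(lambda) for Re lambda >= x.

    Keeps the sign of the diagonal of r, so strongly decaying models get a
    negative bound (unlike the plain row-sum bound, which uses |r|).
    """
    q = np.abs(model.q_values(v))
    r = model.r_values(v)
    qe = q.sum(axis=2) * 1.0 if model.m == 0 else (
        q * np.exp(-x * model.tau)
    ).sum(axis=2)
    rows = np.diag(r) + qe.sum(axis=1) + (np.abs(r).sum(axis=1) - np.abs(np.diag(r)))
    return float(rows.max())


def _upper_bound(model: DelayModel, v: float) -> float:
    """Certified upper bound on Re of any characteristic root.

    Any root lambda is an eigenvalue of H(lambda); the Gershgorin row bound
    G(x) is decreasing in x, so its fixed point bounds the rightmost real
    part from above.
    """
    g = lambda x: x - _gershgorin_bound(model, v, x)
    hi = _gershgorin_bound(model, v, 0.0) + 1.0
    lo = min(-1.0, hi - 1.0)
    while g(lo) > 0:
        lo -= abs(hi) + 1.0
    while g(hi) < 0:
        hi += abs(hi) + 1.0
    return brentq(g, lo, hi, xtol=1e-9) + 1e-6


def _residual(M, det, z) -> float:
    """Scale-normalised determinant residual at a candidate root."""
    scale = max(1.0, float(np.linalg.norm(M(z), np.inf))) ** (M(z).shape[0] - 1)
    return abs(det(z)) / scale


class RootSearchError(RuntimeError):
    """Root enumeration could not be certified (count mismatch)."""


def _winding(det, corners: list[complex], max_points: int = 40000) -> int:
    """Winding number of det along the closed polygon through ``corners``."""
    pts: list[complex] = []
    closed = corners + [corners[0]]
    for a, b in zip(closed[:-1], closed[1:]):
        seg = [a + (b - a) * s for s in np.linspace(0, 1, 17)[:-1]]
        pts.extend(seg)
    pts.append(closed[0])
    vals = [det(p) for p in pts]
    if any(abs(f) == 0.0 for f in vals):
        raise RootSearchError("characteristic root on the search contour")
    # refine until each phase step is below pi/2
    i = 0
    while i < len(pts) - 1:
        dphi = np.angle(vals[i + 1] / vals[i])
        if abs(dphi) > np.pi / 2:
            if len(pts) > max_points:
                raise RootSearchError("contour refinement limit exceeded")
            mid = 0.5 * (pts[i] + pts[i + 1])
            fm = det(mid)
            if abs(fm) == 0.0:
                raise RootSearchError("characteristic root on the search contour")
            pts.insert(i + 1, mid)
            vals.insert(i + 1, fm)
        else:
            i += 1
    total = sum(np.angle(b / a) for a, b in zip(vals[:-1], vals[1:]))
    winding = total / (2 * np.pi)
    if abs(winding - round(winding)) > 0.25:
        raise RootSearchError(f"non-integer winding number {winding:.3f}")
    return int(round(winding))


def _newton(M, Mp, lam0: complex, tol: float = 1e-13, maxit: int = 80):
    lam = complex(lam0)
    for _ in range(maxit):
        Mv = M(lam)
        try:
            trace = np.trace(np.linalg.solve(Mv, Mp(lam)))
        except np.linalg.LinAlgError:
            lam += 1e-12 + 1e-12j
            continue
        if trace == 0:
            return None
        step = -1.0 / trace
        lam = lam + step
        if abs(step) < tol * max(1.0, abs(lam)):
            return lam
    return None


def _roots_in_rect(det, M, Mp, re_lo, re_hi, im_lo, im_hi, roots, depth=0):
    for shift in (0.0, 1.3e-4, -2.1e-4, 3.7e-4):
        try:
            corners = [
                complex(re_lo + shift, im_lo - shift),
                complex(re_hi + shift, im_lo - shift),
                complex(re_hi + shift, im_hi + shift),
                complex(re_lo + shift, im_hi + shift),
            ]
            count = _winding(det, corners)
            break
        except RootSearchError:
            if shift == 3.7e-4:
                raise
            continue
    known = [z for z in roots if re_lo <= z.real <= re_hi and im_lo <= z.imag <= im_hi]
    need = count - len(known)
    if need <= 0:
        return
    if need == 1 or (re_hi - re_lo) + (im_hi - im_lo) < 1e-8:
        z = _newton(M, Mp, complex((re_lo + re_hi) / 2, (im_lo + im_hi) / 2))
        if (
            z is not None
            and re_lo - 1e-6 <= z.real <= re_hi + 1e-6
            and im_lo - 1e-6 <= z.imag <= im_hi + 1e-6
            and all(abs(z - r) > 1e-7 for r in roots)
        ):
            roots.append(z)
            if need == 1:
                return
    if depth > 48:
        raise RootSearchError(
            f"could not isolate {need} root(s) in "
            f"[{re_lo:.3g},{re_hi:.3g}]x[{im_lo:.3g},{im_hi:.3g}]"
        )
    if re_hi - re_lo >= im_hi - im_lo:
        mid = 0.5 * (re_lo + re_hi)
        _roots_in_rect(det, M, Mp, re_lo, mid, im_lo, im_hi, roots, depth + 1)
        _roots_in_rect(det, M, Mp, mid, re_hi, im_lo, im_hi, roots, depth + 1)
    else:
        mid = 0.5 * (im_lo + im_hi)
        _roots_in_rect(det, M, Mp, re_lo, re_hi, im_lo, mid, roots, depth + 1)
        _roots_in_rect(det, M, Mp, re_lo, re_hi, mid, im_hi, roots, depth + 1)


@dataclass
class RootSet:
    """Characteristic roots sorted by descending real part.

    ``residuals`` are determinant residuals |det(H(lambda) - lambda E)|
    normalised by the matrix scale max(1, ||H - lambda E||_inf)^(n-1); for
    roots of order-1 magnitude this is the raw determinant value, while for
    far-imaginary roots it removes the |lambda|^n growth of the determinant
    that would otherwise swamp double-precision evaluation.
    """

    roots: np.ndarray  # sorted by descending real part
    residuals: np.ndarray  # scale-normalised |det(H(lambda) - lambda E)|
    floor: float
    bound: float
    truncated: bool  # imaginary-part enumeration window was capped

    @property
    def rightmost(self) -> complex:
        return complex(self.roots[0])


def characteristic_roots(
    model: DelayModel,
    v: float = None,
    *,
    floor: float | None = None,
    im_cap: float = 60.0,
    residual_tol: float = 1e-10,
) -> RootSet:
    """All characteristic roots with Re(lambda) above ``floor``.

    The search region is certified: ``floor`` defaults to the row-sum upper
    bound minus 10, and any root above the floor has |Im| below the row-sum
    bound evaluated at the floor.  If that bound exceeds ``im_cap`` the
    enumeration window is capped and the result flagged ``truncated`` (the
    rightmost root of the nonnegative models built here is real, so the
    rightmost entry is still reliable when a real root at the top exists).
    """
    if v is None:
        v = float(model.grid.nodes[0])
    M, Mp, det = _char_fns(model, v)
    if model.m == 0:
        vals = np.linalg.eigvals(model.r_values(v))
        order = np.lexsort((-vals.imag, -vals.real))
        vals = vals[order]
        res = np.array([_residual(M, det, z) for z in vals])
        b = float(vals[0].real)
        return RootSet(vals, res, b - 10.0, b, False)

    bound = _upper_bound(model, v)
    if floor is None:
        floor = bound - 10.0
    im_bound = _row_sum_bound(model, v, floor) + 1.0
    truncated = im_bound > im_cap
    im_hi = min(im_bound, im_cap)

    roots: list[complex] = []
    # real-axis bracketing first: the dominant root of nonnegative systems is real
    xs = np.linspace(floor, bound + 0.5, 401)
    fs = np.array([det(x).real for x in xs])
    for a, b in zip(range(len(xs) - 1), range(1, len(xs))):
        if fs[a] == 0.0:
            roots.append(complex(xs[a]))
        elif fs[a] * fs[b] < 0:
            x0 = brentq(lambda x: det(x).real, xs[a], xs[b], xtol=1e-13)
            z = _newton(M, Mp, complex(x0))
            roots.append(z if z is not None else complex(x0))
    # complex roots in the upper half rectangle (conjugates mirrored)
    upper: list[complex] = [z for z in roots]
    _roots_in_rect(det, M, Mp, floor, bound + 0.5, 1e-9, im_hi, upper)
    complex_roots = [z for z in upper if z.imag > 1e-9]
    all_roots = roots + complex_roots + [z.conjugate() for z in complex_roots]
    if not all_roots:
        raise RootSearchError(
            f"no characteristic roots found above the floor {floor:.4g}; "
            "lower the floor"
        )
    arr = np.array(sorted(all_roots, key=lambda z: (-z.real, -abs(z.imag), -z.imag)))
    res = np.array([_residual(M, det, z) for z in arr])
    bad = res > residual_tol
    if bad.any():
        raise RootSearchError(
            f"root residual contract violated: max |det| = {res.max():.3g}"
        )
    return RootSet(arr, res, floor, bound, truncated)


def rightmost_root(model: DelayModel, v: float = None, **kw) -> RootSet:
    """Root set above the default floor, rightmost root first."""
    return characteristic_roots(model, v, **kw)


def delay_fitness(model: DelayModel, **kw) -> pd.DataFrame:
    """Analytic fitness landscape J(v) = max_i Re(lambda_i(v)) / R(v).

    Consumes no initial data.  A root-finder failure at a node marks the
    node with NaN and the run continues.
    """
    rows = []
    for v in model.grid.nodes:
        R = model.R_value(v)
        try:
            rs = characteristic_roots(model, v, **kw)
            lam = rs.rightmost
            rows.append((v, lam.real, lam.imag, R, lam.real / R, rs.truncated))
        except RootSearchError:
            rows.append((v, np.nan, np.nan, R, np.nan, True))
    return pd.DataFrame(
        rows, columns=["v", "re_lambda", "im_lambda", "R", "J", "flagged"]
    )


def validate_root(model: DelayModel, v: float, lam: complex, n_samples: int = 5) -> float:
    """Relative residual of the seeded solution e * exp(lambda t) in the linear DDE.

    The mode vector ``e`` is the null vector of H(lambda) - lambda E (SVD);
    the residual substitutes the exponential solution, with its delayed
    values, directly into the linear delay equation coefficient by
    coefficient.
    """
    Mfn, _, _ = _char_fns(model, v)
    Mv = Mfn(lam)
    _, s, Vh = np.linalg.svd(Mv)
    e = Vh[-1].conj()
    q = model.q_values(v)
    r = model.r_values(v)
    worst = 0.0
    for t in np.linspace(0.0, 1.0, n_samples):
        zeta = e * np.exp(lam * t)
        lhs = lam * zeta
        rhs = r @ zeta
        for i, tau in enumerate(model.tau):
            rhs = rhs + q[:, :, i] @ (e * np.exp(lam * (t - tau)))
        worst = max(worst, float(np.linalg.norm(lhs - rhs) / np.linalg.norm(zeta)))
    return worst


# ---------------------------------------------------------------------------
# Method-of-steps simulation
# ---------------------------------------------------------------------------

@dataclass
class DelayTrajectory:
    model: DelayModel
    times: np.ndarray
    z: np.ndarray  # (n_nodes, n, n_times)
    Phi: np.ndarray  # running integral of the limitation
    f_trace: np.ndarray

    def total_density(self) -> np.ndarray:
        return self.z.sum(axis=1)

    def eta_field(self) -> DensityField:
        """Presence characteristic eta = (sum_j z_j)^(1/R) as a DensityField."""
        Z = np.clip(self.total_density(), 0.0, None)
        Rv = np.array([self.model.R_value(v) for v in self.model.grid.nodes])
        with np.errstate(divide="ignore"):
            log_eta = np.log(Z) / Rv[:, None]
        values = np.where(np.isneginf(log_eta), 0.0, np.exp(np.minimum(log_eta, 700.0)))
        return DensityField(self.model.grid, self.times, values, log_values=log_eta)


def simulate_dde(
    model: DelayModel,
    horizon: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_out: int = 201,
    method: str = "RK45",
    bound: float = 1e250,
) -> DelayTrajectory:
    """Integrate the delay system by the method of steps.

    The macro-step equals the smallest delay, so every delayed evaluation
    falls into already-stored dense output (or the supplied history for
    negative times).  State layout: all node stage vectors plus the running
    limitation integral Phi.
    """
    grid = model.grid
    nn, n = grid.n_nodes, model.n
    qs = np.stack([model.q_values(v) for v in grid.nodes])  # (nn, n, n, m)
    rs = np.stack([model.r_values(v) for v in grid.nodes])  # (nn, n, n)
    Rv = np.array([model.R_value(v) for v in grid.nodes])
    has_f = model.f is not None

    y0 = np.concatenate(
        [np.concatenate([np.asarray(model.history(v, 0.0), float) for v in grid.nodes]),
         [0.0]]
    )
    segments: list[tuple[float, float, object]] = []
    seg_starts: list[float] = []

    def eval_y(t: float) -> np.ndarray:
        if t <= 0.0:
            z = np.concatenate(
                [np.asarray(model.history(v, t), float) for v in grid.nodes]
            )
            return np.concatenate([z, [0.0]])
        idx = min(bisect_right(seg_starts, t) - 1, len(segments) - 1)
        t0, t1, interp = segments[idx]
        return interp(min(t, t1))

    def rhs(t, y):
        z = y[:-1].reshape(nn, n)
        Phi = y[-1]
        fval = model.f(z, grid, t) if has_f else 0.0
        dz = np.einsum("vlj,vj->vl", rs, z) - (Rv * fval)[:, None] * z
        for i, tau in enumerate(model.tau):
            yd = eval_y(t - tau)
            zd = yd[:-1].reshape(nn, n)
            surv = np.exp(-Rv * (Phi - yd[-1])) if has_f else 1.0
            term = np.einsum("vlj,vj->vl", qs[:, :, :, i], zd)
            dz += term * (surv[:, None] if has_f else 1.0)
        return np.concatenate([dz.ravel(), [fval]])

    step = float(model.tau.min()) if model.m else horizon
    t0 = 0.0
    y = y0
    while t0 < horizon - 1e-12:
        t1 = min(t0 + step, horizon)
        sol = solve_ivp(
            rhs, (t0, t1), y, method=method, rtol=rtol, atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(
                f"delay integration failed on [{t0:.4g}, {t1:.4g}]: {sol.message}"
            )
        segments.append((t0, t1, sol.sol))
        seg_starts.append(t0)
        y = sol.y[:, -1]
        if np.max(np.abs(y[:-1])) > bound:
            raise OverflowError(
                f"delay-system state exceeded the bound {bound:g} at t={t1:.4g}"
            )
        t0 = t1

    t_eval = np.linspace(0.0, horizon, n_out)
    ys = np.stack([eval_y(t) for t in t_eval], axis=1)
    z = ys[:-1, :].reshape(nn, n, -1)
    Phi = ys[-1, :]
    f_trace = np.array(
        [model.f(z[:, :, j], grid, t_eval[j]) if has_f else 0.0
         for j in range(t_eval.size)]
    )
    return DelayTrajectory(model, t_eval, z, Phi, f_trace)


def change_of_variables_check(
    model: DelayModel,
    horizon: float = 50.0,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    n_out: int = 201,
) -> float:
    """Verify the limitation-removing substitution numerically.

    Runs the nonlinear model and its linearisation from the same history and
    returns the max over time, nodes and components of the relative
    deviation between z(t) * exp(R Phi(t)) and zeta(t).  When the
    exponential factor overflows, the comparison is done in log space.
    """
    if model.f is None:
        raise ValueError("model has no limitation; the check is trivial")
    nl = simulate_dde(model, horizon, rtol=rtol, atol=atol, n_out=n_out)
    lin = simulate_dde(model.linearised(), horizon, rtol=rtol, atol=atol, n_out=n_out)
    Rv = np.array([model.R_value(v) for v in model.grid.nodes])
    expo = Rv[:, None] * nl.Phi[None, :]  # (nn, n_times)
    worst = 0.0
    for vi in range(model.grid.n_nodes):
        for l in range(model.n):
            zeta = lin.z[vi, l, :]
            scale = np.max(np.abs(zeta))
            if scale == 0.0:
                continue
            if np.max(expo[vi]) > 600.0:
                with np.errstate(divide="ignore", invalid="ignore"):
                    lhs = np.log(np.abs(nl.z[vi, l, :])) + expo[vi]
                    rhs = np.log(np.abs(zeta))
                dev = float(np.nanmax(np.abs(lhs - rhs)))
            else:
                recon = nl.z[vi, l, :] * np.exp(expo[vi])
                dev = float(np.max(np.abs(recon - zeta)) / scale)
            worst = max(worst, dev)
    return worst


# ---------------------------------------------------------------------------
# Age-structured (Foerster) reduction
# ---------------------------------------------------------------------------

def foerster_to_delay(
    ages,
    a,
    b,
    R: float | Callable = 1.0,
    grid: StrategyGrid | None = None,
    f: Callable | None = None,
    history: Callable | None = None,
) -> DelayModel:
    """Reduce a piecewise-constant age-structured model to a delay model.

    ``ages`` are the n-1 increasing age thresholds tau_1 < ... < tau_{n-1}
    (tau_1 is the minimum reproductive age), ``a`` the per-stage mortalities
    and ``b`` the per-stage reproduction coefficients (``b[0]`` must be 0:
    the youngest stage does not reproduce).  Stage totals S_i obey a delay
    system whose l-th equation carries a cohort produced tau_{l-1} ago
    entering the stage (survival exp(-sum_{k<l} a_k (tau_k - tau_{k-1})))
    and a cohort leaving it tau_l later; the last stage has no outflow term.
    The undelayed (tau_0 = 0) reproduction inflow of stage 1 appears in the
    first row of the linear matrix r alongside the diagonal mortalities
    -a_l; it does not alter the characteristic roots governing growth (the
    entry is off the feedback loop) but is required for nonnegative
    stage-1 dynamics.

    Coefficients may be arrays (strategy-independent) or callables of ``v``.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if np.any(np.diff(ages) <= 0) or np.any(ages <= 0):
        raise ValueError("age thresholds must be positive and strictly increasing")
    m = ages.size
    n = m + 1

    a_fn = _as_tensor_fn(a, (n,))
    b_fn = _as_tensor_fn(b, (n,))

    deltas = np.diff(np.concatenate([[0.0], ages]))  # (m,) spans of stages 1..n-1

    def q_of(v):
        av, bv = a_fn(v), b_fn(v)
        if bv[0] != 0.0:
            raise ValueError("b_1 must be zero (minimum reproductive age)")
        cum = np.concatenate([[0.0], np.cumsum(av[:m] * deltas)])  # cum[l] = sum_{k<=l}
        q = np.zeros((n, n, m))
        for l in range(2, n + 1):  # inflow of stage l: cohort delayed by tau_{l-1}
            q[l - 1, :, l - 2] += bv * np.exp(-cum[l - 1])
        for l in range(1, n):  # outflow of stage l (not the last): delayed by tau_l
            q[l - 1, :, l - 1] -= bv * np.exp(-cum[l])
        return q

    def r_of(v):
        av, bv = a_fn(v), b_fn(v)
        r = np.diag(-av)
        r[0, :] += bv  # zero-delay reproduction inflow into stage 1
        return r

    return DelayModel(
        n=n, tau=ages, q=q_of, r=r_of, R=R, grid=grid, f=f, history=history,
        meta={"kind": "foerster"},
    )
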