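"""Discretised strategy space, measures of subsets and density transforms.

The strategy space ``V`` is a compact set of inherited units (traits,
genotypes, behavioural strategies).  We discretise it as an ordered set of
nodes with positive quadrature weights, so that the measure of presence of a
subset ``A`` at time ``t`` is the quadrature of the measure density
``eta(v, t)`` restricted to the node mask of ``A``:

    mu(t)(A) = sum_{v_i in A} w_i * eta(v_i, t).

Subsets are represented as boolean node masks — the finite sigma-algebra of
the discretisation.  Borel subsets of a continuum space are approximated by
their grid traces, which makes set measures exactly additive over disjoint
masks and accurate to O(h) at interval boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StrategyGrid",
    "SubsetIndicator",
    "DensityField",
    "measure_of_set",
    "neighbourhood",
    "transform_density",
]


@dataclass(frozen=True)
class StrategyGrid:
    """Discretised compact strategy space.

    Parameters
    ----------
    nodes
        Strictly increasing strategy points (scalar strategies).
    weights
        Positive quadrature weights, one per node.  For a continuum grid the
        weights sum to the volume of ``V``; for a finite set of discrete
        strategies (``atoms``) each weight is the counting measure of the atom.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)
        if nodes.ndim != 1 or weights.shape != nodes.shape:
            raise ValueError("nodes and weights must be 1-d arrays of equal length")
        if nodes.size >= 2 and not np.all(np.diff(nodes) > 0):
            raise ValueError("nodes must be strictly increasing")
        if np.any(weights <= 0):
            raise ValueError("quadrature weights must be positive")

    @classmethod
    def uniform(cls, n_nodes: int, lo: float = 0.0, hi: float = 1.0) -> "StrategyGrid":
        """Uniform grid on ``[lo, hi]`` with trapezoidal quadrature weights."""
        if n_nodes < 3:
            raise ValueError("a continuum grid needs at least 3 nodes")
        nodes = np.linspace(lo, hi, n_nodes)
        h = (hi - lo) / (n_nodes - 1)
        weights = np.full(n_nodes, h)
        weights[0] = weights[-1] = h / 2.0
        return cls(nodes, weights)

    @classmethod
    def atoms(cls, nodes, weights=None) -> "StrategyGrid":
        """Finite strategy set with counting-measure weights (default 1 each)."""
        nodes = np.asarray(nodes, dtype=float)
        if weights is None:
            weights = np.ones_like(nodes)
        return cls(nodes, np.asarray(weights, dtype=float))

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    @property
    def volume(self) -> float:
        return float(self.weights.sum())

    @property
    def spacing(self) -> float:
        """Smallest distance between adjacent nodes."""
        if self.n_nodes < 2:
            return 0.0
        return float(np.min(np.diff(self.nodes)))

    def metric(self, v: float) -> np.ndarray:
        """Distances of all nodes from strategy point ``v``."""
        return np.abs(self.nodes - v)

    def index_of(self, v: float, tol: float = 1e-9) -> int:
        """Index of the grid node at ``v`` (error if ``v`` is off-grid)."""
        i = int(np.argmin(self.metric(v)))
        if self.metric(v)[i] > tol + 1e-12:
            raise ValueError(f"strategy point {v} is not a grid node")
        return i

    def quadrature(self, values: np.ndarray) -> float:
        return float(self.weights @ np.asarray(values, dtype=float))


@dataclass(frozen=True)
class SubsetIndicator:
    """Boolean node mask representing a measurable subset of the grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @classmethod
    def full(cls, grid: StrategyGrid) -> "SubsetIndicator":
        return cls(np.ones(grid.n_nodes, dtype=bool))

    @classmethod
    def empty(cls, grid: StrategyGrid) -> "SubsetIndicator":
        return cls(np.zeros(grid.n_nodes, dtype=bool))

    @classmethod
    def interval(cls, grid: StrategyGrid, lo: float, hi: float) -> "SubsetIndicator":
        """Grid trace of the closed interval ``[lo, hi]``."""
        return cls((grid.nodes >= lo - 1e-12) & (grid.nodes <= hi + 1e-12))

    def complement(self) -> "SubsetIndicator":
        return SubsetIndicator(~self.mask)

    def union(self, other: "SubsetIndicator") -> "SubsetIndicator":
        return SubsetIndicator(self.mask | other.mask)

    def intersection(self, other: "SubsetIndicator") -> "SubsetIndicator":
        return SubsetIndicator(self.mask & other.mask)

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class DensityField:
    """Time-indexed nonnegative measure density ``eta(v, t)`` on a grid.

    ``values[i, j]`` is the density at node ``i`` and time ``times[j]``.
    ``log_values`` optionally carries ``log eta`` (with ``-inf`` where the
    density is exactly zero); simulators populate it so that ratio and
    growth-rate diagnostics survive severe underflow of the linear values.
    ``bound`` is the declared uniform bound ``c`` on the total measure
    (resource limitation); by default it is the supremum observed over the
    stored times.
    """

    grid: StrategyGrid
    times: np.ndarray
    values: np.ndarray
    log_values: np.ndarray | None = None
    bound: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != (self.grid.n_nodes, self.times.size):
            raise ValueError("values must have shape (n_nodes, n_times)")
        if np.any(self.values < -1e-12):
            raise ValueError("density values must be nonnegative")
        self.values = np.clip(self.values, 0.0, None)
        if self.log_values is not None:
            self.log_values = np.asarray(self.log_values, dtype=float)
            if self.log_values.shape != self.values.shape:
                raise ValueError("log_values must match values in shape")
        totals = self.grid.weights @ self.values
        observed = float(totals.max()) if totals.size else 0.0
        if self.bound is None:
            self.bound = observed
        elif observed > self.bound * (1 + 1e-9) + 1e-12:
            raise ValueError(
                f"total measure {observed:g} exceeds the declared bound {self.bound:g}"
            )

    # -- time access -----------------------------------------------------
    def _check_time(self, t: float) -> None:
        if t < self.times[0] - 1e-12 or t > self.times[-1] + 1e-12:
            raise ValueError(
                f"time {t} outside the field's range [{self.times[0]}, {self.times[-1]}]"
            )

    def at_time(self, t: float) -> np.ndarray:
        """Densities at time ``t`` (linear interpolation, clipped at 0)."""
        self._check_time(t)
        out = np.array([np.interp(t, self.times, row) for row in self.values])
        return np.clip(out, 0.0, None)

    def log_at_time(self, t: float) -> np.ndarray:
        """Log-densities at ``t``; uses stored log values when available."""
        self._check_time(t)
        if self.log_values is not None:
            return np.array([np.interp(t, self.times, row) for row in self.log_values])
        with np.errstate(divide="ignore"):
            return np.log(self.at_time(t))

    def total_measure(self, t: float) -> float:
        return self.grid.quadrature(self.at_time(t))

    # -- serialisation ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        tt, vv = np.meshgrid(self.times, self.grid.nodes)
        return pd.DataFrame(
            {"t": tt.ravel(), "v": vv.ravel(), "eta": self.values.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, grid: StrategyGrid, frame: pd.DataFrame) -> "DensityField":
        pivot = frame.pivot(index="v", columns="t", values="eta").sort_index()
        return cls(grid, pivot.columns.to_numpy(float), pivot.to_numpy(float))


def measure_of_set(field: DensityField, A: SubsetIndicator, t: float) -> float:
    """Measure of subset ``A`` at time ``t``: quadrature of ``eta`` over the mask.

    Exactly additive over disjoint masks.  An empty mask has measure 0.
    """
    if A.is_empty:
        return 0.0
    eta = field.at_time(t)
    return float((field.grid.weights * A.mask) @ eta)


def neighbourhood(grid: StrategyGrid, v: float, radius: float) -> SubsetIndicator:
    """Mask of all grid nodes within ``radius`` of the node at ``v``.

    Always contains ``v`` itself.  A radius below the local grid spacing
    cannot resolve any neighbour; this degenerates to the singleton mask with
    a warning, because ranking diagnostics built on single nodes lose the
    uniform-convergence safeguard.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    i = grid.index_of(v)
    mask = grid.metric(grid.nodes[i]) <= radius + 1e-12
    if mask.sum() == 1 and grid.n_nodes > 1:
        warnings.warn(
            f"radius {radius} below the grid spacing near v={v}; "
            "neighbourhood degenerates to the single node",
            stacklevel=2,
        )
    mask[i] = True
    return SubsetIndicator(mask)


def transform_density(rho: DensityField, R) -> DensityField:
    """Generalised density ``eta(v,t) = rho(v,t)**(1/R(v))``.

    ``R`` may be a callable of ``v`` or an array over the grid; it must be
    strictly positive.  The transform is monotone and fixes zeros, so the
    selection/extinction structure of the field is preserved.
    """
    Rv = R(rho.grid.nodes) if callable(R) else np.asarray(R, dtype=float)
    Rv = np.broadcast_to(Rv, (rho.grid.n_nodes,)).astype(float)
    if np.any(Rv <= 0):
        raise ValueError("R(v) must be positive at every node")
    inv = (1.0 / Rv)[:, None]
    values = np.power(rho.values, inv)
    log_values = None
    if rho.log_values is not None:
        log_values = rho.log_values * inv
    return DensityField(rho.grid, rho.times.copy(), values, log_values=log_values)
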