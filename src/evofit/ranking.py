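"""Selection detection, pairwise ranking of strategies, empirical fitness.

The ranking order compares how much of each strategy's neighbourhood is
present at late times: strategy ``v`` outranks ``w`` when the ratio of
densities eta(w',t)/eta(v',t) tends to zero *uniformly* over neighbourhoods
O(w), O(v).  On a finite trajectory the limit is operationalised as a
final-window statistic: the directed supremum ratio must fall below a
tolerance and be non-increasing over the last dyadic windows, otherwise the
pair is reported incomparable (the limit may genuinely fail to exist, e.g.
under periodic evolutionary succession).

The empirical fitness J1(v) is the long-term time average of the per-capita
growth rate of eta(v, .), computed as a log-density increment over a window:

    J1(v) = (ln eta(v,T) - ln eta(v,T0)) / (T - T0).

Any functional preserving the ranking order is a valid fitness; J1 is the
canonical one, and at a selection equilibrium its maximum over surviving
strategies is zero (the maximal average per-capita growth rate vanishes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DensityField, SubsetIndicator, measure_of_set, neighbourhood

__all__ = [
    "RankingReport",
    "FitnessEstimate",
    "detect_selection",
    "rank_pair",
    "time_average_fitness",
    "fitness_landscape",
    "ranking_consistency_check",
]


@dataclass
class RankingReport:
    pair: tuple[float, float]
    verdict: str  # "v_better" | "w_better" | "incomparable"
    sup_ratio_trace: pd.DataFrame  # columns t, log_ratio_wv, log_ratio_vw
    radius: float
    tolerance: float
    converged: bool
    initial_state: np.ndarray | None = None

    def swapped(self) -> "RankingReport":
        flip = {"v_better": "w_better", "w_better": "v_better"}
        trace = self.sup_ratio_trace.rename(
            columns={"log_ratio_wv": "log_ratio_vw", "log_ratio_vw": "log_ratio_wv"}
        )
        return RankingReport(
            (self.pair[1], self.pair[0]),
            flip.get(self.verdict, self.verdict),
            trace,
            self.radius,
            self.tolerance,
            self.converged,
            self.initial_state,
        )


@dataclass
class FitnessEstimate:
    v: float
    J1: float
    window: tuple[float, float]
    converged: bool
    drift: float = np.nan


class ExtinctionError(RuntimeError):
    """The whole population's measure fell below tolerance (excluded case)."""


def detect_selection(
    field: DensityField, A: SubsetIndicator, tolerance: float = 1e-6
):
    """Decide whether the trajectory selects the subset ``A``.

    Selection of ``A`` means the measure of the complement of ``A`` vanishes
    at large time while the measure of ``A`` does not.  Returns
    ``(selected, trace)`` where ``trace`` records both measures over time.
    Raises :class:`ExtinctionError` if the whole population dies out —
    whole-population extinction is outside the selection framework.
    """
    if A.is_empty:
        raise ValueError("selection of the empty set is undefined")
    comp = A.complement()
    rows = []
    for t in field.times:
        rows.append(
            (t, measure_of_set(field, A, t), measure_of_set(field, comp, t))
        )
    trace = pd.DataFrame(rows, columns=["t", "measure_A", "measure_complement"])
    final = trace.iloc[-1]
    if final.measure_A + final.measure_complement < tolerance:
        raise ExtinctionError(
            f"total measure {final.measure_A + final.measure_complement:g} below "
            f"tolerance {tolerance:g} at t={final.t:g}"
        )
    selected = bool(
        final.measure_complement < tolerance and final.measure_A >= tolerance
    )
    return selected, trace


def _directed_log_sup(field: DensityField, num_mask, den_mask) -> np.ndarray:
    """Per-time log of sup_{x in num, y in den} eta(x,t)/eta(y,t)."""
    if field.log_values is not None:
        logs = field.log_values
    else:
        with np.errstate(divide="ignore"):
            logs = np.log(field.values)
    num = logs[num_mask, :].max(axis=0)
    den = logs[den_mask, :].min(axis=0)
    with np.errstate(invalid="ignore"):
        out = num - den
    # -inf/-inf (both extinct) -> undefined; report NaN
    out[np.isneginf(num) & np.isneginf(den)] = np.nan
    return out


def _vanishes(times: np.ndarray, log_ratio: np.ndarray, log_tol: float) -> tuple[bool, bool]:
    """(ratio fell below tol, trend over last dyadic windows is decreasing)."""
    finite = np.isfinite(log_ratio) | np.isneginf(log_ratio)
    if not finite[-1]:
        return False, False
    final_ok = log_ratio[-1] < log_tol
    # monotone-trend test over the last three dyadic windows
    T = times[-1]
    checkpoints = [T / 8, T / 4, T / 2, T]
    vals = [np.interp(c, times, np.nan_to_num(log_ratio, neginf=-1e30)) for c in checkpoints]
    decreasing = all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))
    return bool(final_ok), bool(decreasing)


def rank_pair(
    field: DensityField,
    v: float,
    w: float,
    radius: float | None = None,
    tolerance: float = 1e-4,
    initial_state: np.ndarray | None = None,
) -> RankingReport:
    """Pairwise ranking verdict for strategies ``v`` and ``w``.

    Verdict ``v_better`` requires the supremum over all node pairs in the two
    neighbourhoods of eta(w',t)/eta(v',t) to fall below ``tolerance`` with a
    decreasing trend over the final dyadic windows; symmetrically for
    ``w_better``; otherwise ``incomparable``.  Swapping the pair flips the
    verdict by construction.
    """
    grid = field.grid
    if radius is None:
        radius = 2.0 * grid.spacing if grid.n_nodes > 1 else 1.0
    Ov = neighbourhood(grid, v, radius)
    Ow = neighbourhood(grid, w, radius)
    eta0 = field.values[:, 0]
    for name, O in (("v", Ov), ("w", Ow)):
        if float((grid.weights * O.mask) @ eta0) <= 0:
            raise ValueError(
                f"neighbourhood of {name} has zero initial measure; the ranking "
                "order is only defined for strategies whose every neighbourhood "
                "is mu-nonzero"
            )
    log_wv = _directed_log_sup(field, Ow.mask, Ov.mask)  # sup eta(w')/eta(v')
    log_vw = _directed_log_sup(field, Ov.mask, Ow.mask)
    trace = pd.DataFrame(
        {"t": field.times, "log_ratio_wv": log_wv, "log_ratio_vw": log_vw}
    )
    log_tol = np.log(tolerance)
    wv_ok, wv_trend = _vanishes(field.times, log_wv, log_tol)
    vw_ok, vw_trend = _vanishes(field.times, log_vw, log_tol)
    if wv_ok and wv_trend and not (vw_ok and vw_trend):
        verdict, converged = "v_better", True
    elif vw_ok and vw_trend and not (wv_ok and wv_trend):
        verdict, converged = "w_better", True
    else:
        verdict, converged = "incomparable", not (wv_ok or vw_ok)
    return RankingReport(
        (v, w), verdict, trace, radius, tolerance, converged, initial_state
    )


def time_average_fitness(
    field: DensityField,
    v: float,
    window: tuple[float, float] | None = None,
    drift_tolerance: float = 1e-2,
) -> FitnessEstimate:
    """Empirical fitness J1(v): window-averaged per-capita growth of eta(v,.).

    The window defaults to the second half of the trajectory.  The
    convergence flag compares the averages over the two halves of the window;
    a drift beyond ``drift_tolerance`` marks the estimate as non-converged.
    """
    i = field.grid.index_of(v)
    if window is None:
        window = (field.times[-1] / 2.0, field.times[-1])
    T0, T = window
    if T <= T0:
        raise ValueError("window must have positive length")

    def log_eta(t: float) -> float:
        val = field.log_at_time(t)[i]
        if not np.isfinite(val):
            raise ValueError(
                f"density at v={v} is zero inside the window; J1 undefined"
            )
        return float(val)

    J1 = (log_eta(T) - log_eta(T0)) / (T - T0)
    mid = 0.5 * (T0 + T)
    J_a = (log_eta(mid) - log_eta(T0)) / (mid - T0)
    J_b = (log_eta(T) - log_eta(mid)) / (T - mid)
    drift = abs(J_b - J_a)
    return FitnessEstimate(v, J1, window, bool(drift <= drift_tolerance), drift)


@dataclass
class FitnessLandscape:
    frame: pd.DataFrame  # columns v, J1, converged, drift
    window: tuple[float, float]
    argmax: np.ndarray  # strategy points attaining the maximum (tie set)

    @property
    def max_J1(self) -> float:
        return float(self.frame.J1.max())


def fitness_landscape(
    field: DensityField,
    window: tuple[float, float] | None = None,
    drift_tolerance: float = 1e-2,
    tie_tolerance: float = 1e-6,
) -> FitnessLandscape:
    """Empirical fitness per node plus the argmax set (polymorphic maximum).

    Nodes whose density vanishes inside the window get J1 = -inf and a
    non-converged flag rather than being dropped silently.
    """
    if window is None:
        window = (field.times[-1] / 2.0, field.times[-1])
    rows = []
    for v in field.grid.nodes:
        try:
            est = time_average_fitness(field, v, window, drift_tolerance)
            rows.append((v, est.J1, est.converged, est.drift))
        except ValueError:
            rows.append((v, -np.inf, False, np.nan))
    frame = pd.DataFrame(rows, columns=["v", "J1", "converged", "drift"])
    best = frame.J1.max()
    argmax = frame.v[frame.J1 >= best - tie_tolerance].to_numpy()
    return FitnessLandscape(frame, window, argmax)


def ranking_consistency_check(reports) -> tuple[bool, list[str]]:
    """Check a set of ranking reports for partial-order consistency.

    Violations: a symmetric pair (both directions claimed better) or a broken
    transitivity chain (v>w, w>u, yet the (v,u) report claims otherwise).
    Incomparable verdicts never violate anything.
    """
    better: dict[tuple[float, float], bool] = {}
    for rep in reports:
        v, w = rep.pair
        if rep.verdict == "v_better":
            better[(v, w)] = True
        elif rep.verdict == "w_better":
            better[(w, v)] = True
    violations: list[str] = []
    for (v, w) in better:
        if (w, v) in better:
            violations.append(f"symmetric pair: {v} > {w} and {w} > {v}")
    for (v, w) in better:
        for (w2, u) in better:
            if w2 != w or u == v:
                continue
            if (u, v) in better:
                violations.append(
                    f"transitivity violated: {v} > {w} > {u} but {u} > {v}"
                )
    return (len(violations) == 0), sorted(set(violations))
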