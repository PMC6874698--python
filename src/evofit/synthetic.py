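"""Seeded generators of well-posed model instances.

Every other module's test surface runs on models produced here, so no
external data is ever needed.  Coefficient functions of ``v`` are low-order
polynomials with positive lower bounds, which guarantees the continuity in
``v`` the ranking and fitness theory requires.  Generation is driven by a
single integer seed and has no hidden entropy: the same recipe always
yields the same model and the same JSON serialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .delay import DelayModel, _upper_bound, characteristic_roots, total_density_limitation
from .grid import StrategyGrid
from .modelspec import ModelSpecDocument, build_model

__all__ = [
    "ModelRecipe",
    "random_stage_model",
    "random_delay_model",
    "two_strategy_delay_contest",
    "tradeoff_family",
    "TradeoffFamily",
    "make_fixture_document",
]


@dataclass
class ModelRecipe:
    """Declarative recipe for a random model instance."""

    kind: str = "stage"
    seed: int = 0
    n: int = 2
    m: int = 1
    n_nodes: int = 21
    irreducible: bool = True
    root_cap: float | None = None
    tau_range: tuple[float, float] = (0.1, 2.0)
    separation: float = 0.05


def _poly(rng, lo0, hi0, lo1=0.0, hi1=0.0) -> dict:
    coeffs = [float(rng.uniform(lo0, hi0))]
    if hi1 > lo1 or hi1 > 0:
        coeffs.append(float(rng.uniform(lo1, hi1)))
    return {"type": "poly", "coeffs": coeffs}


def random_stage_model(recipe: ModelRecipe):
    """Random stage model document + object.

    Reproduction b_i (i >= 2), mortality a_i and transition p_i are positive
    low-order polynomials of v; irreducibility (hence a simple real dominant
    eigenvalue at every node) is guaranteed by p_i > 0 on every transition
    and b_n > 0.  Returns ``(model, document)``.
    """
    if recipe.n < 2:
        raise ValueError("a stage model needs n >= 2")
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n
    b = [{"type": "constant", "value": 0.0}]
    for i in range(1, n):
        if recipe.irreducible and i == n - 1:
            b.append(_poly(rng, 0.8, 2.5, 0.0, 1.0))
        else:
            b.append(_poly(rng, 0.2, 2.0, 0.0, 1.0))
    a = [_poly(rng, 0.05, 0.5, 0.0, 0.3) for _ in range(n)]
    p = [_poly(rng, 0.3, 1.5, 0.0, 0.5) for _ in range(n - 1)]
    p.append({"type": "constant", "value": 0.0})
    doc = ModelSpecDocument.model_validate(
        {
            "grid": {"n_nodes": recipe.n_nodes},
            "model": {
                "kind": "stage", "n": n, "b": b, "a": a, "p": p,
                "R": _poly(rng, 0.5, 2.0, 0.0, 0.5),
            },
            "solver": {"seed": recipe.seed},
        }
    )
    return build_model(doc), doc


def random_delay_model(recipe: ModelRecipe, max_draws: int = 100):
    """Random scalar-or-small delay model with a certified root cap.

    Delayed coefficients are nonnegative, the undelayed matrix is negative
    diagonal-dominant and delays lie in ``recipe.tau_range``.  When
    ``recipe.root_cap`` is set, models are redrawn until the row-sum bound
    certifies every characteristic root below the cap; failure after
    ``max_draws`` draws raises.  Returns ``(model, document)``.
    """
    n, m = recipe.n, recipe.m
    if n < 1 or m < 1:
        raise ValueError("delay models need n >= 1 and m >= 1")
    for draw in range(max_draws):
        rng = np.random.default_rng((recipe.seed, draw))
        tau = sorted(rng.uniform(*recipe.tau_range, size=m).tolist())
        q = [[[{"type": "constant",
                "value": float(rng.uniform(0.2, 1.8) / m) if l == j or rng.random() < 0.3 else 0.0}
               for _ in range(m)] for j in range(n)] for l in range(n)]
        r = [[{"type": "constant",
               "value": float(-rng.uniform(0.1, 1.0)) if l == j else 0.0}
              for j in range(n)] for l in range(n)]
        doc = ModelSpecDocument.model_validate(
            {
                "grid": {"atoms": [0.0]},
                "model": {
                    "kind": "delay", "n": n, "tau": tau, "q": q, "r": r,
                    "R": {"type": "constant", "value": float(rng.uniform(0.5, 2.0))},
                },
                "solver": {"seed": recipe.seed},
            }
        )
        model = build_model(doc)
        if recipe.root_cap is not None:
            if _upper_bound(model, 0.0) > recipe.root_cap:
                continue
        return model, doc
    raise RuntimeError(
        f"could not draw a delay model under the root cap {recipe.root_cap} "
        f"in {max_draws} draws"
    )


def two_strategy_delay_contest(
    seed: int, margin: float = 0.05, max_draws: int = 200
) -> tuple[DelayModel, float, float, float]:
    """Scalar delay model on two competing strategies with separated fitness.

    Draws per-strategy coefficients (q, r, tau shared; R per strategy) until
    the analytic fitness J = Re(lambda_1)/R separates the strategies by at
    least ``margin`` and the winner grows (lambda_1 > 0), so the nonlinear
    contest with a total-density limitation has a well-defined survivor.
    Returns ``(model, J_winner, J_loser, winner_node)``.
    """
    for draw in range(max_draws):
        rng = np.random.default_rng((seed, draw, 7))
        tau = float(rng.uniform(0.3, 1.5))
        qv = rng.uniform(0.5, 2.0, size=2)
        rv = -rng.uniform(0.1, 0.8, size=2)
        Rv = rng.uniform(0.5, 2.0, size=2)
        grid = StrategyGrid.atoms([0.0, 1.0])

        def q_of(v, _q=qv):
            return np.array([[[_q[int(round(v))]]]])

        def r_of(v, _r=rv):
            return np.array([[_r[int(round(v))]]])

        def R_of(v, _R=Rv):
            return float(_R[int(round(v))])

        model = DelayModel(
            n=1, tau=[tau], q=q_of, r=r_of, R=R_of, grid=grid,
            f=total_density_limitation,
        )
        lam = [characteristic_roots(model, v).rightmost.real for v in (0.0, 1.0)]
        J = [lam[i] / Rv[i] for i in range(2)]
        win = int(np.argmax(J))
        if abs(J[0] - J[1]) >= margin and lam[win] > 0.05:
            return model, J[win], J[1 - win], float(grid.nodes[win])
    raise RuntimeError(f"no separated contest found for seed {seed}")


@dataclass
class TradeoffFamily:
    name: str
    k: callable
    r: callable
    argmax: np.ndarray = field(default=None)  # argmax of k/r on [0,1]; None = flat

    def ratio(self, v):
        return self.k(np.asarray(v, float)) / self.r(np.asarray(v, float))


_FAMILIES = {
    "example3-linear": lambda: TradeoffFamily(
        "example3-linear", lambda v: 1.0 + v, lambda v: np.ones_like(v),
        np.array([1.0]),
    ),
    "linear-quadratic": lambda: TradeoffFamily(
        "linear-quadratic", lambda v: 1.0 + v, lambda v: 1.0 + v**2 / 2.0,
        np.array([np.sqrt(3.0) - 1.0]),  # root of 1 - v - v^2/2
    ),
    "constant": lambda: TradeoffFamily(
        "constant", lambda v: np.ones_like(v), lambda v: np.ones_like(v), None
    ),
}


def tradeoff_family(name: str, grid: StrategyGrid | None = None) -> TradeoffFamily:
    """Named (k, r) trade-off family with a documented argmax of k/r."""
    if name not in _FAMILIES:
        raise KeyError(
            f"unknown trade-off family {name!r}; available: {sorted(_FAMILIES)}"
        )
    fam = _FAMILIES[name]()
    if grid is not None:
        kv, rv = fam.k(grid.nodes), fam.r(grid.nodes)
        if np.any(kv <= 0) or np.any(rv <= 0):
            raise ValueError("trade-off coefficients must be positive on the grid")
    return fam


def make_fixture_document(kind: str, seed: int, **kw) -> ModelSpecDocument:
    """Fixture document for the CLI: a serialisable random model spec."""
    recipe = ModelRecipe(kind=kind, seed=seed, **kw)
    if kind == "stage":
        return random_stage_model(recipe)[1]
    if kind == "delay":
        return random_delay_model(recipe)[1]
    if kind == "replicator":
        rng = np.random.default_rng(seed)
        mu0 = rng.dirichlet(np.ones(3)).tolist()
        return ModelSpecDocument.model_validate(
            {"model": {"kind": "replicator", "mu0": mu0}, "solver": {"seed": seed}}
        )
    raise ValueError(f"unknown fixture kind {kind!r}")
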