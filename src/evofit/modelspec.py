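"""Model-spec documents: JSON schema, validation, building, result writing.

A model spec is a JSON document declaring the strategy grid, the model kind
and its coefficient functions, and solver settings.  Coefficient functions
of ``v`` are declared as one of

* ``{"type": "constant", "value": c}``
* ``{"type": "poly", "coeffs": [c0, c1, ...]}``  (c0 + c1 v + c2 v^2 + ...)
* ``{"type": "table", "v": [...], "values": [...]}``  (piecewise linear)
* a bare number (shorthand for a constant)

Unknown keys are rejected; every run echoes its validated spec into the
output directory so results are reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__ as _version
from .grid import StrategyGrid

__all__ = [
    "ModelSpecDocument",
    "load_model_spec",
    "build_model",
    "write_results",
    "coefficient_to_callable",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConstantCoeff(_Strict):
    type: Literal["constant"] = "constant"
    value: float


class PolyCoeff(_Strict):
    type: Literal["poly"] = "poly"
    coeffs: list[float]


class TableCoeff(_Strict):
    type: Literal["table"] = "table"
    v: list[float]
    values: list[float]

    @field_validator("values")
    @classmethod
    def _lengths(cls, values, info):
        v = info.data.get("v")
        if v is not None and len(values) != len(v):
            raise ValueError("table 'v' and 'values' must have equal length")
        return values


Coefficient = Union[float, ConstantCoeff, PolyCoeff, TableCoeff]


def coefficient_to_callable(spec: Coefficient):
    """Vectorised callable of ``v`` for a coefficient declaration."""
    if isinstance(spec, (int, float)):
        c = float(spec)
        return lambda v, _c=c: np.full_like(np.asarray(v, dtype=float), _c)
    if isinstance(spec, ConstantCoeff):
        return coefficient_to_callable(spec.value)
    if isinstance(spec, PolyCoeff):
        coeffs = np.asarray(spec.coeffs, dtype=float)
        return lambda v, _c=coeffs: np.polynomial.polynomial.polyval(
            np.asarray(v, dtype=float), _c
        )
    if isinstance(spec, TableCoeff):
        xs = np.asarray(spec.v, dtype=float)
        ys = np.asarray(spec.values, dtype=float)
        return lambda v, _x=xs, _y=ys: np.interp(np.asarray(v, dtype=float), _x, _y)
    raise TypeError(f"unsupported coefficient declaration {spec!r}")


class GridSpec(_Strict):
    lo: float = 0.0
    hi: float = 1.0
    n_nodes: int = Field(101, ge=1)
    atoms: list[float] | None = None

    def build(self) -> StrategyGrid:
        if self.atoms is not None:
            return StrategyGrid.atoms(self.atoms)
        return StrategyGrid.uniform(self.n_nodes, self.lo, self.hi)


class SolverSpec(_Strict):
    horizon: float = Field(100.0, gt=0)
    rtol: float = Field(1e-8, gt=0)
    atol: float = Field(1e-10, gt=0)
    n_out: int = Field(201, ge=2)
    seed: int = 0


class ReplicatorSpec(_Strict):
    kind: Literal["replicator"] = "replicator"
    mu0: list[float] = Field(default=[1 / 3, 1 / 3, 1 / 3])

    @field_validator("mu0")
    @classmethod
    def _simplex(cls, mu0):
        if len(mu0) != 3 or any(x < 0 for x in mu0) or abs(sum(mu0) - 1) > 1e-6:
            raise ValueError("mu0 must be 3 nonnegative frequencies summing to 1")
        return mu0


class LogisticSpec(_Strict):
    kind: Literal["logistic"] = "logistic"
    k: Coefficient | Literal["time_dependent_reproduction"] = 1.0
    r: Coefficient | None = None
    coupling: Literal["k_rho", "rho", "eta_r"] = "rho"
    rho0: Coefficient = 1.0


class StageSpec(_Strict):
    kind: Literal["stage"] = "stage"
    n: int = Field(ge=2)
    b: list[Coefficient]
    a: list[Coefficient]
    p: list[Coefficient]
    R: Coefficient = 1.0

    @field_validator("b", "a", "p")
    @classmethod
    def _stage_lengths(cls, val, info):
        n = info.data.get("n")
        if n is not None and len(val) != n:
            raise ValueError(f"'{info.field_name}' must list {n} per-stage coefficients")
        return val


class DelaySpec(_Strict):
    kind: Literal["delay"] = "delay"
    n: int = Field(ge=1)
    tau: list[float]
    q: list[list[list[Coefficient]]]  # indexed [l][j][i]
    r: list[list[Coefficient]]
    R: Coefficient = 1.0
    limitation: Literal["none", "total_density"] = "none"

    @field_validator("tau")
    @classmethod
    def _tau_positive(cls, tau):
        if any(t <= 0 for t in tau):
            raise ValueError("tau: all delays must be positive")
        return tau


ModelSpec = Union[ReplicatorSpec, LogisticSpec, StageSpec, DelaySpec]


class ModelSpecDocument(_Strict):
    schema_version: int = 1
    grid: GridSpec = GridSpec()
    model: ModelSpec = Field(discriminator="kind")
    solver: SolverSpec = SolverSpec()

    def dump(self) -> dict:
        return json.loads(self.model_dump_json())


def load_model_spec(path) -> ModelSpecDocument:
    """Load and fully validate a model spec JSON file."""
    with open(path) as fh:
        raw = json.load(fh)
    return ModelSpecDocument.model_validate(raw)


def build_model(doc: ModelSpecDocument):
    """Instantiate the concrete model object declared by a validated document."""
    from . import delay as _delay
    from . import dynamics as _dyn
    from . import stage as _stage

    spec = doc.model
    if spec.kind == "replicator":
        return np.asarray(spec.mu0, dtype=float)
    grid = doc.grid.build()
    if spec.kind == "logistic":
        if spec.k == "time_dependent_reproduction":
            return _dyn.time_dependent_reproduction_model(grid)
        k_fn = coefficient_to_callable(spec.k)
        r_fn = coefficient_to_callable(spec.r) if spec.r is not None else None
        rho0 = coefficient_to_callable(spec.rho0)(grid.nodes)
        return _dyn.NonlocalLogisticModel(
            grid=grid,
            k=lambda v, t, _k=k_fn: _k(v),
            r=r_fn,
            coupling=spec.coupling,
            rho0=rho0,
        )
    if spec.kind == "stage":
        fns = {
            name: [coefficient_to_callable(c) for c in getattr(spec, name)]
            for name in ("b", "a", "p")
        }

        def vec(name):
            fs = fns[name]
            return lambda v, _fs=fs: np.array([float(f(v)) for f in _fs])

        return _stage.StageModel(
            n=spec.n, b=vec("b"), a=vec("a"), p=vec("p"),
            R=lambda v, _f=coefficient_to_callable(spec.R): float(_f(v)),
            grid=grid,
        )
    if spec.kind == "delay":
        n, m = spec.n, len(spec.tau)
        q_fns = [[[coefficient_to_callable(spec.q[l][j][i]) for i in range(m)]
                  for j in range(n)] for l in range(n)]
        r_fns = [[coefficient_to_callable(spec.r[l][j]) for j in range(n)]
                 for l in range(n)]

        def q_of(v):
            return np.array(
                [[[float(q_fns[l][j][i](v)) for i in range(m)]
                  for j in range(n)] for l in range(n)]
            )

        def r_of(v):
            return np.array(
                [[float(r_fns[l][j](v)) for j in range(n)] for l in range(n)]
            )

        f = _delay.total_density_limitation if spec.limitation == "total_density" else None
        return _delay.DelayModel(
            n=n, tau=np.asarray(spec.tau, dtype=float), q=q_of, r=r_of,
            R=lambda v, _f=coefficient_to_callable(spec.R): float(_f(v)),
            grid=grid, f=f,
        )
    raise ValueError(f"unknown model kind {spec.kind!r}")


def write_results(outputs: dict, out_dir, doc: ModelSpecDocument | None = None) -> dict:
    """Write run outputs and a manifest to ``out_dir``.

    ``outputs`` maps file stems to pandas DataFrames (written as CSV) or
    JSON-serialisable objects.  The manifest records the spec hash, tool
    version and the file list.  The path is checked writable up front so a
    run never computes into an unwritable sink.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    probe = out_dir / ".write_probe"
    try:
        probe.write_text("")
    finally:
        if probe.exists():
            probe.unlink()
    manifest: dict = {"tool": "evofit", "version": _version, "files": []}
    if doc is not None:
        spec_json = doc.model_dump_json(indent=2)
        (out_dir / "spec.json").write_text(spec_json)
        manifest["spec_hash"] = hashlib.sha256(spec_json.encode()).hexdigest()
        manifest["seed"] = doc.solver.seed
        manifest["files"].append("spec.json")
    for stem, obj in outputs.items():
        if hasattr(obj, "to_csv"):
            name = f"{stem}.csv"
            obj.to_csv(out_dir / name, index=False)
        else:
            name = f"{stem}.json"
            (out_dir / name).write_text(json.dumps(obj, indent=2, default=float))
        manifest["files"].append(name)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
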