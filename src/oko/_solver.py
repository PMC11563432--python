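"""Thin LP/MILP backend layer.

Optimization models in this package are assembled through :class:`LinearModel`,
a backend-agnostic builder holding variables (with bounds and integrality),
two-sided linear constraints and a linear objective.  The default backend is
HiGHS through :func:`scipy.optimize.milp`; a GLPK backend through optlang is
provided so that results can be cross-checked against an independent solver.

Sign convention: objectives are stated with an explicit ``sense`` ("min" or
"max"); constraint rows are ``lb <= a.x <= ub`` with ``-inf``/``inf`` for
one-sided rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = [
    "LinearModel",
    "Solution",
    "SolverError",
    "InfeasibleError",
    "UnboundedError",
    "solve",
    "available_backends",
]

#: requested feasibility/optimality tolerance, mirrored in invariant checks
FEASIBILITY_TOL = 1e-9
#: slack used when re-checking solver output arithmetically
CHECK_TOL = 1e-6


class SolverError(RuntimeError):
    """Base class for optimization failures."""


class InfeasibleError(SolverError):
    """The model admits no feasible point."""


class UnboundedError(SolverError):
    """The objective is unbounded over the feasible region."""


@dataclass
class Solution:
    status: str                  # "optimal" | "feasible" (incumbent, limit hit)
    objective: float
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class LinearModel:
    """Incremental builder for an LP/MILP in named variables."""

    name: str = "model"
    _names: list[str] = field(default_factory=list)
    _index: dict[str, int] = field(default_factory=dict)
    _lb: list[float] = field(default_factory=list)
    _ub: list[float] = field(default_factory=list)
    _integer: list[bool] = field(default_factory=list)
    _rows: list[dict[int, float]] = field(default_factory=list)
    _row_lb: list[float] = field(default_factory=list)
    _row_ub: list[float] = field(default_factory=list)
    _row_names: list[str] = field(default_factory=list)
    _obj: dict[int, float] = field(default_factory=dict)
    sense: str = "min"

    # -- variables ---------------------------------------------------------
    def add_var(self, name: str, lb: float = 0.0, ub: float = np.inf,
                integer: bool = False) -> str:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        if lb > ub:
            raise ValueError(f"variable {name!r}: lb {lb} > ub {ub}")
        self._index[name] = len(self._names)
        self._names.append(name)
        self._lb.append(float(lb))
        self._ub.append(float(ub))
        self._integer.append(bool(integer))
        return name

    def add_binary(self, name: str) -> str:
        return self.add_var(name, 0.0, 1.0, integer=True)

    def set_bounds(self, name: str, lb: float, ub: float) -> None:
        i = self._index[name]
        self._lb[i] = float(lb)
        self._ub[i] = float(ub)

    def has_var(self, name: str) -> bool:
        return name in self._index

    @property
    def n_vars(self) -> int:
        return len(self._names)

    # -- constraints -------------------------------------------------------
    def add_constraint(self, coeffs: dict[str, float], lb: float = -np.inf,
                       ub: float = np.inf, name: str = "") -> None:
        row = {}
        for var, c in coeffs.items():
            if c == 0.0:
                continue
            row[self._index[var]] = row.get(self._index[var], 0.0) + float(c)
        self._rows.append(row)
        self._row_lb.append(float(lb))
        self._row_ub.append(float(ub))
        self._row_names.append(name)

    def set_objective(self, coeffs: dict[str, float], sense: str = "min") -> None:
        if sense not in ("min", "max"):
            raise ValueError(f"sense must be 'min' or 'max', got {sense!r}")
        self._obj = {self._index[v]: float(c) for v, c in coeffs.items()}
        self.sense = sense

    # -- assembly ----------------------------------------------------------
    def to_arrays(self):
        n = self.n_vars
        c = np.zeros(n)
        for i, v in self._obj.items():
            c[i] = v
        if self.sense == "max":
            c = -c
        m = len(self._rows)
        if m:
            data, ri, ci = [], [], []
            for r, row in enumerate(self._rows):
                for i, v in row.items():
                    ri.append(r)
                    ci.append(i)
                    data.append(v)
            A = sparse.csr_matrix((data, (ri, ci)), shape=(m, n))
        else:
            A = sparse.csr_matrix((0, n))
        return (c, A, np.array(self._row_lb), np.array(self._row_ub),
                np.array(self._lb), np.array(self._ub),
                np.array(self._integer, dtype=int))


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------

def _solve_highs(model: LinearModel, time_limit: float | None,
                 mip_gap: float) -> Solution:
    c, A, rl, ru, lb, ub, integ = model.to_arrays()
    constraints = [LinearConstraint(A, rl, ru)] if A.shape[0] else []
    options: dict = {"presolve": True, "mip_rel_gap": mip_gap}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(c=c, integrality=integ, bounds=Bounds(lb, ub),
               constraints=constraints, options=options)
    if res.status == 2:
        raise InfeasibleError(f"{model.name}: infeasible")
    if res.status == 3:
        raise UnboundedError(f"{model.name}: unbounded objective")
    if res.x is None:
        raise SolverError(f"{model.name}: solver failed ({res.message})")
    obj = float(res.fun) if res.fun is not None else float(c @ res.x)
    if model.sense == "max":
        obj = -obj
    status = "optimal" if res.status == 0 else "feasible"
    return Solution(status=status, objective=obj,
                    values={n: float(res.x[i]) for i, n in enumerate(model._names)})


def _solve_glpk(model: LinearModel, time_limit: float | None,
                mip_gap: float) -> Solution:
    import optlang.glpk_interface as glpk

    m = glpk.Model(name=model.name)
    vs = []
    for i, name in enumerate(model._names):
        lb = None if model._lb[i] == -np.inf else model._lb[i]
        ub = None if model._ub[i] == np.inf else model._ub[i]
        vtype = "integer" if model._integer[i] else "continuous"
        vs.append(glpk.Variable(name, lb=lb, ub=ub, type=vtype))
    m.add(vs)
    cons = []
    for r, row in enumerate(model._rows):
        expr = sum(v * vs[i] for i, v in row.items())
        lb = None if model._row_lb[r] == -np.inf else model._row_lb[r]
        ub = None if model._row_ub[r] == np.inf else model._row_ub[r]
        cons.append(glpk.Constraint(expr, lb=lb, ub=ub))
    m.add(cons)
    obj_expr = sum(v * vs[i] for i, v in model._obj.items()) if model._obj else 0
    m.objective = glpk.Objective(obj_expr, direction=model.sense)
    status = m.optimize()
    if status == "infeasible":
        raise InfeasibleError(f"{model.name}: infeasible (glpk)")
    if status == "unbounded":
        raise UnboundedError(f"{model.name}: unbounded (glpk)")
    if status not in ("optimal", "feasible"):
        raise SolverError(f"{model.name}: glpk status {status}")
    return Solution(status=status, objective=float(m.objective.value),
                    values={v.name: float(v.primal) for v in vs})


_BACKENDS = {"highs": _solve_highs, "glpk": _solve_glpk}


def available_backends() -> list[str]:
    out = ["highs"]
    try:
        import optlang.glpk_interface  # noqa: F401
        out.append("glpk")
    except ImportError:
        pass
    return out


def solve(model: LinearModel, backend: str = "highs",
          time_limit: float | None = None, mip_gap: float = 0.0) -> Solution:
    """Solve a :class:`LinearModel`, raising on infeasibility/unboundedness."""
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown backend {backend!r}; "
                         f"available: {available_backends()}") from None
    return fn(model, time_limit, mip_gap)
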