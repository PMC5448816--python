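"""LP solving behind a single contract: load, set objective, solve, query.

The backend is scipy's HiGHS interface.  Everything above this module
talks in :class:`~steadycom.core.LinearProgram` objects and variable-id
dictionaries, so swapping in another solver means reimplementing
:func:`solve_lp` only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from .core import LinearProgram, VarId

__all__ = ["LPSolution", "LPError", "UnboundedLPError", "solve_lp", "BACKEND_ID"]

BACKEND_ID = "scipy-highs"


class LPError(RuntimeError):
    pass


class UnboundedLPError(LPError):
    """The LP is unbounded — typically a missing uptake bound on a
    growth-limiting resource."""


@dataclass
class LPSolution:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: Optional[float]
    values: dict[VarId, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def value(self, vid: VarId) -> float:
        return self.values[vid]


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


def solve_lp(
    lp: LinearProgram,
    objective: Optional[Mapping[VarId, float]] = None,
    direction: Optional[str] = None,
) -> LPSolution:
    """Solve *lp*, optionally overriding its objective.

    Returns an :class:`LPSolution`; infeasible and unbounded problems are
    reported in ``status`` rather than raised, so callers can branch on
    feasibility cheaply.
    """
    var_index = {vid: i for i, (vid, _, _) in enumerate(lp.variables)}
    n = len(lp.variables)
    bounds = [(None if not math.isfinite(lo) else lo, None if not math.isfinite(hi) else hi)
              for _, lo, hi in lp.variables]

    obj = dict(objective) if objective is not None else dict(lp.objective[0])
    sense = direction if direction is not None else lp.objective[1]
    c = np.zeros(n)
    for vid, w in obj.items():
        c[var_index[vid]] += w
    if sense == "max":
        c = -c
    elif sense != "min":
        raise ValueError(f"bad objective direction {sense!r}")

    eq_rows, eq_rhs, ub_rows, ub_rhs = [], [], [], []
    for coeffs, rsense, rhs in lp.rows:
        if rsense == "=":
            eq_rows.append(coeffs)
            eq_rhs.append(rhs)
        elif rsense == "<=":
            ub_rows.append(coeffs)
            ub_rhs.append(rhs)
        else:  # >=  ->  negate
            ub_rows.append({vid: -w for vid, w in coeffs.items()})
            ub_rhs.append(-rhs)

    def to_sparse(rows):
        data, indices, indptr = [], [], [0]
        for coeffs in rows:
            for vid, w in coeffs.items():
                indices.append(var_index[vid])
                data.append(w)
            indptr.append(len(indices))
        return csr_matrix((data, indices, indptr), shape=(len(rows), n))

    kwargs = {}
    if eq_rows:
        kwargs["A_eq"] = to_sparse(eq_rows)
        kwargs["b_eq"] = np.asarray(eq_rhs, dtype=float)
    if ub_rows:
        kwargs["A_ub"] = to_sparse(ub_rows)
        kwargs["b_ub"] = np.asarray(ub_rhs, dtype=float)

    res = linprog(c, bounds=bounds, method="highs", **kwargs)
    status = _STATUS.get(res.status, f"unknown({res.status})")
    if status == "iteration_limit":
        raise LPError("LP solver hit its iteration limit")
    if status != "optimal":
        return LPSolution(status=status, objective_value=None, values={})
    obj_val = float(res.fun)
    if sense == "max":
        obj_val = -obj_val
    values = {vid: float(res.x[i]) for vid, i in var_index.items()}
    return LPSolution(status="optimal", objective_value=obj_val, values=values)
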