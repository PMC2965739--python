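"""Minimal LP/MILP backend interface, implemented on scipy's HiGHS.

Every optimization in the package (FBA, FVA, SR-FBA, GeneForce) goes
through :class:`LinearProblem`: named variables, two-sided linear
constraints, a linear objective, and a solve that reports status plus a
value map. Problems are mutable — constraints and objective swaps can be
added between solves (used by FVA and integer-cut enumeration); each solve
rebuilds the sparse matrix, which is cheap at the problem sizes involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
FAILED = "failed"

_STATUS = {0: OPTIMAL, 1: FAILED, 2: INFEASIBLE, 3: UNBOUNDED, 4: FAILED}


class SolverError(RuntimeError):
    pass


@dataclass
class Solution:
    status: str
    objective: float | None
    values: dict[str, float]

    def __getitem__(self, var: str) -> float:
        return self.values[var]


@dataclass
class LinearProblem:
    maximize: bool = False
    _names: list[str] = field(default_factory=list)
    _index: dict[str, int] = field(default_factory=dict)
    _lb: list[float] = field(default_factory=list)
    _ub: list[float] = field(default_factory=list)
    _integer: list[bool] = field(default_factory=list)
    _rows: list[tuple[dict[int, float], float, float]] = field(default_factory=list)
    _objective: dict[int, float] = field(default_factory=dict)

    def add_var(
        self, name: str, lb: float = 0.0, ub: float = np.inf, integer: bool = False
    ) -> str:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        self._index[name] = len(self._names)
        self._names.append(name)
        self._lb.append(lb)
        self._ub.append(ub)
        self._integer.append(integer)
        return name

    def add_binary(self, name: str) -> str:
        return self.add_var(name, 0.0, 1.0, integer=True)

    def has_var(self, name: str) -> bool:
        return name in self._index

    def set_bounds(self, name: str, lb: float, ub: float) -> None:
        i = self._index[name]
        self._lb[i], self._ub[i] = lb, ub

    def get_bounds(self, name: str) -> tuple[float, float]:
        i = self._index[name]
        return self._lb[i], self._ub[i]

    def add_constraint(
        self, coeffs: Mapping[str, float], lb: float = -np.inf, ub: float = np.inf
    ) -> int:
        row = {}
        for name, c in coeffs.items():
            i = self._index[name]
            row[i] = row.get(i, 0.0) + float(c)
        self._rows.append((row, float(lb), float(ub)))
        return len(self._rows) - 1

    def set_objective(self, coeffs: Mapping[str, float], maximize: bool) -> None:
        self._objective = {self._index[k]: float(v) for k, v in coeffs.items()}
        self.maximize = maximize

    def solve(
        self,
        time_limit: float | None = None,
        mip_gap: float | None = None,
    ) -> Solution:
        n = len(self._names)
        c = np.zeros(n)
        for i, v in self._objective.items():
            c[i] = -v if self.maximize else v
        constraints = []
        if self._rows:
            data, ri, ci = [], [], []
            lo, hi = [], []
            for k, (row, lb, ub) in enumerate(self._rows):
                for i, v in row.items():
                    ri.append(k)
                    ci.append(i)
                    data.append(v)
                lo.append(lb)
                hi.append(ub)
            mat = sparse.csr_array((data, (ri, ci)), shape=(len(self._rows), n))
            constraints = [LinearConstraint(mat, np.array(lo), np.array(hi))]
        options: dict = {"presolve": True}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        if mip_gap is not None:
            options["mip_rel_gap"] = float(mip_gap)
        res = milp(
            c=c,
            constraints=constraints,
            integrality=np.array(self._integer, dtype=int),
            bounds=Bounds(np.array(self._lb), np.array(self._ub)),
            options=options,
        )
        status = _STATUS.get(res.status, FAILED)
        if status == OPTIMAL and res.x is not None:
            obj = float(res.fun) * (-1.0 if self.maximize else 1.0)
            values = dict(zip(self._names, map(float, res.x)))
            return Solution(OPTIMAL, obj, values)
        return Solution(status, None, {})

    @property
    def variable_names(self) -> Sequence[str]:
        return tuple(self._names)
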