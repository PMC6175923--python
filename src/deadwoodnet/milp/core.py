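"""Thin variable/constraint registry over scipy's HiGHS-backed MILP solver."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp


@dataclass
class SolveResult:
    x: np.ndarray | None
    objective: float | None  # in the *maximization* sense
    status: str  # optimal | time_limit | infeasible | unbounded | error
    gap: float | None


class MilpBuilder:
    """Accumulates variables, linear constraints and a linear objective.

    Objective sense is maximization; constraints are two-sided
    ``lb <= a.x <= ub`` rows.  ``solve`` hands the model to HiGHS through
    :func:`scipy.optimize.milp`.
    """

    def __init__(self) -> None:
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integrality: list[int] = []
        self._obj: dict[int, float] = {}
        self._rows_i: list[int] = []
        self._rows_j: list[int] = []
        self._rows_v: list[float] = []
        self._row_lb: list[float] = []
        self._row_ub: list[float] = []
        self._n_rows = 0
        self.names: dict[str, np.ndarray] = {}

    @property
    def n_vars(self) -> int:
        return len(self._lb)

    def add_vars(
        self,
        name: str,
        n: int,
        lb: float = 0.0,
        ub: float = np.inf,
        integer: bool = False,
    ) -> np.ndarray:
        idx = np.arange(self.n_vars, self.n_vars + n)
        self._lb.extend([lb] * n)
        self._ub.extend([ub] * n)
        self._integrality.extend([1 if integer else 0] * n)
        self.names[name] = idx
        return idx

    def fix(self, idx: int, value: float) -> None:
        self._lb[idx] = value
        self._ub[idx] = value

    def set_objective(self, idx, coefs) -> None:
        for i, c in zip(np.atleast_1d(idx), np.atleast_1d(coefs)):
            self._obj[int(i)] = self._obj.get(int(i), 0.0) + float(c)

    def add_constraint(self, idx, coefs, lb: float = -np.inf, ub: float = np.inf) -> int:
        idx = np.atleast_1d(idx)
        coefs = np.atleast_1d(coefs).astype(float)
        self._rows_i.extend([self._n_rows] * len(idx))
        self._rows_j.extend(int(i) for i in idx)
        self._rows_v.extend(float(c) for c in coefs)
        self._row_lb.append(lb)
        self._row_ub.append(ub)
        self._n_rows += 1
        return self._n_rows - 1

    def solve(self, mip_rel_gap: float = 0.0, time_limit: float | None = None) -> SolveResult:
        n = self.n_vars
        c = np.zeros(n)
        for i, v in self._obj.items():
            c[i] = -v  # milp minimizes
        a = sparse.csr_matrix(
            (self._rows_v, (self._rows_i, self._rows_j)), shape=(self._n_rows, n)
        )
        constraints = LinearConstraint(a, np.array(self._row_lb), np.array(self._row_ub))
        options: dict = {"mip_rel_gap": mip_rel_gap, "disp": False}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        res = milp(
            c=c,
            constraints=constraints,
            integrality=np.array(self._integrality),
            bounds=Bounds(np.array(self._lb), np.array(self._ub)),
            options=options,
        )
        status_map = {0: "optimal", 1: "time_limit", 2: "infeasible", 3: "unbounded"}
        status = status_map.get(res.status, "error")
        if res.x is None:
            return SolveResult(x=None, objective=None, status=status, gap=None)
        gap = getattr(res, "mip_gap", None)
        return SolveResult(x=np.asarray(res.x), objective=float(-res.fun), status=status, gap=gap)

    def value(self, result: SolveResult, name: str) -> np.ndarray:
        return result.x[self.names[name]]
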