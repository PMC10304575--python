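"""Narrow linear-programming contract used by FBA/FVA.

All optimization in the package goes through :func:`solve_lp`, so results are
solver-agnostic by construction; the default backend is scipy's HiGHS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

__all__ = ["LPResult", "solve_lp", "SOLVER_NAME"]

SOLVER_NAME = "scipy.optimize.linprog (HiGHS)"

#: Primal feasibility tolerance requested from the backend.
PRIMAL_TOL = 1e-9


@dataclass
class LPResult:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective: float | None
    x: np.ndarray | None


def solve_lp(
    c: np.ndarray,
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    sense: str = "max",
    extra_rows: list[tuple[np.ndarray, float, float]] | None = None,
) -> LPResult:
    """Optimize ``c . v`` subject to ``S v = 0``, ``lb <= v <= ub``.

    ``extra_rows`` is a list of ``(row, lo, hi)`` range constraints
    ``lo <= row . v <= hi`` (use ``-inf``/``inf`` for one-sided bounds).
    """
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    a_ub_rows: list[np.ndarray] = []
    b_ub: list[float] = []
    for row, lo, hi in extra_rows or []:
        row = np.asarray(row, dtype=float)
        if np.isfinite(hi):
            a_ub_rows.append(row)
            b_ub.append(hi)
        if np.isfinite(lo):
            a_ub_rows.append(-row)
            b_ub.append(-lo)
    res = linprog(
        sign * c,
        A_ub=np.array(a_ub_rows) if a_ub_rows else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=S if S.size else None,
        b_eq=np.zeros(S.shape[0]) if S.size else None,
        bounds=list(zip(lb, ub)),
        method="highs",
        options={"primal_feasibility_tolerance": PRIMAL_TOL,
                 "dual_feasibility_tolerance": PRIMAL_TOL},
    )
    if res.status == 2:
        return LPResult("infeasible", None, None)
    if res.status == 3:
        return LPResult("unbounded", None, None)
    if res.status != 0:  # pragma: no cover - numerical failure
        raise RuntimeError(f"LP solver failure: {res.message}")
    return LPResult("optimal", sign * res.fun, res.x)
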