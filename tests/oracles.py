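"""Brute-force oracles for cross-checking the LP-based code paths.

For small problems with finite bounds the optimum of
``max c.v  s.t.  A v = b, lb <= v <= ub`` is attained at a vertex of the
polytope, and every vertex fixes at least ``n - rank(A)`` variables at their
bounds.  Enumerating all such bound patterns and solving the remaining
square system yields every vertex, hence the exact optimum — independent of
any LP solver.
"""

from __future__ import annotations

import itertools

import numpy as np

from larvaflux.model import MetabolicModel, stoichiometric_matrix

FEAS_TOL = 1e-7


def enumerate_vertices(A, b, lb, ub):
    A = np.atleast_2d(np.asarray(A, dtype=float))
    b = np.asarray(b, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = A.shape[1]
    rank = np.linalg.matrix_rank(A) if A.size else 0
    vertices = []
    for free in itertools.combinations(range(n), rank):
        A_free = A[:, free] if rank else np.zeros((A.shape[0], 0))
        if rank and np.linalg.matrix_rank(A_free) < rank:
            continue
        fixed = [j for j in range(n) if j not in free]
        for choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            x = np.empty(n)
            x[fixed] = choice
            rhs = b - (A[:, fixed] @ x[fixed] if fixed else 0.0)
            if rank:
                sol = np.linalg.lstsq(A_free, rhs, rcond=None)[0]
                x[list(free)] = sol
            if A.size and np.max(np.abs(A @ x - b)) > FEAS_TOL:
                continue
            if np.any(x < lb - FEAS_TOL) or np.any(x > ub + FEAS_TOL):
                continue
            vertices.append(np.clip(x, lb, ub))
    return vertices


def oracle_optimum(c, A, b, lb, ub, sense="max"):
    """Exact optimum by vertex enumeration; None when infeasible."""
    vertices = enumerate_vertices(A, b, lb, ub)
    if not vertices:
        return None
    values = [float(np.dot(c, v)) for v in vertices]
    return max(values) if sense == "max" else min(values)


def _model_arrays(model: MetabolicModel):
    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.array([1.0 if r.id == model.objective else 0.0
                  for r in model.reactions])
    return c, S, lb, ub


def oracle_fba(model: MetabolicModel):
    """Exact FBA optimum of a small finite-bounded model (None = infeasible)."""
    c, S, lb, ub = _model_arrays(model)
    b = np.zeros(S.shape[0])
    sense = "max" if model.objective_direction == "maximize" else "min"
    return oracle_optimum(c, S, b, lb, ub, sense)


def oracle_fva(model: MetabolicModel, fraction: float, rxn_id: str):
    """Exact FVA (min, max) for one reaction via a slack-variable reduction.

    The objective-retention inequality ``c.v >= fraction * opt`` becomes the
    equality ``c.v - s = fraction * opt`` with a bounded slack ``s >= 0``.
    """
    c, S, lb, ub = _model_arrays(model)
    opt = oracle_fba(model)
    if opt is None:
        raise ValueError("infeasible base problem")
    slack_max = float(np.sum(np.abs(c) * np.maximum(np.abs(lb), np.abs(ub)))
                      + abs(fraction * opt) + 1.0)
    n = len(c)
    A = np.vstack([np.hstack([S, np.zeros((S.shape[0], 1))]),
                   np.hstack([c, [-1.0]])])
    b = np.append(np.zeros(S.shape[0]), fraction * opt)
    lb2 = np.append(lb, 0.0)
    ub2 = np.append(ub, slack_max)
    e = np.zeros(n + 1)
    e[[r.id for r in model.reactions].index(rxn_id)] = 1.0
    lo = oracle_optimum(e, A, b, lb2, ub2, "min")
    hi = oracle_optimum(e, A, b, lb2, ub2, "max")
    return lo, hi
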