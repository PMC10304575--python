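"""Model quality-control statistics.

Four network-health indicators commonly reported for metabolic
reconstructions: the share of dead-end metabolites (only produced or only
consumed given reaction directionalities), blocked reactions (zero flux in
every feasible steady state), elementally unbalanced reactions, and
boundary/exchange reactions.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .linear import solve_lp
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    formula_is_balanceable,
    parse_formula,
    stoichiometric_matrix,
)

__all__ = [
    "QCReport",
    "find_exchange_reactions",
    "detect_dead_ends",
    "find_blocked_reactions",
    "check_mass_balance",
    "qc_report",
]


@dataclass
class QCReport:
    model_id: str
    n_metabolites: int
    n_reactions: int
    n_genes: int
    pct_dead_end_metabolites: float
    pct_blocked_reactions: float
    pct_unbalanced_reactions: float
    pct_exchange_reactions: float
    dead_end_metabolites: list[str]
    blocked_reactions: list[str]
    unbalanced_reactions: list[str]
    exchange_reactions: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    def summary_row(self) -> dict:
        """One comparison-table row (counts and the four percentages)."""
        return {
            "model": self.model_id,
            "metabolites": self.n_metabolites,
            "reactions": self.n_reactions,
            "genes": self.n_genes,
            "pct_dead_end_metabolites": self.pct_dead_end_metabolites,
            "pct_blocked_reactions": self.pct_blocked_reactions,
            "pct_unbalanced_reactions": self.pct_unbalanced_reactions,
            "pct_exchange_reactions": self.pct_exchange_reactions,
        }


def write_comparison_csv(reports: list[QCReport], path: str | Path) -> None:
    """Multi-model comparison table, one row per model."""
    rows = [r.summary_row() for r in reports]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)


def find_exchange_reactions(model: MetabolicModel) -> list[str]:
    """Boundary reactions: stoichiometry touches exactly one metabolite."""
    return [r.id for r in model.reactions if r.is_boundary()]


def detect_dead_ends(model: MetabolicModel) -> list[str]:
    """Metabolites that can only be produced or only consumed.

    Direction capability respects the bounds: a reaction with ``ub > 0`` can
    run forward, one with ``lb < 0`` can run backward.
    """
    producible: set[str] = set()
    consumable: set[str] = set()
    for rxn in model.reactions:
        fwd = rxn.upper_bound > 0
        bwd = rxn.lower_bound < 0
        for met, coef in rxn.stoichiometry.items():
            if coef > 0:
                if fwd:
                    producible.add(met)
                if bwd:
                    consumable.add(met)
            elif coef < 0:
                if fwd:
                    consumable.add(met)
                if bwd:
                    producible.add(met)
    return [
        m.id for m in model.metabolites
        if m.id not in producible or m.id not in consumable
    ]


def _opened(model: MetabolicModel) -> MetabolicModel:
    opened = model.copy()
    for rxn in opened.reactions:
        if rxn.is_boundary():
            rxn.lower_bound = -DEFAULT_BOUND
            rxn.upper_bound = DEFAULT_BOUND
    return opened


def find_blocked_reactions(
    model: MetabolicModel,
    tolerance: float = 1e-9,
    open_exchanges: bool = True,
) -> list[str]:
    """Reactions whose flux range is [0, 0] over the whole flux cone.

    With ``open_exchanges`` (the default, matching common practice) all
    boundary reactions are first opened to ±1000 so that blockage reflects
    network topology rather than the applied diet.
    """
    work = _opened(model) if open_exchanges else model
    S = stoichiometric_matrix(work)
    lb = np.array([r.lower_bound for r in work.reactions])
    ub = np.array([r.upper_bound for r in work.reactions])
    blocked = []
    for j, rxn in enumerate(work.reactions):
        e = np.zeros(len(work.reactions))
        e[j] = 1.0
        hi = solve_lp(e, S, lb, ub, sense="max")
        if hi.status == "optimal" and hi.objective > tolerance:
            continue
        lo = solve_lp(e, S, lb, ub, sense="min")
        if lo.status == "optimal" and lo.objective < -tolerance:
            continue
        if hi.status == "infeasible":  # empty flux cone: everything blocked
            return [r.id for r in work.reactions]
        blocked.append(rxn.id)
    return blocked


def check_mass_balance(model: MetabolicModel) -> dict[str, dict]:
    """Per-reaction elemental imbalance.

    Each entry is ``{"status": ..., "imbalance": {element: net}}`` with
    status ``balanced``, ``unbalanced`` or ``unparseable`` (some metabolite
    lacks a formula or uses pseudo-elements; such reactions count as
    unbalanced in the aggregate statistic).
    """
    out: dict[str, dict] = {}
    for rxn in model.reactions:
        formulas = {
            met: model.metabolite(met).formula for met in rxn.stoichiometry
        }
        if not all(formula_is_balanceable(f) for f in formulas.values()):
            out[rxn.id] = {"status": "unparseable", "imbalance": {}}
            continue
        net: dict[str, float] = {}
        for met, coef in rxn.stoichiometry.items():
            for el, n in parse_formula(formulas[met]).items():
                net[el] = net.get(el, 0.0) + coef * n
        net = {el: v for el, v in net.items() if abs(v) > 1e-6}
        out[rxn.id] = {
            "status": "balanced" if not net else "unbalanced",
            "imbalance": net,
        }
    return out


def qc_report(
    model: MetabolicModel,
    blocked_tolerance: float = 1e-9,
    open_exchanges: bool = True,
) -> QCReport:
    """Aggregate the four statistics; percentages to two decimals."""
    model.validate()
    dead = detect_dead_ends(model)
    blocked = find_blocked_reactions(model, blocked_tolerance, open_exchanges)
    balance = check_mass_balance(model)
    unbalanced = [r for r, v in balance.items() if v["status"] != "balanced"]
    exchanges = find_exchange_reactions(model)
    n_m, n_r = len(model.metabolites), len(model.reactions)

    def pct(count: int, total: int) -> float:
        return round(100.0 * count / total, 2) if total else 0.0

    return QCReport(
        model_id=model.id,
        n_metabolites=n_m,
        n_reactions=n_r,
        n_genes=len(model.genes),
        pct_dead_end_metabolites=pct(len(dead), n_m),
        pct_blocked_reactions=pct(len(blocked), n_r),
        pct_unbalanced_reactions=pct(len(unbalanced), n_r),
        pct_exchange_reactions=pct(len(exchanges), n_r),
        dead_end_metabolites=sorted(dead),
        blocked_reactions=sorted(blocked),
        unbalanced_reactions=sorted(unbalanced),
        exchange_reactions=sorted(exchanges),
    )
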