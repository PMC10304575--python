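"""Flux balance analysis, flux variability analysis and diet perturbations.

FBA maximizes (or minimizes) the model's objective flux subject to the
steady-state constraint ``S v = 0`` and the reaction bounds.  FVA then asks,
for each reaction, how far its flux can move while the objective retains at
least a fraction (default 90%) of the FBA optimum — the spread quantifies the
network's resource-allocation flexibility under a given diet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diet import ExchangeBounds, apply_diet, scale_uptake
from .linear import solve_lp
from .model import MetabolicModel, stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "FVAResult",
    "fba",
    "fva",
    "growth_change_percent",
    "run_perturbation_experiment",
]

#: Steady-state residual tolerance for reported optimal solutions.
STEADY_STATE_TOL = 1e-6


@dataclass
class FluxSolution:
    status: str
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    fraction_of_optimum: float
    reference_optimum: float
    minimum: dict[str, float]
    maximum: dict[str, float]

    def range(self, rxn_id: str) -> tuple[float, float]:
        return self.minimum[rxn_id], self.maximum[rxn_id]


def _lp_arrays(model: MetabolicModel):
    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return S, lb, ub


def _objective_vector(model: MetabolicModel) -> np.ndarray:
    c = np.zeros(len(model.reactions))
    for j, r in enumerate(model.reactions):
        if r.id == model.objective:
            c[j] = 1.0
    return c


def fba(model: MetabolicModel) -> FluxSolution:
    """Solve the FBA linear program for ``model``.

    Infeasibility or unboundedness is reported through the solution status,
    never silently.
    """
    model.validate()
    S, lb, ub = _lp_arrays(model)
    c = _objective_vector(model)
    sense = "max" if model.objective_direction == "maximize" else "min"
    res = solve_lp(c, S, lb, ub, sense=sense)
    if res.status != "optimal":
        return FluxSolution(res.status, None)
    residual = np.abs(S @ res.x).max() if S.size else 0.0
    scale = max(1.0, np.abs(res.x).max())
    if residual > STEADY_STATE_TOL * scale:  # pragma: no cover - solver guard
        raise RuntimeError(f"steady-state residual {residual} above tolerance")
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxSolution("optimal", float(res.objective), fluxes)


def fva(
    model: MetabolicModel,
    fraction: float = 0.9,
    reactions: list[str] | None = None,
) -> FVAResult:
    """Flux variability analysis at ``fraction`` of the FBA optimum.

    For each requested reaction the flux is minimized and maximized subject
    to steady state, the bounds, and the objective retaining at least
    ``fraction`` of its optimal value.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    base = fba(model)
    if not base.optimal:
        raise RuntimeError(f"FVA base problem is {base.status}")
    S, lb, ub = _lp_arrays(model)
    c = _objective_vector(model)
    opt = base.objective_value
    if model.objective_direction == "maximize":
        extra = [(c, fraction * opt, np.inf)]
    else:
        extra = [(c, -np.inf, fraction * opt)]
    wanted = reactions if reactions is not None else [r.id for r in model.reactions]
    index = {r.id: j for j, r in enumerate(model.reactions)}
    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    for rxn_id in wanted:
        j = index[rxn_id]
        e = np.zeros(len(model.reactions))
        e[j] = 1.0
        for sense, store in (("min", lo), ("max", hi)):
            res = solve_lp(e, S, lb, ub, sense=sense, extra_rows=extra)
            if res.status != "optimal":  # pragma: no cover - guarded by base
                raise RuntimeError(f"FVA subproblem {rxn_id}/{sense}: {res.status}")
            store[rxn_id] = float(res.objective)
        # numerical jitter can invert the pair by ~solver tolerance
        if lo[rxn_id] > hi[rxn_id]:
            lo[rxn_id], hi[rxn_id] = hi[rxn_id], lo[rxn_id]
    return FVAResult(fraction, opt, lo, hi)


def growth_change_percent(reference: FluxSolution, perturbed: FluxSolution) -> float:
    """Percent change of the perturbed objective relative to the reference."""
    if not (reference.optimal and perturbed.optimal):
        raise ValueError("both solutions must be optimal")
    if reference.objective_value == 0:
        raise ValueError("reference objective is zero; percent change undefined")
    return 100.0 * (perturbed.objective_value - reference.objective_value) \
        / reference.objective_value


def run_perturbation_experiment(
    model: MetabolicModel,
    base_bounds: ExchangeBounds,
    scenario: str,
    *,
    eaa_exchanges: list[str] | None = None,
    glucose_exchange: str = "EX_glc_e",
    fa_drains: list[str] | None = None,
    fva_fraction: float = 0.9,
    factor: float = 2.0,
) -> dict:
    """Scale a dietary uptake set, re-run FBA and (optionally) drain FVA.

    ``scenario`` is ``"doubled_glucose"``, ``"doubled_EAA"`` or
    ``"doubled_<exchange id>"`` for a single substrate (e.g.
    ``"doubled_EX_val_e"``).  Returns the reference and perturbed solutions,
    the growth change in percent, and FVA ranges over ``fa_drains`` at
    ``fva_fraction`` of each state's optimum when drains are given.
    """
    if scenario == "doubled_glucose":
        targets = [glucose_exchange]
    elif scenario == "doubled_EAA":
        if eaa_exchanges is None:
            raise ValueError("doubled_EAA scenario needs eaa_exchanges")
        targets = list(eaa_exchanges)
    elif scenario.startswith("doubled_"):
        targets = [scenario[len("doubled_"):]]
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    unknown = [t for t in targets if t not in base_bounds.bounds]
    if unknown:
        raise KeyError(f"scenario targets not in diet bounds: {unknown}")

    reference_model = apply_diet(model, base_bounds)
    reference = fba(reference_model)
    perturbed_bounds = scale_uptake(base_bounds, targets, factor)
    perturbed_model = apply_diet(model, perturbed_bounds)
    perturbed = fba(perturbed_model)
    result = {
        "scenario": scenario,
        "targets": targets,
        "reference": reference,
        "perturbed": perturbed,
        "growth_change_percent": growth_change_percent(reference, perturbed),
    }
    if fa_drains:
        result["reference_fva"] = fva(reference_model, fva_fraction, fa_drains)
        result["perturbed_fva"] = fva(perturbed_model, fva_fraction, fa_drains)
    return result
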