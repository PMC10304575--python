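"""Dietary carbon-conversion efficiency per fatty-acid product.

The statistic relates carbon atoms entering through dietary uptake fluxes to
carbon atoms leaving through a fatty acid's maximal synthesis flux (the FVA
maximum while holding 90% of the optimal growth rate).  Two orientations are
reported for each fatty acid:

* ``printed``  = 100 * sum_i(Ci * uptake_i) / (Cf * drain),
  carbon-in over carbon-out — the formula as published;
* ``efficiency`` = 100 * (Cf * drain) / sum_i(Ci * uptake_i),
  carbon-out over carbon-in — the direction matching the "efficiency
  dropped" reading of the result.

The two are reciprocal: printed * efficiency = 10000 whenever both are
defined.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .diet import ExchangeBounds, apply_diet
from .fluxopt import fva
from .model import MetabolicModel, parse_formula

__all__ = [
    "CarbonEfficiencyInput",
    "CCEResult",
    "carbon_count",
    "compute_cce",
    "cce_experiment",
]


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in a Hill-notation formula."""
    return parse_formula(formula).get("C", 0)


@dataclass
class CarbonEfficiencyInput:
    """Uptake terms and one fatty-acid drain term for the statistic."""

    uptake_terms: list[tuple[str, float, int]]  # (exchange id, rate, Ci)
    drain_id: str
    drain_rate: float
    drain_carbons: int

    def __post_init__(self) -> None:
        for ex, rate, ci in self.uptake_terms:
            if rate < 0 or ci <= 0 or int(ci) != ci:
                raise ValueError(
                    f"uptake term {ex!r}: rate must be >= 0 and Ci a "
                    f"positive integer (got {rate}, {ci})"
                )
        if self.drain_rate < 0 or self.drain_carbons <= 0:
            raise ValueError("drain rate must be >= 0 and Cf positive")

    @property
    def n(self) -> int:
        return len(self.uptake_terms)

    @property
    def carbon_in(self) -> float:
        return sum(ci * rate for _, rate, ci in self.uptake_terms)

    @property
    def carbon_out(self) -> float:
        return self.drain_carbons * self.drain_rate


def compute_cce(inp: CarbonEfficiencyInput, orientation: str = "efficiency") -> float:
    """Evaluate the statistic in one orientation (percent)."""
    if orientation == "printed":
        if inp.carbon_out <= 0:
            raise ZeroDivisionError(
                f"drain {inp.drain_id!r} carries no carbon; printed "
                "orientation undefined"
            )
        return 100.0 * inp.carbon_in / inp.carbon_out
    if orientation == "efficiency":
        if inp.carbon_in <= 0:
            raise ZeroDivisionError(
                "diet carries no carbon; efficiency orientation undefined"
            )
        return 100.0 * inp.carbon_out / inp.carbon_in
    raise ValueError(f"orientation must be printed/efficiency, got {orientation!r}")


@dataclass
class CCEResult:
    diet_label: str
    per_fatty_acid: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fatty_acid_drain", "diet",
                             "cce_printed_pct", "cce_efficiency_pct"])
            for drain in sorted(self.per_fatty_acid):
                vals = self.per_fatty_acid[drain]
                writer.writerow([drain, self.diet_label,
                                 vals["printed"], vals["efficiency"]])


def cce_experiment(
    model: MetabolicModel,
    bounds: ExchangeBounds,
    fa_drains: list[str],
    fraction: float = 0.9,
    diet_label: str = "reference",
    carbon_overrides: dict[str, int] | None = None,
) -> CCEResult:
    """Carbon-conversion efficiency for each fatty-acid drain under a diet.

    The drain rate is the FVA maximum at ``fraction`` of the diet's FBA
    optimum; uptake rates are the applied diet limits, and carbon counts are
    resolved from metabolite formulas in the model (``carbon_overrides``
    supplies counts for formula-less exchanges).
    """
    constrained = apply_diet(model, bounds)
    overrides = carbon_overrides or {}

    def exchange_carbons(ex_id: str) -> int:
        if ex_id in overrides:
            return overrides[ex_id]
        met_id = next(iter(model.reaction(ex_id).stoichiometry))
        formula = model.metabolite(met_id).formula
        if not formula:
            raise ValueError(
                f"exchange {ex_id!r}: metabolite has no formula; provide a "
                "carbon override"
            )
        return carbon_count(formula)

    uptake_terms = [
        (ex, rate, exchange_carbons(ex))
        for ex, rate in sorted(bounds.bounds.items())
        if rate > 0 and exchange_carbons(ex) > 0
    ]
    variability = fva(constrained, fraction, fa_drains)
    result = CCEResult(diet_label=diet_label)
    for drain in fa_drains:
        met_id = next(iter(model.reaction(drain).stoichiometry))
        cf = carbon_count(model.metabolite(met_id).formula or "")
        inp = CarbonEfficiencyInput(
            uptake_terms=uptake_terms,
            drain_id=drain,
            drain_rate=max(variability.maximum[drain], 0.0),
            drain_carbons=cf,
        )
        entry: dict[str, float] = {}
        try:
            entry["printed"] = compute_cce(inp, "printed")
        except ZeroDivisionError:
            entry["printed"] = float("inf")
        entry["efficiency"] = compute_cce(inp, "efficiency")
        result.per_fatty_acid[drain] = entry
    return result
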