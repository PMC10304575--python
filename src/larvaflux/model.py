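"""Core domain types for stoichiometric metabolic models.

A :class:`MetabolicModel` is an ordered collection of metabolites and
reactions plus an objective, from which the stoichiometric matrix ``S``
(rows = metabolites, columns = reactions) is derived on demand.  Fluxes are
expressed in mmol per larva per day throughout the package; the flux of the
biomass pseudo-reaction is a specific growth rate in 1/day.

Sign conventions follow the constraint-based modeling literature: negative
stoichiometric coefficients denote substrates, positive denote products, and
for boundary (exchange) reactions a negative flux is uptake, so an uptake
limit ``u`` is encoded as ``lower_bound = -u``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DEFAULT_BOUND",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "FormulaError",
    "parse_formula",
    "formula_molar_mass",
    "stoichiometric_matrix",
]

#: Default flux bound (mmol/larva/day) applied when a file omits bounds,
#: following the COBRA community convention.
DEFAULT_BOUND = 1000.0

# Element symbols accepted for elemental balancing.  Tokens that match the
# Hill-notation grammar but are not in this set (e.g. "R", "X" residue
# markers) parse, but flag the formula as unusable for balance checks.
_REAL_ELEMENTS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U""".split()
)

# Standard atomic weights (g/mol) for the elements that occur in this
# package's metabolites; used to compute molar masses from formulas.
ATOMIC_WEIGHTS = {
    "H": 1.00794, "C": 12.011, "N": 14.0067, "O": 15.9994, "P": 30.97376,
    "S": 32.065, "Na": 22.98977, "K": 39.0983, "Cl": 35.453, "Mg": 24.305,
    "Ca": 40.078, "Fe": 55.845, "Zn": 65.38, "Se": 78.96,
}

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelValidationError(ValueError):
    """A model or one of its components violates a structural invariant."""


class FormulaError(ValueError):
    """A chemical formula string cannot be interpreted."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation formula into ``{element: count}``.

    Pseudo-element tokens (anything outside the periodic-table symbol set,
    e.g. ``R`` or ``X``) are accepted and returned, but callers performing
    elemental balancing should treat formulas containing them as
    unparseable-for-balance (see :func:`formula_is_balanceable`).

    >>> parse_formula("C6H12O6")
    {'C': 6, 'H': 12, 'O': 6}
    """
    if not formula or not isinstance(formula, str):
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    pos = 0
    counts: dict[str, int] = {}
    for match in _TOKEN_RE.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"unparseable formula {formula!r} at position {pos}"
            )
        pos = match.end()
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        raise FormulaError(f"unparseable formula {formula!r} at position {pos}")
    return counts


def formula_is_balanceable(formula: str | None) -> bool:
    """True when a formula exists and contains only real element symbols."""
    if not formula:
        return False
    try:
        counts = parse_formula(formula)
    except FormulaError:
        return False
    return all(el in _REAL_ELEMENTS for el in counts)


def formula_molar_mass(formula: str) -> float:
    """Molar mass in g/mol (equivalently mg/mmol) from a Hill formula."""
    counts = parse_formula(formula)
    try:
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise FormulaError(f"no atomic weight for element {exc} in {formula!r}")


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if self.formula is not None:
            parse_formula(self.formula)  # raises FormulaError when malformed


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(
                f"reaction {self.id!r}: stoichiometry must be non-empty"
            )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def is_boundary(self) -> bool:
        """Exchange/demand/sink reactions touch exactly one metabolite."""
        return len(self.stoichiometry) == 1


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    compartments: dict[str, str] = field(default_factory=dict)
    objective: str | None = None
    objective_direction: str = "maximize"
    genes: list[str] = field(default_factory=list)

    # -- lookups ----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index()[met_id]
        except KeyError:
            raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}")

    def _met_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any broken invariant."""
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for met in self.metabolites:
            if self.compartments and met.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.id!r}: compartment {met.compartment!r} "
                    "not declared in model"
                )
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolites: "
                    f"{sorted(missing)}"
                )
        if self.objective is None:
            raise ModelValidationError(f"model {self.id!r} has no objective")
        if self.objective not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective!r} not in model"
            )
        if self.objective_direction not in ("maximize", "minimize"):
            raise ModelValidationError(
                f"objective direction must be maximize/minimize, got "
                f"{self.objective_direction!r}"
            )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry))
                for r in self.reactions
            ],
            compartments=dict(self.compartments),
            objective=self.objective,
            objective_direction=self.objective_direction,
            genes=list(self.genes),
        )

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_boundary()]


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense stoichiometric matrix S (metabolites x reactions).

    Entry ``(i, j)`` is the signed coefficient of metabolite ``i`` in
    reaction ``j`` and zero where the metabolite does not participate.
    """
    met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            S[met_pos[met_id], j] = coef
    return S
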