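"""Conversion of a fed-diet description into exchange-reaction bounds.

The feeding experiment supplies ingredient masses over a fixed duration for a
known larva population; assuming linear consumption, each dietary compound is
converted to a per-larva-per-day molar uptake limit that constrains the
corresponding exchange reaction (uptake = negative flux, so a limit ``u``
becomes ``lower_bound = -u``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from . import data
from .model import MetabolicModel

__all__ = [
    "DietSpec",
    "ExchangeBounds",
    "consumed_mass",
    "aa_rates",
    "apply_diet",
    "scale_uptake",
    "reference_exchange_bounds",
    "DEFAULT_UPTAKE_WHITELIST",
]

#: Exchanges left open to uptake even when a diet does not list them:
#: water, gases and common inorganic ions.
DEFAULT_UPTAKE_WHITELIST = frozenset(
    {"EX_h2o_e", "EX_o2_e", "EX_co2_e", "EX_pi_e", "EX_so4_e", "EX_nh3_e",
     "EX_h_e"}
)


@dataclass
class DietSpec:
    """A fed diet: ingredient totals/residues plus the protein profile."""

    ingredients: dict[str, dict[str, float]]
    duration_days: int
    larva_count: float
    water_g: float = 0.0
    final_larva_wet_weight_g: float | None = None
    amino_acid_profile: dict[str, float] = field(default_factory=dict)
    molar_masses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if self.larva_count < 1:
            raise ValueError("larva_count must be >= 1")
        for name, masses in self.ingredients.items():
            consumed_mass(masses, name=name)  # validates residue <= total


@dataclass
class ExchangeBounds:
    """Uptake limits per exchange reaction, mmol/larva/day (all >= 0)."""

    bounds: dict[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.bounds.items() if v < 0}
        if bad:
            raise ValueError(f"negative uptake limits: {bad}")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["exchange_id", "uptake_mmol_per_larva_day"])
            for key in sorted(self.bounds):
                writer.writerow([key, repr(self.bounds[key])])

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExchangeBounds":
        bounds: dict[str, float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                bounds[row["exchange_id"]] = float(
                    row["uptake_mmol_per_larva_day"]
                )
        return cls(bounds)


def consumed_mass(ingredient: dict[str, float], name: str = "") -> float:
    """Grams consumed = total applied minus residue left in the substrate."""
    total, residue = ingredient["total_g"], ingredient["residue_g"]
    if residue > total:
        raise ValueError(
            f"ingredient {name or '?'}: residue {residue} g exceeds "
            f"total {total} g"
        )
    return total - residue


def aa_rates(
    profile: dict[str, float],
    consumed_aa_mass: dict[str, float],
    larva_count: float,
    duration_days: int,
    molar_masses: dict[str, float],
    exchange_prefix: str = "EX_",
    exchange_suffix: str = "_e",
) -> ExchangeBounds:
    """Per-amino-acid uptake limits from consumed masses.

    ``consumed_aa_mass`` holds grams of each amino acid consumed over the
    whole experiment; assuming linear consumption this becomes
    ``mg/larva/day = consumed_g * 1000 / (larva_count * duration_days)`` and
    then ``mmol/larva/day`` through the molar mass (mg/mmol).  ``profile``
    names the amino acids expected; each needs a molar mass.
    """
    if larva_count <= 0 or duration_days <= 0:
        raise ValueError("larva_count and duration_days must be positive")
    bounds: dict[str, float] = {}
    for aa in profile:
        if aa not in molar_masses:
            raise KeyError(f"no molar mass for amino acid {aa!r}")
        grams = consumed_aa_mass.get(aa, 0.0)
        mg_per_larva_day = grams * 1000.0 / (larva_count * duration_days)
        bounds[f"{exchange_prefix}{aa}{exchange_suffix}"] = (
            mg_per_larva_day / molar_masses[aa]
        )
    return ExchangeBounds(bounds)


def apply_diet(
    model: MetabolicModel,
    bounds: ExchangeBounds,
    whitelist: frozenset[str] | set[str] = DEFAULT_UPTAKE_WHITELIST,
) -> MetabolicModel:
    """Constrain a model's exchange uptakes to a diet (pure function).

    Listed exchanges get ``lower_bound = -limit``; unlisted exchanges are
    closed to uptake (``lower_bound = 0``) unless whitelisted.  Upper
    (secretion) bounds are untouched.  Returns a modified copy.
    """
    exchange_ids = {r.id for r in model.exchange_reactions()}
    unknown = sorted(set(bounds.bounds) - exchange_ids)
    if unknown:
        raise KeyError(f"diet bounds reference unknown exchanges: {unknown}")
    constrained = model.copy()
    for rxn in constrained.reactions:
        if not rxn.is_boundary():
            continue
        if rxn.id in bounds.bounds:
            rxn.lower_bound = -bounds.bounds[rxn.id]
        elif rxn.id not in whitelist:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return constrained


def scale_uptake(
    bounds: ExchangeBounds, targets, factor: float
) -> ExchangeBounds:
    """Multiply the listed uptake limits by ``factor`` (> 0); others kept."""
    if factor <= 0:
        raise ValueError(f"factor must be positive, got {factor}")
    targets = set(targets)
    unknown = sorted(targets - set(bounds.bounds))
    if unknown:
        raise KeyError(f"unknown scaling targets: {unknown}")
    return ExchangeBounds(
        {k: (v * factor if k in targets else v)
         for k, v in bounds.bounds.items()}
    )


def reference_exchange_bounds(
    larva_count: float | None = None,
    glucose_exchange: str = "EX_glc_e",
    cholesterol_exchange: str = "EX_chol_e",
    cholesterol_uptake: float = 0.004,
) -> ExchangeBounds:
    """The measured reference diet as exchange bounds.

    Amino-acid limits come from the measured per-larva rates; glucose is
    converted analogously from the 846 g consumed over nine days.  The larva
    count defaults to the value implied by the printed per-larva rates.  A
    small cholesterol allowance covers the membrane-sterol demand that
    insects cannot synthesize de novo.
    """
    count = larva_count if larva_count is not None else data.implied_larva_count()
    bounds = aa_rates(
        data.AMINO_ACID_PROFILE_MG_PER_100G_PROTEIN,
        data.AMINO_ACID_CONSUMED_G,
        count,
        data.DIET_DURATION_DAYS,
        data.AMINO_ACID_MOLAR_MASSES,
    ).bounds
    glucose_g = consumed_mass(data.DIET_INGREDIENTS["glucose"], "glucose")
    bounds[glucose_exchange] = (
        glucose_g * 1000.0 / (count * data.DIET_DURATION_DAYS)
        / data.GLUCOSE_MOLAR_MASS
    )
    bounds[cholesterol_exchange] = cholesterol_uptake
    return ExchangeBounds(bounds)
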