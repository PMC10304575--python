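"""Biomass objective construction from chemical-composition assays.

The larval biomass pseudo-reaction consumes precursor metabolites in the
proportions measured by composition assays: macromolecule classes in
g/100 g dry weight, an amino-acid profile in mg/100 g protein, and a
fatty-acid profile in g/100 g fat.  Water, ash and unresolved carbohydrates
are excluded and the remaining mass fractions renormalized to 1; membrane
cholesterol, not captured by the assays, is inserted at a donor-model ratio.
Mass fractions become molar coefficients through
``coef = fraction * larva_dry_weight / molar_mass`` so that the assembled
reaction consumes exactly one larva dry weight of precursors per unit flux.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .model import Reaction

__all__ = [
    "CompositionAssay",
    "BiomassSpec",
    "normalize_composition",
    "select_tag_composition",
    "approximate_cholesterol",
    "assemble_biomass_reaction",
    "build_biomass_spec",
    "saturation_summary",
    "round_percent",
]

#: Macromolecule classes excluded from the biomass by default.
DEFAULT_EXCLUDED_CLASSES = frozenset({"water", "ash", "carbohydrates_other"})

#: Acyl chains of the two modeled triacylglycerol species.
TAG_A_CHAINS = ("C12:0", "C14:0", "C16:0")
TAG_B_CHAINS = ("C16:1", "C18:1", "C18:2")

#: Declared TAG-A:TAG-B split of the total biomass fat.
DECLARED_TAG_SPLIT = (0.49, 0.51)


class CompositionError(ValueError):
    pass


@dataclass
class CompositionAssay:
    """Raw composition measurements (all values >= 0)."""

    macromolecules: dict[str, float]
    fatty_acid_profile: dict[str, float] = field(default_factory=dict)
    amino_acid_profile: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping in (self.macromolecules, self.fatty_acid_profile,
                        self.amino_acid_profile):
            bad = {k: v for k, v in mapping.items() if v < 0}
            if bad:
                raise CompositionError(f"negative composition values: {bad}")


@dataclass
class BiomassSpec:
    """Normalized species-level mass fractions and molar coefficients."""

    normalized_mass_fractions: dict[str, float]
    larva_dry_weight: float
    tag_split: tuple[float, float] = DECLARED_TAG_SPLIT
    cholesterol_fraction: float = 0.0
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.normalized_mass_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise CompositionError(
                f"normalized mass fractions sum to {total}, expected 1"
            )
        if any(v < 0 for v in self.coefficients.values()):
            raise CompositionError("biomass coefficients must be >= 0")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "normalized_mass_fractions": self.normalized_mass_fractions,
            "larva_dry_weight": self.larva_dry_weight,
            "tag_split": list(self.tag_split),
            "cholesterol_fraction": self.cholesterol_fraction,
            "coefficients": self.coefficients,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "BiomassSpec":
        payload = json.loads(Path(path).read_text())
        payload["tag_split"] = tuple(payload["tag_split"])
        return cls(**payload)


def round_percent(x: float) -> int:
    """Round-half-away-from-zero to integer percent."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def normalize_composition(
    composition: dict[str, float], excluded: set[str] | frozenset[str] = frozenset()
) -> dict[str, float]:
    """Drop the excluded classes and renormalize the rest to sum to 1."""
    kept = {k: v for k, v in composition.items() if k not in excluded}
    total = sum(kept.values())
    if total <= 0:
        raise CompositionError(
            "no positive mass left after exclusions; cannot normalize"
        )
    return {k: v / total for k, v in kept.items()}


def select_tag_composition(
    fa_profile: dict[str, float],
    declared_split: tuple[float, float] | None = DECLARED_TAG_SPLIT,
) -> tuple[tuple[float, float], dict[str, tuple[str, ...]]]:
    """TAG species definitions and their split of the total biomass fat.

    With ``declared_split=None`` the split is recomputed from the profile as
    the normalized chain-mass sums of the two species.
    """
    missing = [fa for fa in TAG_A_CHAINS + TAG_B_CHAINS if fa not in fa_profile]
    if missing:
        raise CompositionError(f"profile missing TAG constituent acids: {missing}")
    species = {"tag_a": TAG_A_CHAINS, "tag_b": TAG_B_CHAINS}
    if declared_split is not None:
        return tuple(declared_split), species
    mass_a = sum(fa_profile[fa] for fa in TAG_A_CHAINS)
    mass_b = sum(fa_profile[fa] for fa in TAG_B_CHAINS)
    total = mass_a + mass_b
    if total <= 0:
        raise CompositionError("TAG constituent acids have zero total mass")
    return (mass_a / total, mass_b / total), species


def approximate_cholesterol(
    fractions: dict[str, float], donor_ratio: float
) -> dict[str, float]:
    """Insert cholesterol at a donor-model mass ratio, rescaling the rest.

    The ratio comes from a published fruit-fly larval biomass formulation;
    with ratio ``r`` the existing fractions shrink by ``1 - r`` so the total
    stays 1.
    """
    if not 0 <= donor_ratio <= 0.2:
        raise CompositionError(
            f"cholesterol donor ratio {donor_ratio} outside [0, 0.2]"
        )
    if donor_ratio == 0:
        return dict(fractions)
    out = {k: v * (1.0 - donor_ratio) for k, v in fractions.items()}
    out["cholesterol"] = out.get("cholesterol", 0.0) + donor_ratio
    return out


def assemble_biomass_reaction(
    spec: BiomassSpec,
    molar_masses: dict[str, float],
    metabolite_ids: dict[str, str] | None = None,
    biomass_metabolite: str = "biomass_c",
    reaction_id: str = "BIOMASS",
) -> Reaction:
    """Turn mass fractions into a biomass reaction producing 1 unit biomass.

    ``molar_masses`` are g/mmol per species; ``metabolite_ids`` maps species
    names onto model metabolite ids (identity by default).  The coefficients
    are also stored back onto ``spec.coefficients``.
    """
    ids = metabolite_ids or {}
    stoich: dict[str, float] = {}
    coefficients: dict[str, float] = {}
    for species, fraction in spec.normalized_mass_fractions.items():
        if fraction == 0:
            continue
        if species not in molar_masses:
            raise CompositionError(f"no molar mass for biomass species {species!r}")
        coef = fraction * spec.larva_dry_weight / molar_masses[species]
        met_id = ids.get(species, species)
        stoich[met_id] = stoich.get(met_id, 0.0) - coef
        coefficients[met_id] = coefficients.get(met_id, 0.0) + coef
    if not stoich:
        raise CompositionError("biomass composition is empty")
    stoich[biomass_metabolite] = 1.0
    spec.coefficients = coefficients
    return Reaction(
        id=reaction_id,
        name="biomass objective (larva dry weight)",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="biomass",
    )


def build_biomass_spec(
    assay: CompositionAssay,
    larva_dry_weight: float,
    tag_split: tuple[float, float] | None = DECLARED_TAG_SPLIT,
    cholesterol_ratio: float = 0.02,
    excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CLASSES,
    tag_species: dict[str, tuple[str, ...]] | None = None,
) -> BiomassSpec:
    """Full species-level biomass spec from a raw composition assay.

    Normalizes the macromolecule classes, expands the amino-acid class over
    the amino-acid profile and the fat class over the two TAG species, and
    inserts the cholesterol approximation.
    """
    macro = normalize_composition(assay.macromolecules, excluded)
    fractions: dict[str, float] = {}
    for cls, frac in macro.items():
        if cls == "amino_acids":
            prof_total = sum(assay.amino_acid_profile.values())
            if prof_total <= 0:
                raise CompositionError("empty amino-acid profile")
            for aa, mg in assay.amino_acid_profile.items():
                if mg > 0:
                    fractions[aa] = frac * mg / prof_total
        elif cls == "fat":
            if tag_split is None or tag_species is None:
                split, species = select_tag_composition(
                    assay.fatty_acid_profile,
                    declared_split=tag_split,
                )
            else:
                split, species = tuple(tag_split), tag_species
            for (name, _chains), share in zip(sorted(species.items()), split):
                if share > 0:
                    fractions[name] = frac * share
        elif cls == "starch_glycogen":
            fractions["glycogen"] = frac
        else:
            fractions[cls] = frac
    fractions = approximate_cholesterol(fractions, cholesterol_ratio)
    used_split = tag_split if tag_split is not None else select_tag_composition(
        assay.fatty_acid_profile, declared_split=None
    )[0]
    return BiomassSpec(
        normalized_mass_fractions=fractions,
        larva_dry_weight=larva_dry_weight,
        tag_split=tuple(used_split),
        cholesterol_fraction=cholesterol_ratio,
    )


def saturation_summary(fa_profile: dict[str, float]) -> dict[str, float]:
    """Saturated/unsaturated/MUFA/PUFA bookkeeping on a fatty-acid profile.

    Values are sums of g/100 g fat over the conventional chain classes, so
    on a profile reported per 100 g fat they read directly as percent.
    """
    saturated = ("C12:0", "C14:0", "C16:0", "C18:0")
    unsaturated = ("C14:1", "C16:1", "C18:1", "C18:2")
    mono = ("C14:1", "C16:1", "C18:1")
    poly = ("C18:2",)
    def total(keys):
        return sum(fa_profile.get(k, 0.0) for k in keys)
    return {
        "saturated_pct": total(saturated),
        "unsaturated_pct": total(unsaturated),
        "monounsaturated_pct": total(mono),
        "polyunsaturated_pct": total(poly),
    }
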