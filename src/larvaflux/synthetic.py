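"""Generator for small larva-like metabolic networks with known optima.

The generated network mirrors the structure of the black-soldier-fly larval
model it emulates: three compartments (extracellular, cytosol,
mitochondrion), exchange and transport reactions for twenty amino acids,
glucose and cholesterol, a lumped glycolysis/pyruvate-dehydrogenase carbon
backbone feeding acetyl-CoA, one lumped mass-balanced synthesis reaction per
fatty acid (with a cytochrome-b5 reductase redox recharge gating the
desaturations), two triacylglycerol assembly reactions, and a biomass
pseudo-reaction consuming amino acids, TAGs, glycogen, sugars, glycerol and
cholesterol.

Because the biomass amino-acid demand is in fixed ratios and the network
contains no amino-acid interconversion, the FBA optimum has a closed form:
the bottleneck ``min_i(uptake_i / biomass_coefficient_i)`` over the dietary
precursors, provided glucose and cholesterol supply the remaining demand
with slack (which the generator verifies at construction).  Every internal
reaction except the biomass pseudo-reaction is elementally balanced; the
generator closes hydrogen and oxygen with explicit ``h``/``h2o`` species and
refuses to emit a reaction whose other elements do not cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import data
from .biomass import (
    BiomassSpec,
    CompositionAssay,
    assemble_biomass_reaction,
    build_biomass_spec,
)
from .diet import ExchangeBounds, reference_exchange_bounds
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_formula,
)

__all__ = [
    "SyntheticNetworkParams",
    "GenerationError",
    "generate_network",
    "reference_diet",
    "analytic_bottleneck",
    "random_toy_network",
]


class GenerationError(ValueError):
    pass


#: Default macromolecule assay, g/100 g dry weight.  Amino acids and fat are
#: the validated larval values; the carbohydrate remainder is split over
#: glycogen, free sugars and glycerol.  Water/ash are excluded downstream.
DEFAULT_MACROMOLECULES = {
    "amino_acids": 70.0,
    "fat": 16.0,
    "starch_glycogen": 6.0,
    "sugars": 4.0,
    "glycerol": 4.0,
}

#: Default larva dry weight (g): 30% solids of the 0.028 g final wet weight.
DEFAULT_LARVA_DRY_WEIGHT = 0.3 * data.FINAL_LARVA_WET_WEIGHT_G


@dataclass
class SyntheticNetworkParams:
    n_amino_acids: int = 20
    fatty_acid_set: tuple[str, ...] = data.MODELED_FATTY_ACIDS
    tag_split: tuple[float, float] = (0.49, 0.51)
    include_glucose: bool = True
    biomass: BiomassSpec | str = "auto"
    larva_dry_weight: float = DEFAULT_LARVA_DRY_WEIGHT
    cholesterol_ratio: float = 0.02
    macromolecules: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MACROMOLECULES)
    )
    n_decoys: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fatty_acid_set:
            raise GenerationError("fatty_acid_set must be non-empty")
        if abs(sum(self.tag_split) - 1.0) > 1e-9:
            raise GenerationError(f"tag_split {self.tag_split} must sum to 1")
        if not 1 <= self.n_amino_acids <= 20:
            raise GenerationError("n_amino_acids must be in 1..20")
        unknown = set(self.fatty_acid_set) - set(data.MODELED_FATTY_ACIDS)
        if unknown:
            raise GenerationError(f"unsupported fatty acids: {sorted(unknown)}")

    def amino_acids(self) -> list[str]:
        return list(data.AMINO_ACID_PROFILE_MG_PER_100G_PROTEIN)[: self.n_amino_acids]


# ---------------------------------------------------------------------------
# chemistry helpers
# ---------------------------------------------------------------------------

def _fa_token(label: str) -> str:
    return "fa" + label[1:].replace(":", "_")


def _fa_length_db(label: str) -> tuple[int, int]:
    length, db = label[1:].split(":")
    return int(length), int(db)


def _compose(counts: dict[str, int]) -> str:
    """Elemental counts -> Hill-notation string (C, H, then alphabetical)."""
    order = ["C", "H"] + sorted(e for e in counts if e not in ("C", "H"))
    return "".join(
        f"{el}{counts[el] if counts[el] != 1 else ''}"
        for el in order
        if counts.get(el, 0)
    )


def _tag_formula(chains: tuple[str, ...]) -> str:
    """Glycerol esterified with three acyl chains (3 waters released)."""
    counts = dict(parse_formula(data.GLYCEROL_FORMULA))
    for chain in chains:
        for el, n in parse_formula(data.FATTY_ACID_FORMULAS[chain]).items():
            counts[el] = counts.get(el, 0) + n
    counts["H"] -= 6
    counts["O"] -= 3
    return _compose(counts)


class _Builder:
    """Accumulates metabolites/reactions; auto-closes H/O on internal ones."""

    def __init__(self) -> None:
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: list[Reaction] = []

    def met(self, met_id: str, formula: str | None, name: str = "",
            compartment: str | None = None) -> str:
        comp = compartment or met_id.rsplit("_", 1)[-1]
        if met_id not in self.metabolites:
            self.metabolites[met_id] = Metabolite(
                id=met_id, name=name or met_id, compartment=comp,
                formula=formula,
            )
        return met_id

    def add(self, rxn_id: str, stoich: dict[str, float], *, name: str = "",
            lb: float = 0.0, ub: float = DEFAULT_BOUND, gpr: str = "",
            subsystem: str = "", balance_in: str | None = None) -> Reaction:
        if balance_in is not None:
            stoich = self._close_h_o(rxn_id, dict(stoich), balance_in)
        rxn = Reaction(id=rxn_id, stoichiometry=stoich, name=name or rxn_id,
                       lower_bound=lb, upper_bound=ub, gpr=gpr,
                       subsystem=subsystem)
        self.reactions.append(rxn)
        return rxn

    def _close_h_o(self, rxn_id: str, stoich: dict[str, float],
                   compartment: str) -> dict[str, float]:
        residual: dict[str, float] = {}
        for met_id, coef in stoich.items():
            formula = self.metabolites[met_id].formula
            for el, n in parse_formula(formula).items():
                residual[el] = residual.get(el, 0.0) + coef * n
        h2o = self.met(f"h2o_{compartment}", "H2O", "water")
        h = self.met(f"h_{compartment}", "H", "proton")
        d_h2o = -residual.get("O", 0.0)
        stoich[h2o] = stoich.get(h2o, 0.0) + d_h2o
        d_h = -(residual.get("H", 0.0) + 2.0 * d_h2o)
        stoich[h] = stoich.get(h, 0.0) + d_h
        for met in (h2o, h):
            if abs(stoich[met]) < 1e-12:
                del stoich[met]
        leftover = {
            el: r for el, r in residual.items()
            if el not in ("H", "O") and abs(r) > 1e-9
        }
        if leftover:
            raise GenerationError(
                f"reaction {rxn_id}: cannot balance elements {leftover}"
            )
        return stoich


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def _tag_species(params: SyntheticNetworkParams) -> dict[str, tuple[str, ...]]:
    """TAG species restricted to the requested fatty-acid set.

    Each species keeps three acyl positions, cycling over its available
    chains; a species with no available chain is dropped.
    """
    fa_set = set(params.fatty_acid_set)
    species: dict[str, tuple[str, ...]] = {}
    for name, chains in (("tag_a", data.TAG_A_CHAINS),
                         ("tag_b", data.TAG_B_CHAINS)):
        avail = [c for c in chains if c in fa_set]
        if avail:
            species[name] = tuple(avail[i % len(avail)] for i in range(3))
    if not species and params.macromolecules.get("fat", 0) > 0:
        raise GenerationError(
            "unsatisfiable precursor: biomass fat requires at least one "
            "TAG-constituent fatty acid in fatty_acid_set"
        )
    return species


def _effective_tag_split(params: SyntheticNetworkParams,
                         species: dict[str, tuple[str, ...]]) -> tuple[float, float]:
    split = {"tag_a": params.tag_split[0], "tag_b": params.tag_split[1]}
    present = {k: split[k] for k in species}
    total = sum(present.values())
    if total <= 0:
        raise GenerationError(
            "unsatisfiable precursor: tag_split allocates no mass to any "
            "available TAG species"
        )
    shares = [present.get(k, 0.0) / total for k in ("tag_a", "tag_b")]
    return (shares[0], shares[1])


def build_biomass(params: SyntheticNetworkParams) -> tuple[BiomassSpec, dict[str, tuple[str, ...]]]:
    """Biomass spec for the generated network (or the one supplied)."""
    species = _tag_species(params)
    if isinstance(params.biomass, BiomassSpec):
        return params.biomass, species
    amino_acids = params.amino_acids()
    assay = CompositionAssay(
        macromolecules=dict(params.macromolecules),
        fatty_acid_profile=dict(data.FATTY_ACID_PROFILE_G_PER_100G_FAT),
        amino_acid_profile={
            aa: data.AMINO_ACID_PROFILE_MG_PER_100G_PROTEIN[aa]
            for aa in amino_acids
        },
    )
    split = _effective_tag_split(params, species)
    spec = build_biomass_spec(
        assay,
        larva_dry_weight=params.larva_dry_weight,
        tag_split=split,
        cholesterol_ratio=params.cholesterol_ratio,
        tag_species=species,
    )
    return spec, species


def _species_molar_masses(species: dict[str, tuple[str, ...]]) -> dict[str, float]:
    """Molar masses of the biomass species, g/mmol."""
    from .model import formula_molar_mass

    masses = {
        "glycogen": formula_molar_mass(data.GLYCOGEN_UNIT_FORMULA),
        "sugars": data.GLUCOSE_MOLAR_MASS,
        "glycerol": formula_molar_mass(data.GLYCEROL_FORMULA),
        "cholesterol": data.CHOLESTEROL_MOLAR_MASS,
    }
    masses.update(data.AMINO_ACID_MOLAR_MASSES)
    for name, chains in species.items():
        masses[name] = formula_molar_mass(_tag_formula(chains))
    return {k: v / 1000.0 for k, v in masses.items()}


def generate_network(params: SyntheticNetworkParams | None = None) -> MetabolicModel:
    """Generate the larva-like network with the reference diet applied.

    Deterministic for a given seed; the seed only permutes reaction order
    and populates optional decoy reactions, never the core topology.
    """
    params = params or SyntheticNetworkParams()
    spec, species = build_biomass(params)
    amino_acids = params.amino_acids()
    diet = reference_diet(params)
    b = _Builder()

    # -- extracellular nutrients, transports -----------------------------
    def nutrient(token: str, formula: str, name: str) -> None:
        e = b.met(f"{token}_e", formula, name)
        c = b.met(f"{token}_c", formula, name)
        uptake = diet.bounds.get(f"EX_{token}_e", 0.0)
        b.add(f"EX_{token}_e", {e: -1.0}, lb=-uptake, ub=DEFAULT_BOUND,
              name=f"{name} exchange", subsystem="exchange")
        b.add(f"T_{token}", {e: -1.0, c: 1.0}, name=f"{name} transport",
              subsystem="transport")

    for aa in amino_acids:
        nutrient(aa, data.AMINO_ACID_FORMULAS[aa], aa)
    if params.include_glucose:
        nutrient("glc", data.GLUCOSE_FORMULA, "glucose")
    nutrient("chol", data.CHOLESTEROL_FORMULA, "cholesterol")

    # -- freely exchanged small species -----------------------------------
    for token, formula, name in (("o2", "O2", "oxygen"),
                                 ("co2", "CO2", "carbon dioxide"),
                                 ("h2o", "H2O", "water"),
                                 ("h", "H", "proton")):
        e = b.met(f"{token}_e", formula, name)
        c = b.met(f"{token}_c", formula, name)
        b.add(f"EX_{token}_e", {e: -1.0}, lb=-DEFAULT_BOUND, ub=DEFAULT_BOUND,
              name=f"{name} exchange", subsystem="exchange")
        b.add(f"T_{token}", {e: -1.0, c: 1.0}, lb=-DEFAULT_BOUND,
              name=f"{name} transport", subsystem="transport")

    # -- cytosolic cofactors ----------------------------------------------
    cof = {k: b.met(f"{k}_c", f, k) for k, f in data.COFACTOR_FORMULAS.items()}

    # -- mitochondrial respiration ----------------------------------------
    m = {k: b.met(f"{k}_m", data.COFACTOR_FORMULAS[k], k)
         for k in ("nad", "nadh", "atp", "adp", "pi", "o2")}
    b.add("O2tm", {cof["o2"]: -1, m["o2"]: 1}, name="oxygen transport, mito",
          subsystem="transport")
    b.add("NADHSHUTTLE", {cof["nadh"]: -1, m["nad"]: -1,
                          cof["nad"]: 1, m["nadh"]: 1},
          name="malate-aspartate shuttle (lumped)", subsystem="energy")
    b.add("ATPtm", {m["atp"]: -1, cof["adp"]: -1, cof["atp"]: 1, m["adp"]: 1},
          name="ADP/ATP translocase", subsystem="transport")
    b.add("PItm", {cof["pi"]: -1, m["pi"]: 1}, name="phosphate carrier",
          subsystem="transport")
    for token, formula, name in (("h2o", "H2O", "water"), ("h", "H", "proton")):
        b.add(f"{token.upper()}tm",
              {b.met(f"{token}_c", formula, name): -1.0,
               b.met(f"{token}_m", formula, name): 1.0},
              lb=-DEFAULT_BOUND, name=f"{name} transport, mito",
              subsystem="transport")
    b.add("RESP", {m["nadh"]: -1, m["o2"]: -0.5, m["adp"]: -2, m["pi"]: -2,
                   m["nad"]: 1, m["atp"]: 2},
          name="oxidative phosphorylation (lumped, P/O 2)",
          subsystem="energy", balance_in="m")
    b.add("ATPM", {cof["atp"]: -1, cof["adp"]: 1, cof["pi"]: 1},
          name="ATP hydrolysis valve (non-enforced maintenance)",
          subsystem="energy", balance_in="c")

    # -- central carbon ----------------------------------------------------
    if params.include_glucose:
        b.add("GLYCPDH",
              {b.met("glc_c", data.GLUCOSE_FORMULA, "glucose"): -1,
               cof["adp"]: -2, cof["pi"]: -2, cof["nad"]: -4, cof["coa"]: -2,
               cof["accoa"]: 2, cof["co2"]: 2, cof["atp"]: 2, cof["nadh"]: 4},
              name="glycolysis + pyruvate dehydrogenase (lumped)",
              gpr="g_glyc1 and g_pdh1", subsystem="central carbon",
              balance_in="c")
        b.add("ACCOAOX",
              {cof["accoa"]: -1, cof["nad"]: -4, cof["adp"]: -1, cof["pi"]: -1,
               cof["co2"]: 2, cof["coa"]: 1, cof["nadh"]: 4, cof["atp"]: 1},
              name="citric acid cycle (lumped)", subsystem="central carbon",
              balance_in="c")
        b.add("THD", {cof["nadh"]: -1, cof["nadp"]: -1,
                      cof["nad"]: 1, cof["nadph"]: 1},
              name="transhydrogenase (lumped NADPH supply)",
              subsystem="energy")
        b.add("GLYCOGENS",
              {b.met("glc_c", None, ""): -1, cof["atp"]: -1,
               b.met("glycogen_c", data.GLYCOGEN_UNIT_FORMULA, "glycogen unit"): 1,
               cof["adp"]: 1, cof["pi"]: 1},
              name="glycogen synthesis (lumped)", subsystem="storage",
              balance_in="c")
        b.add("GLYCEROLS",
              {b.met("glc_c", None, ""): -0.5, cof["nadh"]: -1,
               b.met("glycerol_c", data.GLYCEROL_FORMULA, "glycerol"): 1,
               cof["nad"]: 1},
              name="glycerol synthesis (lumped)", subsystem="storage",
              balance_in="c")

    # -- fatty-acid synthesis ---------------------------------------------
    unsaturated_present = any(_fa_length_db(fa)[1] > 0
                              for fa in params.fatty_acid_set)
    if unsaturated_present:
        b.add("CYTB5R", {cof["nadh"]: -1, cof["ficytb5"]: -2,
                         cof["nad"]: 1, cof["focytb5"]: 2},
              name="cytochrome-b5 reductase", gpr="g_cyb5r",
              subsystem="lipid", balance_in="c")
    for fa in params.fatty_acid_set:
        length, db = _fa_length_db(fa)
        n_ac = length // 2
        fa_met = b.met(f"{_fa_token(fa)}_c", data.FATTY_ACID_FORMULAS[fa],
                       f"fatty acid {fa}")
        stoich = {
            cof["accoa"]: -float(n_ac),
            cof["nadph"]: -float(length - 2),
            cof["atp"]: -float(n_ac - 1),
            fa_met: 1.0,
            cof["coa"]: float(n_ac),
            cof["nadp"]: float(length - 2),
            cof["adp"]: float(n_ac - 1),
            cof["pi"]: float(n_ac - 1),
        }
        if db:
            stoich[cof["focytb5"]] = -2.0 * db
            stoich[cof["o2"]] = stoich.get(cof["o2"], 0.0) - 1.0 * db
            stoich[cof["ficytb5"]] = 2.0 * db
        b.add(f"FAS_{_fa_token(fa)}", stoich,
              name=f"{fa} synthesis (lumped acyl-CoA route + hydrolase)",
              gpr=f"g_fas and g_te{'' if not db else ' and g_scd'}",
              subsystem="lipid", balance_in="c")
        b.add(f"DM_{_fa_token(fa)}", {fa_met: -1.0},
              name=f"{fa} drain", subsystem="demand")

    # -- TAG assembly ------------------------------------------------------
    for name, chains in sorted(species.items()):
        tag_met = b.met(f"{name}_c", _tag_formula(chains),
                        f"triacylglycerol ({'/'.join(chains)})")
        stoich = {b.met("glycerol_c", data.GLYCEROL_FORMULA, "glycerol"): -1.0,
                  cof["atp"]: -3.0, tag_met: 1.0, cof["adp"]: 3.0,
                  cof["pi"]: 3.0}
        for chain in chains:
            key = b.met(f"{_fa_token(chain)}_c", None, "")
            stoich[key] = stoich.get(key, 0.0) - 1.0
        b.add(f"TAGS_{name}", stoich,
              name=f"TAG assembly ({'/'.join(chains)}), lumped",
              gpr="g_gpat and g_dgat", subsystem="lipid", balance_in="c")

    # -- biomass -----------------------------------------------------------
    met_ids = {s: _biomass_met_id(s) for s in spec.normalized_mass_fractions}
    for s, met_id in met_ids.items():
        if met_id not in b.metabolites:
            raise GenerationError(
                f"unsatisfiable precursor: biomass species {s!r} has no "
                f"producing route in the generated network"
            )
    b.met("biomass_c", None, "biomass")
    biomass_rxn = assemble_biomass_reaction(
        spec, _species_molar_masses(species), metabolite_ids=met_ids
    )
    b.reactions.append(biomass_rxn)
    b.add("DM_biomass", {"biomass_c": -1.0}, name="biomass drain",
          subsystem="demand")

    # -- decoys ------------------------------------------------------------
    rng = np.random.default_rng(params.seed)
    for i in range(params.n_decoys):
        k = int(rng.integers(3, 9))
        formula = _compose({"C": k, "H": 2 * k, "O": k})
        x = b.met(f"decoy{i}a_c", formula, f"decoy metabolite {i}a")
        y = b.met(f"decoy{i}b_c", formula, f"decoy metabolite {i}b")
        b.add(f"DECOY_{i}", {x: -1.0, y: 1.0},
              name=f"decoy isomerase {i}", subsystem="decoy")

    reactions = list(b.reactions)
    order = rng.permutation(len(reactions))
    reactions = [reactions[i] for i in order]

    used = {met for r in reactions for met in r.stoichiometry}
    genes = sorted({tok for r in reactions for tok in r.gpr.split()
                    if tok.startswith("g_")})
    model = MetabolicModel(
        id=f"synthetic_larva_seed{params.seed}",
        metabolites=sorted(
            (m for m in b.metabolites.values() if m.id in used),
            key=lambda m: m.id,
        ),
        reactions=reactions,
        compartments={"e": "extracellular", "c": "cytosol",
                      "m": "mitochondrion"},
        objective="BIOMASS",
        objective_direction="maximize",
        genes=genes,
    )
    model.validate()
    _check_feasible(params, spec, species, diet)
    return model


def _check_feasible(params, spec, species, diet) -> None:
    """Raise when the diet cannot support positive growth analytically."""
    mu, limiting = analytic_bottleneck(params)
    if not mu > 0:
        raise GenerationError(
            f"unsatisfiable precursor: {limiting or 'unknown'} has zero "
            "dietary supply"
        )


def _biomass_met_id(species: str) -> str:
    if species == "sugars":
        return "glc_c"
    if species == "cholesterol":
        return "chol_c"
    if species in ("tag_a", "tag_b", "glycogen", "glycerol"):
        return f"{species}_c"
    return f"{species}_c"  # amino acids


def reference_diet(params: SyntheticNetworkParams | None = None) -> ExchangeBounds:
    """Measured reference diet restricted to the generated nutrient set."""
    params = params or SyntheticNetworkParams()
    full = reference_exchange_bounds()
    keep = {f"EX_{aa}_e" for aa in params.amino_acids()}
    keep.add("EX_chol_e")
    if params.include_glucose:
        keep.add("EX_glc_e")
    return ExchangeBounds(
        {k: v for k, v in full.bounds.items() if k in keep}
    )


# ---------------------------------------------------------------------------
# analytic optimum
# ---------------------------------------------------------------------------

def analytic_bottleneck(
    params: SyntheticNetworkParams | None = None,
) -> tuple[float, str]:
    """Closed-form FBA optimum of the generated network.

    Returns ``(optimum, limiting_precursor)`` where the optimum is
    ``min_i(uptake_i / biomass_coefficient_i)`` over the directly supplied
    precursors (amino acids, cholesterol).  Raises when glucose-derived
    demand (carbon plus energy) would exceed the glucose uptake at that
    optimum, because the bottleneck formula then no longer holds.
    """
    params = params or SyntheticNetworkParams()
    spec, species = build_biomass(params)
    diet = reference_diet(params)
    masses = _species_molar_masses(species)
    coefs = {
        s: f * params.larva_dry_weight / masses[s]
        for s, f in spec.normalized_mass_fractions.items() if f > 0
    }
    mu, limiting = np.inf, ""
    for s, coef in coefs.items():
        ex = {"cholesterol": "EX_chol_e"}.get(s, f"EX_{s}_e")
        if ex not in diet.bounds:
            if s in ("tag_a", "tag_b", "glycogen", "sugars", "glycerol"):
                continue  # glucose-derived, handled below
            raise GenerationError(f"unsatisfiable precursor: {s}")
        rate = diet.bounds[ex] / coef
        if rate < mu:
            mu, limiting = rate, s
    glc_need = _glucose_demand_per_unit(params, spec, species, coefs)
    if params.include_glucose:
        glc_cap = diet.bounds["EX_glc_e"]
        if glc_need * mu > glc_cap + 1e-12:
            raise GenerationError(
                "unsatisfiable precursor: glucose-derived demand "
                f"{glc_need * mu:.4g} exceeds uptake {glc_cap:.4g} "
                "mmol/larva/day at the amino-acid bottleneck"
            )
    elif glc_need > 0:
        raise GenerationError(
            "unsatisfiable precursor: glucose-derived biomass species "
            "present but include_glucose is False"
        )
    return float(mu), limiting


def _glucose_demand_per_unit(params, spec, species, coefs) -> float:
    """Glucose (mmol) needed per unit biomass flux: carbon plus energy."""
    accoa = nadph = desat_nadh = atp = glycerol_units = 0.0
    glc = coefs.get("sugars", 0.0) + coefs.get("glycogen", 0.0)
    atp += coefs.get("glycogen", 0.0)
    glycerol_units += coefs.get("glycerol", 0.0)
    for name, chains in species.items():
        n_tag = coefs.get(name, 0.0)
        if not n_tag:
            continue
        glycerol_units += n_tag
        atp += 3.0 * n_tag
        for chain in chains:
            length, db = _fa_length_db(chain)
            accoa += n_tag * length / 2
            nadph += n_tag * (length - 2)
            atp += n_tag * (length / 2 - 1)
            desat_nadh += n_tag * db
    glc += 0.5 * glycerol_units + accoa / 2.0
    glc_glyco = accoa / 2.0  # glucose that passes the glycolysis lump
    nadh = 4.0 * glc_glyco - glycerol_units - nadph - desat_nadh
    atp_avail = 2.0 * glc_glyco + 2.0 * max(nadh, 0.0)
    # energy shortfalls are covered by fully oxidizing extra glucose
    # (glycolysis + citric-acid-cycle lumps: 12 NADH + 4 ATP per glucose)
    if nadh < 0:
        extra = -nadh / 12.0
        glc += extra
        atp_avail = 2.0 * glc_glyco + 4.0 * extra
    if atp_avail < atp:
        glc += (atp - atp_avail) / 28.0  # 4 ATP + 12 NADH * P/O 2
    return glc


# ---------------------------------------------------------------------------
# random toy networks (oracle fodder)
# ---------------------------------------------------------------------------

def random_toy_network(
    seed: int,
    n_reactions: int = 8,
    n_metabolites: int = 4,
) -> MetabolicModel:
    """Small random network for brute-force oracle cross-checks.

    Builds an uptake -> internal web -> drain chain whose last reaction is
    the objective.  Feasibility is not guaranteed to be nonzero, but the
    problem is always bounded (all bounds finite).
    """
    rng = np.random.default_rng(seed)
    n_internal = max(1, n_reactions - 2)
    mets = [
        Metabolite(id=f"m{i}", compartment="c") for i in range(n_metabolites)
    ]
    reactions = [
        Reaction(id="UPT", stoichiometry={"m0": 1.0},
                 lower_bound=0.0, upper_bound=float(rng.integers(1, 10))),
        Reaction(id="DRAIN", stoichiometry={f"m{n_metabolites - 1}": -1.0},
                 lower_bound=0.0, upper_bound=float(rng.integers(1, 10))),
    ]
    for j in range(n_internal):
        k = int(rng.integers(2, min(4, n_metabolites) + 1))
        chosen = rng.choice(n_metabolites, size=k, replace=False)
        stoich = {}
        for idx, met in enumerate(chosen):
            coef = float(rng.integers(1, 3))
            stoich[f"m{met}"] = coef if idx % 2 else -coef
        lb = float(rng.choice([0.0, -rng.integers(1, 8)]))
        reactions.append(
            Reaction(id=f"R{j}", stoichiometry=stoich, lower_bound=lb,
                     upper_bound=float(rng.integers(1, 10)))
        )
    model = MetabolicModel(
        id=f"toy_seed{seed}",
        metabolites=mets,
        reactions=reactions,
        compartments={"c": "cytosol"},
        objective="DRAIN",
    )
    model.validate()
    return model
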