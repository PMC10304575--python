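"""Reference data for the black-soldier-fly larva feeding experiment.

Bundles the measured inputs the pipeline operates on: the applied diet
(ingredient masses and residues over a nine-day feeding of V-instar larvae on
a glucose / egg-white-protein substrate), the dietary amino-acid profile with
its per-larva transport rates, and the larval fatty-acid profile, together
with chemical formulas for every compound the synthetic network uses.
"""

from __future__ import annotations

from .model import formula_molar_mass

# ---------------------------------------------------------------------------
# Diet: ingredient masses over the whole experiment (grams) and residues.
# ---------------------------------------------------------------------------

DIET_INGREDIENTS = {
    "glucose": {"total_g": 846.0, "residue_g": 0.0},
    "egg_white_protein": {"total_g": 1870.0, "residue_g": 1310.0},
    "water": {"total_g": 5284.0, "residue_g": 4890.0},
}

DIET_DURATION_DAYS = 9
FINAL_LARVA_WET_WEIGHT_G = 0.028

# ---------------------------------------------------------------------------
# Dietary amino-acid profile: mg per 100 g protein, the amino-acid mass
# consumed over the experiment (g), and the measured transport rate in
# mg per larva per day.  Cystine is the oxidized dimer.
# ---------------------------------------------------------------------------

AMINO_ACID_PROFILE_MG_PER_100G_PROTEIN = {
    "lysine": 6000.0, "methionine": 3500.0, "cystine": 2500.0,
    "aspartate": 4800.0, "asparagine": 4800.0, "threonine": 4300.0,
    "serine": 6400.0, "glutamate": 6150.0, "glutamine": 6150.0,
    "proline": 3600.0, "glycine": 3300.0, "alanine": 5800.0,
    "valine": 6500.0, "isoleucine": 5100.0, "leucine": 8000.0,
    "tyrosine": 3700.0, "phenylalanine": 5500.0, "histidine": 2200.0,
    "arginine": 5400.0, "tryptophan": 1500.0,
}

AMINO_ACID_CONSUMED_G = {
    "lysine": 85.272, "methionine": 50.116, "cystine": 36.465,
    "aspartate": 48.62, "asparagine": 48.62, "threonine": 62.832,
    "serine": 93.687, "glutamate": 62.271, "glutamine": 62.271,
    "proline": 52.921, "glycine": 47.872, "alanine": 84.898,
    "valine": 95.183, "isoleucine": 74.239, "leucine": 117.062,
    "tyrosine": 54.604, "phenylalanine": 78.914, "histidine": 32.164,
    "arginine": 79.475, "tryptophan": 23.001,
}

AMINO_ACID_MG_PER_LARVA_DAY = {
    "lysine": 1.769, "methionine": 1.039, "cystine": 0.756,
    "aspartate": 1.008, "asparagine": 1.008, "threonine": 1.303,
    "serine": 1.943, "glutamate": 1.292, "glutamine": 1.292,
    "proline": 1.098, "glycine": 0.993, "alanine": 1.761,
    "valine": 1.974, "isoleucine": 1.540, "leucine": 2.428,
    "tyrosine": 1.133, "phenylalanine": 1.637, "histidine": 0.667,
    "arginine": 1.648, "tryptophan": 0.477,
}

AMINO_ACID_FORMULAS = {
    "lysine": "C6H14N2O2", "methionine": "C5H11NO2S", "cystine": "C6H12N2O4S2",
    "aspartate": "C4H7NO4", "asparagine": "C4H8N2O3", "threonine": "C4H9NO3",
    "serine": "C3H7NO3", "glutamate": "C5H9NO4", "glutamine": "C5H10N2O3",
    "proline": "C5H9NO2", "glycine": "C2H5NO2", "alanine": "C3H7NO2",
    "valine": "C5H11NO2", "isoleucine": "C6H13NO2", "leucine": "C6H13NO2",
    "tyrosine": "C9H11NO3", "phenylalanine": "C9H11NO2",
    "histidine": "C6H9N3O2", "arginine": "C6H14N4O2",
    "tryptophan": "C11H12N2O2",
}

#: Molar masses (g/mmol == g/mol / 1000 is NOT applied; values are g/mol,
#: numerically equal to mg/mmol) derived from the formulas above.
AMINO_ACID_MOLAR_MASSES = {
    aa: formula_molar_mass(f) for aa, f in AMINO_ACID_FORMULAS.items()
}

#: Classical animal essential amino acids; the experiment's doubled-EAA
#: scenario scales these uptakes.  Configurable wherever used.
ESSENTIAL_AMINO_ACIDS = frozenset(
    {"lysine", "methionine", "threonine", "valine", "isoleucine",
     "leucine", "phenylalanine", "histidine", "arginine", "tryptophan"}
)

# ---------------------------------------------------------------------------
# Larval fatty-acid profile (g per 100 g fat).  The starred six acids are the
# ones carried into the biomass triacylglycerols.
# ---------------------------------------------------------------------------

FATTY_ACID_PROFILE_G_PER_100G_FAT = {
    "C8:0": 0.13,
    "C12:0": 29.4,
    "C14:0": 5.75,
    "C14:1": 0.73,
    "C16:0": 10.45,
    "C16:1": 5.69,
    "C18:0": 3.5,
    "C18:1": 21.05,
    "C18:2": 19.8,
    "C18:3": 0.48,
}

#: The fatty acids modeled explicitly (synthesis routes + drains).
MODELED_FATTY_ACIDS = ("C12:0", "C14:0", "C16:0", "C16:1", "C18:0",
                       "C18:1", "C18:2")

#: The six profile acids esterified into the two biomass TAG species.
TAG_A_CHAINS = ("C12:0", "C14:0", "C16:0")
TAG_B_CHAINS = ("C16:1", "C18:1", "C18:2")

SATURATED_FATTY_ACIDS = ("C12:0", "C14:0", "C16:0", "C18:0")
UNSATURATED_FATTY_ACIDS = ("C14:1", "C16:1", "C18:1", "C18:2")
MONOUNSATURATED_FATTY_ACIDS = ("C14:1", "C16:1", "C18:1")
POLYUNSATURATED_FATTY_ACIDS = ("C18:2",)

FATTY_ACID_FORMULAS = {
    "C8:0": "C8H16O2",
    "C12:0": "C12H24O2",
    "C14:0": "C14H28O2",
    "C14:1": "C14H26O2",
    "C16:0": "C16H32O2",
    "C16:1": "C16H30O2",
    "C18:0": "C18H36O2",
    "C18:1": "C18H34O2",
    "C18:2": "C18H32O2",
    "C18:3": "C18H30O2",
}

# ---------------------------------------------------------------------------
# Other compounds.
# ---------------------------------------------------------------------------

GLUCOSE_FORMULA = "C6H12O6"
GLUCOSE_MOLAR_MASS = formula_molar_mass(GLUCOSE_FORMULA)
CHOLESTEROL_FORMULA = "C27H46O"
CHOLESTEROL_MOLAR_MASS = formula_molar_mass(CHOLESTEROL_FORMULA)
GLYCEROL_FORMULA = "C3H8O3"
GLYCOGEN_UNIT_FORMULA = "C6H10O5"  # anhydroglucose repeat unit

#: Cofactor formulas (BiGG-style species at physiological protonation).
COFACTOR_FORMULAS = {
    "atp": "C10H12N5O13P3",
    "adp": "C10H12N5O10P2",
    "pi": "HO4P",
    "nad": "C21H26N7O14P2",
    "nadh": "C21H27N7O14P2",
    "nadp": "C21H25N7O17P3",
    "nadph": "C21H26N7O17P3",
    "coa": "C21H32N7O16P3S",
    "accoa": "C23H34N7O17P3S",
    "pyr": "C3H3O3",
    "h2o": "H2O",
    "h": "H",
    "co2": "CO2",
    "o2": "O2",
    # cytochrome b5: a fixed heme-protein stand-in differing by one H
    "ficytb5": "C42H52FeN8O6",
    "focytb5": "C42H53FeN8O6",
}


def implied_larva_count() -> float:
    """Larva count consistent with the printed per-larva amino-acid rates.

    The experiment's directly printed counts are mutually inconsistent, so
    the count is back-computed from consumed mass and the measured
    mg/larva/day column (averaged over the twenty amino acids).
    """
    counts = [
        AMINO_ACID_CONSUMED_G[aa] * 1000.0
        / (DIET_DURATION_DAYS * AMINO_ACID_MG_PER_LARVA_DAY[aa])
        for aa in AMINO_ACID_MG_PER_LARVA_DAY
    ]
    return sum(counts) / len(counts)
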