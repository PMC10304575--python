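import json

import pytest

from larvaflux import data
from larvaflux.diet import apply_diet
from larvaflux.fluxopt import fba
from larvaflux.io import write_model
from larvaflux.qc import check_mass_balance
from larvaflux.synthetic import (
    GenerationError,
    SyntheticNetworkParams,
    analytic_bottleneck,
    generate_network,
    random_toy_network,
    reference_diet,
)


def serialized(model, tmp_path, tag):
    path = tmp_path / f"{tag}.json"
    write_model(model, path)
    return path.read_text()


class TestDeterminism:
    def test_same_seed_identical(self, tmp_path):
        a = generate_network(SyntheticNetworkParams(seed=7))
        b = generate_network(SyntheticNetworkParams(seed=7))
        assert serialized(a, tmp_path, "a") == serialized(b, tmp_path, "b")

    def test_seed_permutes_order_not_content(self):
        a = generate_network(SyntheticNetworkParams(seed=1))
        b = generate_network(SyntheticNetworkParams(seed=2))
        assert [r.id for r in a.reactions] != [r.id for r in b.reactions]
        assert {r.id for r in a.reactions} == {r.id for r in b.reactions}
        assert fba(a).objective_value == pytest.approx(
            fba(b).objective_value, rel=1e-12)

    def test_decoys_seeded_and_harmless(self):
        base = generate_network(SyntheticNetworkParams(seed=5))
        decoyed = generate_network(SyntheticNetworkParams(seed=5, n_decoys=4))
        assert len(decoyed.reactions) == len(base.reactions) + 4
        assert fba(decoyed).objective_value == pytest.approx(
            fba(base).objective_value, rel=1e-12)


class TestStructure:
    def test_three_compartments(self, synthetic_model):
        assert set(synthetic_model.compartments) == {"e", "c", "m"}

    def test_nutrient_exchanges_present(self, synthetic_model):
        ids = {r.id for r in synthetic_model.reactions}
        for aa in data.AMINO_ACID_PROFILE_MG_PER_100G_PROTEIN:
            assert f"EX_{aa}_e" in ids
        assert "EX_glc_e" in ids and "EX_chol_e" in ids

    def test_fatty_acid_routes_and_tags(self, synthetic_model):
        ids = {r.id for r in synthetic_model.reactions}
        for fa in data.MODELED_FATTY_ACIDS:
            token = "fa" + fa[1:].replace(":", "_")
            assert f"FAS_{token}" in ids
            assert f"DM_{token}" in ids
        assert "TAGS_tag_a" in ids and "TAGS_tag_b" in ids
        assert "CYTB5R" in ids

    def test_biomass_consumes_required_classes(self, synthetic_model):
        stoich = synthetic_model.reaction("BIOMASS").stoichiometry
        consumed = {m for m, c in stoich.items() if c < 0}
        assert {"tag_a_c", "tag_b_c", "glycogen_c", "glc_c", "glycerol_c",
                "chol_c"} <= consumed
        assert "lysine_c" in consumed and "tryptophan_c" in consumed
        assert stoich["biomass_c"] == 1.0
        assert synthetic_model.objective == "BIOMASS"

    def test_genes_collected_from_gprs(self, synthetic_model):
        assert "g_cyb5r" in synthetic_model.genes
        assert all(g.startswith("g_") for g in synthetic_model.genes)


class TestMassBalance:
    def test_all_internal_reactions_balanced_except_biomass(self, synthetic_model):
        balance = check_mass_balance(synthetic_model)
        for rxn in synthetic_model.reactions:
            if rxn.is_boundary() or rxn.id == "BIOMASS":
                continue
            assert balance[rxn.id]["status"] == "balanced", (
                rxn.id, balance[rxn.id])


class TestAnalyticOptimum:
    def test_lp_recovers_bottleneck(self, synthetic_model, default_params):
        mu, limiting = analytic_bottleneck(default_params)
        solution = fba(synthetic_model)
        assert solution.optimal
        assert solution.objective_value == pytest.approx(mu, rel=1e-9)
        assert limiting in ("glutamate", "glutamine")

    def test_glucose_not_limiting(self, synthetic_model, synthetic_diet):
        solution = fba(synthetic_model)
        glc_flux = -solution.fluxes["EX_glc_e"]
        assert glc_flux < synthetic_diet.bounds["EX_glc_e"] - 1e-6

    def test_steady_state_and_bounds_respected(self, synthetic_model):
        solution = fba(synthetic_model)
        for rxn in synthetic_model.reactions:
            v = solution.fluxes[rxn.id]
            assert rxn.lower_bound - 1e-6 <= v <= rxn.upper_bound + 1e-6

    def test_cytb5r_gates_growth(self, synthetic_model, synthetic_diet):
        knockout = synthetic_model.copy()
        rxn = knockout.reaction("CYTB5R")
        rxn.lower_bound = rxn.upper_bound = 0.0
        solution = fba(apply_diet(knockout, synthetic_diet))
        assert solution.optimal
        assert abs(solution.objective_value) < 1e-9

    def test_saturated_only_fatty_acid_set(self):
        params = SyntheticNetworkParams(
            seed=0, fatty_acid_set=("C12:0", "C14:0", "C16:0"))
        model = generate_network(params)
        assert not model.has_reaction("CYTB5R")
        assert not model.has_reaction("TAGS_tag_b")
        mu, _ = analytic_bottleneck(params)
        assert fba(model).objective_value == pytest.approx(mu, rel=1e-9)


class TestParamsValidation:
    def test_bad_tag_split(self):
        with pytest.raises(GenerationError, match="tag_split"):
            SyntheticNetworkParams(tag_split=(0.6, 0.6))

    def test_bad_n_amino_acids(self):
        with pytest.raises(GenerationError, match="n_amino_acids"):
            SyntheticNetworkParams(n_amino_acids=0)

    def test_unknown_fatty_acid(self):
        with pytest.raises(GenerationError, match="unsupported"):
            SyntheticNetworkParams(fatty_acid_set=("C20:4",))

    def test_empty_fatty_acid_set(self):
        with pytest.raises(GenerationError, match="non-empty"):
            SyntheticNetworkParams(fatty_acid_set=())

    def test_unsatisfiable_fat_demand_names_the_precursor(self):
        # C18:0 is modeled but belongs to neither TAG species; biomass fat
        # then has no producible constituent.
        with pytest.raises(GenerationError, match="unsatisfiable precursor"):
            generate_network(
                SyntheticNetworkParams(seed=0, fatty_acid_set=("C18:0",)))


class TestReferenceDiet:
    def test_restricted_to_generated_nutrients(self, default_params):
        bounds = reference_diet(default_params).bounds
        assert set(bounds) == (
            {f"EX_{aa}_e" for aa in default_params.amino_acids()}
            | {"EX_glc_e", "EX_chol_e"}
        )

    def test_no_glucose_variant(self):
        params = SyntheticNetworkParams(include_glucose=False)
        assert "EX_glc_e" not in reference_diet(params).bounds

    def test_all_limits_nonnegative(self, synthetic_diet):
        assert all(v >= 0 for v in synthetic_diet.bounds.values())


class TestRandomToyNetwork:
    def test_deterministic(self):
        a = random_toy_network(3)
        b = random_toy_network(3)
        assert [r.stoichiometry for r in a.reactions] == \
               [r.stoichiometry for r in b.reactions]
        assert [(r.lower_bound, r.upper_bound) for r in a.reactions] == \
               [(r.lower_bound, r.upper_bound) for r in b.reactions]

    def test_valid_and_bounded(self):
        for seed in range(10):
            model = random_toy_network(seed)
            model.validate()
            for rxn in model.reactions:
                assert rxn.lower_bound > -float("inf")
                assert rxn.upper_bound < float("inf")
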