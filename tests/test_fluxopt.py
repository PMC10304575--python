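import numpy as np
import pytest

from larvaflux.diet import ExchangeBounds, apply_diet
from larvaflux.fluxopt import (
    FluxSolution,
    fba,
    fva,
    growth_change_percent,
    run_perturbation_experiment,
)
from larvaflux.model import MetabolicModel, Metabolite, Reaction, \
    stoichiometric_matrix
from larvaflux.synthetic import random_toy_network

from oracles import oracle_fba, oracle_fva


class TestFBA:
    def test_linear_chain_optimum_is_uptake_limit(self, linear_chain_model):
        solution = fba(linear_chain_model)
        assert solution.optimal
        assert solution.objective_value == pytest.approx(10.0, abs=1e-9)
        assert solution.fluxes["EX_A"] == pytest.approx(-10.0, abs=1e-9)

    def test_infeasible_reported_not_raised(self):
        # forced production with no outlet
        model = MetabolicModel(
            id="stuck",
            metabolites=[Metabolite(id="a", compartment="c")],
            reactions=[Reaction(id="MAKE", stoichiometry={"a": 1.0},
                                lower_bound=1.0, upper_bound=2.0)],
            compartments={"c": "cytosol"},
            objective="MAKE",
        )
        solution = fba(model)
        assert solution.status == "infeasible"
        assert solution.objective_value is None

    def test_unbounded_reported(self):
        model = MetabolicModel(
            id="loose",
            metabolites=[Metabolite(id="a", compartment="c")],
            reactions=[
                Reaction(id="IN", stoichiometry={"a": 1.0},
                         lower_bound=-np.inf, upper_bound=np.inf),
                Reaction(id="OUT", stoichiometry={"a": -1.0},
                         lower_bound=-np.inf, upper_bound=np.inf),
            ],
            compartments={"c": "cytosol"},
            objective="OUT",
        )
        assert fba(model).status == "unbounded"

    def test_matches_vertex_enumeration_oracle(self):
        """FBA optimum equals the brute-force oracle on random networks
        with <= 8 reactions (1e-7)."""
        checked = 0
        for seed in range(30):
            for n_rxns in (4, 6, 8):
                model = random_toy_network(seed, n_reactions=n_rxns)
                expected = oracle_fba(model)
                solution = fba(model)
                if expected is None:
                    assert solution.status == "infeasible"
                    continue
                assert solution.optimal
                assert solution.objective_value == pytest.approx(
                    expected, abs=1e-7), (seed, n_rxns)
                checked += 1
        assert checked >= 50  # the ensemble is overwhelmingly feasible

    def test_steady_state_residual_below_1e6(self):
        for seed in range(30):
            model = random_toy_network(seed)
            solution = fba(model)
            if not solution.optimal:
                continue
            S = stoichiometric_matrix(model)
            v = np.array([solution.fluxes[r.id] for r in model.reactions])
            assert np.max(np.abs(S @ v)) <= 1e-6


class TestFVA:
    def test_sandwich_and_objective_retention(self, synthetic_model):
        base = fba(synthetic_model)
        drains = [r.id for r in synthetic_model.reactions
                  if r.id.startswith("DM_fa")]
        result = fva(synthetic_model, 0.9, drains)
        assert result.reference_optimum == pytest.approx(base.objective_value)
        for rxn_id in drains:
            lo, hi = result.range(rxn_id)
            assert lo <= hi + 1e-9
            assert lo >= -1e-9  # irreversible drains
            assert hi > 0  # slack at 90% allows some fatty-acid export

    def test_full_fraction_pins_objective(self, linear_chain_model):
        result = fva(linear_chain_model, 1.0, ["EX_C"])
        lo, hi = result.range("EX_C")
        assert lo == pytest.approx(10.0, abs=1e-7)
        assert hi == pytest.approx(10.0, abs=1e-7)

    def test_matches_vertex_enumeration_oracle(self):
        """FVA extrema equal the slack-variable brute-force oracle (1e-7)."""
        checked = 0
        for seed in range(12):
            model = random_toy_network(seed, n_reactions=6)
            if not fba(model).optimal:
                continue
            result = fva(model, 0.9)
            for rxn in model.reactions:
                lo_exp, hi_exp = oracle_fva(model, 0.9, rxn.id)
                lo, hi = result.range(rxn.id)
                assert lo == pytest.approx(lo_exp, abs=1e-7), (seed, rxn.id)
                assert hi == pytest.approx(hi_exp, abs=1e-7), (seed, rxn.id)
                checked += 1
        assert checked >= 30

    def test_bad_fraction_rejected(self, linear_chain_model):
        with pytest.raises(ValueError, match="fraction"):
            fva(linear_chain_model, 0.0)
        with pytest.raises(ValueError, match="fraction"):
            fva(linear_chain_model, 1.5)


class TestRelaxationMonotonicity:
    def test_doubling_any_uptake_never_decreases_optimum(self):
        """Over 100 seeded random networks, doubling the uptake capacity
        can only enlarge the feasible region, so the optimum cannot drop —
        the mechanism behind a non-limiting substrate showing 0% change."""
        for seed in range(100):
            model = random_toy_network(seed)
            base = fba(model)
            if not base.optimal:
                continue
            relaxed = model.copy()
            relaxed.reaction("UPT").upper_bound *= 2.0
            widened = fba(relaxed)
            assert widened.optimal
            assert widened.objective_value >= base.objective_value - 1e-9

    def test_doubled_glucose_zero_change_on_synthetic(self, synthetic_model,
                                                      synthetic_diet):
        result = run_perturbation_experiment(
            synthetic_model, synthetic_diet, "doubled_glucose")
        assert result["growth_change_percent"] == pytest.approx(0.0, abs=1e-6)

    def test_doubling_the_limiting_uptake_raises_growth(self, synthetic_model,
                                                        synthetic_diet):
        """Glutamate/glutamine tie for the bottleneck; doubling both moves
        the optimum up to the next bottleneck, predicted in closed form from
        min_i(uptake_i / biomass coefficient_i).

        Diet and biomass derive from the same protein profile, so the amino
        acids are nearly co-limiting and the lift is small but exact.
        """
        stoich = synthetic_model.reaction("BIOMASS").stoichiometry
        ratios = {}
        for ex, limit in synthetic_diet.bounds.items():
            met = ex[len("EX_"):-len("_e")] + "_c"
            if met in stoich and stoich[met] < 0:
                ratios[ex] = limit / -stoich[met]
        doubled = {ex: r * (2.0 if ex in ("EX_glutamate_e", "EX_glutamine_e")
                            else 1.0)
                   for ex, r in ratios.items()}
        expected = 100.0 * (min(doubled.values()) / min(ratios.values()) - 1.0)
        assert expected > 0
        result = run_perturbation_experiment(
            synthetic_model, synthetic_diet, "doubled_EAA",
            eaa_exchanges=["EX_glutamate_e", "EX_glutamine_e"])
        assert result["growth_change_percent"] == pytest.approx(
            expected, rel=1e-6)

    def test_doubling_a_nonlimiting_amino_acid_changes_nothing(
            self, synthetic_model, synthetic_diet):
        result = run_perturbation_experiment(
            synthetic_model, synthetic_diet, "doubled_EX_valine_e")
        assert result["growth_change_percent"] == pytest.approx(0.0, abs=1e-6)


class TestPerturbationMachinery:
    def test_growth_change_arithmetic(self):
        ref = FluxSolution("optimal", 0.029)
        pert = FluxSolution("optimal", 0.051)
        assert growth_change_percent(ref, pert) == pytest.approx(
            75.86, abs=0.005)

    def test_growth_change_requires_optimal_inputs(self):
        with pytest.raises(ValueError):
            growth_change_percent(FluxSolution("infeasible", None),
                                  FluxSolution("optimal", 1.0))

    def test_growth_change_zero_reference(self):
        with pytest.raises(ValueError, match="zero"):
            growth_change_percent(FluxSolution("optimal", 0.0),
                                  FluxSolution("optimal", 1.0))

    def test_unknown_scenario(self, synthetic_model, synthetic_diet):
        with pytest.raises(ValueError, match="scenario"):
            run_perturbation_experiment(synthetic_model, synthetic_diet,
                                        "halved_glucose")

    def test_scenario_target_must_exist(self, synthetic_model):
        with pytest.raises(KeyError):
            run_perturbation_experiment(
                synthetic_model, ExchangeBounds({"EX_glc_e": 0.1}),
                "doubled_EX_lysine_e")

    def test_fva_attached_when_drains_given(self, synthetic_model,
                                            synthetic_diet):
        result = run_perturbation_experiment(
            synthetic_model, synthetic_diet, "doubled_glucose",
            fa_drains=["DM_fa12_0"])
        assert result["reference_fva"].range("DM_fa12_0")[1] >= 0
        assert result["perturbed_fva"].range("DM_fa12_0")[1] >= \
            result["reference_fva"].range("DM_fa12_0")[1] - 1e-9
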