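import pytest
from hypothesis import given, settings, strategies as st

from larvaflux.cce import (
    CarbonEfficiencyInput,
    carbon_count,
    cce_experiment,
    compute_cce,
)
from larvaflux.diet import ExchangeBounds, scale_uptake
from larvaflux.model import MetabolicModel, Metabolite, Reaction


class TestCarbonCount:
    def test_examples(self):
        assert carbon_count("C6H12O6") == 6
        assert carbon_count("C12H24O2") == 12
        assert carbon_count("C27H46O") == 27
        assert carbon_count("H2O") == 0

    def test_unparseable_raises(self):
        with pytest.raises(ValueError):
            carbon_count("six carbons")


class TestComputeCCE:
    def test_all_carbon_routed(self):
        inp = CarbonEfficiencyInput(
            uptake_terms=[("EX_glc_e", 1.0, 6)],
            drain_id="DM_fa12_0", drain_rate=0.5, drain_carbons=12)
        assert compute_cce(inp, "printed") == pytest.approx(100.0)
        assert compute_cce(inp, "efficiency") == pytest.approx(100.0)

    def test_half_the_carbon_routed(self):
        inp = CarbonEfficiencyInput(
            uptake_terms=[("EX_glc_e", 1.0, 6)],
            drain_id="DM_fa12_0", drain_rate=0.25, drain_carbons=12)
        assert compute_cce(inp, "efficiency") == pytest.approx(50.0)
        assert compute_cce(inp, "printed") == pytest.approx(200.0)

    def test_doubling_uptakes_doubles_printed_halves_efficiency(self):
        base = CarbonEfficiencyInput(
            uptake_terms=[("EX_a_e", 1.0, 6), ("EX_b_e", 0.5, 3)],
            drain_id="d", drain_rate=0.1, drain_carbons=12)
        doubled = CarbonEfficiencyInput(
            uptake_terms=[(ex, 2 * r, ci) for ex, r, ci in base.uptake_terms],
            drain_id="d", drain_rate=0.1, drain_carbons=12)
        assert compute_cce(doubled, "printed") == pytest.approx(
            2 * compute_cce(base, "printed"))
        assert compute_cce(doubled, "efficiency") == pytest.approx(
            compute_cce(base, "efficiency") / 2)

    @settings(max_examples=200, deadline=None)
    @given(
        rates=st.lists(st.floats(0.001, 100.0), min_size=1, max_size=6),
        carbons=st.lists(st.integers(1, 30), min_size=6, max_size=6),
        drain=st.floats(0.001, 100.0),
        cf=st.integers(1, 30),
    )
    def test_orientation_duality(self, rates, carbons, drain, cf):
        inp = CarbonEfficiencyInput(
            uptake_terms=[(f"EX_{i}", r, carbons[i])
                          for i, r in enumerate(rates)],
            drain_id="d", drain_rate=drain, drain_carbons=cf)
        product = compute_cce(inp, "printed") * compute_cce(inp, "efficiency")
        assert product == pytest.approx(10000.0, rel=1e-12)

    def test_zero_denominators_guarded(self):
        no_drain = CarbonEfficiencyInput(
            uptake_terms=[("EX_a", 1.0, 6)], drain_id="d",
            drain_rate=0.0, drain_carbons=12)
        with pytest.raises(ZeroDivisionError):
            compute_cce(no_drain, "printed")
        no_carbon_in = CarbonEfficiencyInput(
            uptake_terms=[("EX_a", 0.0, 6)], drain_id="d",
            drain_rate=1.0, drain_carbons=12)
        with pytest.raises(ZeroDivisionError):
            compute_cce(no_carbon_in, "efficiency")

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            CarbonEfficiencyInput(uptake_terms=[("EX_a", -1.0, 6)],
                                  drain_id="d", drain_rate=1.0,
                                  drain_carbons=12)
        with pytest.raises(ValueError):
            CarbonEfficiencyInput(uptake_terms=[("EX_a", 1.0, 0)],
                                  drain_id="d", drain_rate=1.0,
                                  drain_carbons=12)
        inp = CarbonEfficiencyInput(uptake_terms=[("EX_a", 1.0, 6)],
                                    drain_id="d", drain_rate=1.0,
                                    drain_carbons=12)
        with pytest.raises(ValueError, match="orientation"):
            compute_cce(inp, "sideways")


def _single_chain_model():
    """EX_glc -> glc -> (2x) fa3 -> DM_fa3: loss-free carbon chain."""
    return MetabolicModel(
        id="chain",
        metabolites=[
            Metabolite(id="glc_c", compartment="c", formula="C6H12O6"),
            Metabolite(id="fa_c", compartment="c", formula="C3H6O3"),
        ],
        reactions=[
            Reaction(id="EX_glc_e", stoichiometry={"glc_c": -1.0},
                     lower_bound=-1.0, upper_bound=0.0),
            Reaction(id="SPLIT", stoichiometry={"glc_c": -1.0, "fa_c": 2.0},
                     lower_bound=0.0),
            Reaction(id="DM_fa", stoichiometry={"fa_c": -1.0},
                     lower_bound=0.0),
        ],
        compartments={"c": "cytosol"},
        objective="DM_fa",
    )


class TestExperiment:
    def test_loss_free_chain_is_100_percent(self):
        model = _single_chain_model()
        result = cce_experiment(model, ExchangeBounds({"EX_glc_e": 1.0}),
                                ["DM_fa"], fraction=1.0)
        vals = result.per_fatty_acid["DM_fa"]
        assert vals["efficiency"] == pytest.approx(100.0, abs=1e-6)
        assert vals["printed"] == pytest.approx(100.0, abs=1e-6)

    def test_zero_uptake_diet_errors(self):
        model = _single_chain_model()
        with pytest.raises(ZeroDivisionError):
            cce_experiment(model, ExchangeBounds({"EX_glc_e": 0.0}),
                           ["DM_fa"], fraction=1.0)

    def test_duality_holds_on_synthetic(self, synthetic_model, synthetic_diet):
        drains = sorted(r.id for r in synthetic_model.reactions
                        if r.id.startswith("DM_fa"))
        result = cce_experiment(synthetic_model, synthetic_diet, drains)
        for vals in result.per_fatty_acid.values():
            assert vals["printed"] * vals["efficiency"] == pytest.approx(
                10000.0, rel=1e-9)

    def test_doubled_glucose_follows_exact_ratio_identity(
            self, synthetic_model, synthetic_diet):
        """efficiency ratio = drain ratio / carbon-in ratio, so efficiency
        decreases exactly when the drain rises less than total dietary
        carbon.  (On this network the freed acetyl-CoA surplus makes every
        drain rise more, so efficiency increases.)"""
        drains = sorted(r.id for r in synthetic_model.reactions
                        if r.id.startswith("DM_fa"))
        doubled = scale_uptake(synthetic_diet, ["EX_glc_e"], 2.0)
        ref = cce_experiment(synthetic_model, synthetic_diet, drains)
        dbl = cce_experiment(synthetic_model, doubled, drains,
                             diet_label="doubled_glucose")

        def carbon_in(bounds):
            total = 0.0
            for ex, rate in bounds.bounds.items():
                met = next(iter(synthetic_model.reaction(ex).stoichiometry))
                total += rate * carbon_count(
                    synthetic_model.metabolite(met).formula)
            return total

        cin_ratio = carbon_in(doubled) / carbon_in(synthetic_diet)
        assert 1.0 < cin_ratio < 2.0  # only glucose doubled

        from larvaflux.diet import apply_diet
        from larvaflux.fluxopt import fva

        ref_fva = fva(apply_diet(synthetic_model, synthetic_diet), 0.9, drains)
        dbl_fva = fva(apply_diet(synthetic_model, doubled), 0.9, drains)
        for drain in drains:
            e0 = ref.per_fatty_acid[drain]["efficiency"]
            e1 = dbl.per_fatty_acid[drain]["efficiency"]
            drain_ratio = dbl_fva.maximum[drain] / ref_fva.maximum[drain]
            assert e1 / e0 == pytest.approx(drain_ratio / cin_ratio, rel=1e-6)
            assert (e1 < e0) == (drain_ratio < cin_ratio)

    def test_csv_output(self, synthetic_model, synthetic_diet, tmp_path):
        result = cce_experiment(synthetic_model, synthetic_diet,
                                ["DM_fa12_0"])
        result.to_csv(tmp_path / "cce.csv")
        lines = (tmp_path / "cce.csv").read_text().strip().splitlines()
        assert lines[0].startswith("fatty_acid_drain")
        assert len(lines) == 2
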