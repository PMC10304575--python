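import pytest

from larvaflux.model import MetabolicModel, Metabolite, Reaction
from larvaflux.synthetic import (
    SyntheticNetworkParams,
    generate_network,
    reference_diet,
)


@pytest.fixture(scope="session")
def default_params():
    return SyntheticNetworkParams(seed=0)


@pytest.fixture(scope="session")
def synthetic_model(default_params):
    return generate_network(default_params)


@pytest.fixture(scope="session")
def synthetic_diet(default_params):
    return reference_diet(default_params)


@pytest.fixture
def linear_chain_model():
    """EX_A -> (A) -> R1 -> (B) -> R2 -> (C) -> EX_C, all open."""
    return MetabolicModel(
        id="chain",
        metabolites=[
            Metabolite(id="A", compartment="c", formula="C6H12O6"),
            Metabolite(id="B", compartment="c", formula="C6H12O6"),
            Metabolite(id="C", compartment="c", formula="C6H12O6"),
        ],
        reactions=[
            Reaction(id="EX_A", stoichiometry={"A": -1.0},
                     lower_bound=-10.0, upper_bound=0.0),
            Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="R2", stoichiometry={"B": -1.0, "C": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="EX_C", stoichiometry={"C": -1.0},
                     lower_bound=0.0, upper_bound=1000.0),
        ],
        compartments={"c": "cytosol"},
        objective="EX_C",
    )


@pytest.fixture
def qc_fixture_model():
    """Hand-countable QC fixture.

    Metabolites: A, B, C, D (D only ever produced -> dead end).
    Reactions: EX_A, R1: A->B, R2: B->C, EX_C, R3: B->D (unbalanced in O,
    blocked by the dead end).  Hand counts: 1/4 dead-end metabolites (25%),
    1/5 blocked (20%), 3/5 unbalanced (60%: both exchanges plus R3),
    2/5 exchanges (40%).
    """
    return MetabolicModel(
        id="qc_fixture",
        metabolites=[
            Metabolite(id="A", compartment="c", formula="C6H12O6"),
            Metabolite(id="B", compartment="c", formula="C6H12O6"),
            Metabolite(id="C", compartment="c", formula="C6H12O6"),
            Metabolite(id="D", compartment="c", formula="C6H12O7"),
        ],
        reactions=[
            Reaction(id="EX_A", stoichiometry={"A": -1.0},
                     lower_bound=-5.0, upper_bound=0.0),
            Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="R2", stoichiometry={"B": -1.0, "C": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="EX_C", stoichiometry={"C": -1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="R3", stoichiometry={"B": -1.0, "D": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
        ],
        compartments={"c": "cytosol"},
        objective="EX_C",
    )
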