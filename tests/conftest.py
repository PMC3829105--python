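import pytest

from fluxrecon.model import MetabolicModel, Metabolite, Reaction
from fluxrecon.synth import ToyModelSpec, toy_model


@pytest.fixture(scope="session")
def toy():
    """Default toy network (GAM 85, NGAM 3.96, P:O 1.33)."""
    return toy_model()


@pytest.fixture(scope="session")
def toy_bare():
    """Toy network with maintenance zeroed (closed-form yield checks)."""
    return toy_model(ToyModelSpec(gam=0.0, ngam=0.0))


@pytest.fixture(scope="session")
def toy_loop():
    """Toy network with the gluconate/Entner-Doudoroff branch enabled."""
    return toy_model(ToyModelSpec(include_gluconate_loop=True))


@pytest.fixture
def chain_model():
    """Linear chain A_ext -> A -> B -> biomass; 10 B per unit biomass flux."""
    return MetabolicModel(
        reactions=[
            Reaction("EX_A", {"A_ext": -1.0}, -10.0, 0.0),
            Reaction("T_A", {"A_ext": -1.0, "A": 1.0}, 0.0, 1000.0),
            Reaction("CONV", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"B": -10.0}, 0.0, 1000.0),
        ],
        metabolites=[Metabolite(m) for m in ("A_ext", "A", "B")],
        objective_reaction="BIOMASS",
    )


@pytest.fixture
def parallel_model():
    """Two equivalent routes able to carry the full flux, plus a dead branch."""
    return MetabolicModel(
        reactions=[
            Reaction("EX_A", {"A_ext": -1.0}, -10.0, 0.0),
            Reaction("T1", {"A_ext": -1.0, "A": 1.0}, 0.0, 1000.0),
            Reaction("T2", {"A_ext": -1.0, "A": 1.0}, 0.0, 1000.0),
            Reaction("DM_A", {"A": -1.0}, 0.0, 1000.0),
            Reaction("DEAD", {"C": -1.0, "D": 1.0}, 0.0, 1000.0),
        ],
        metabolites=[Metabolite(m) for m in ("A_ext", "A", "C", "D")],
        objective_reaction="DM_A",
    )
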