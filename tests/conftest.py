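import pytest

from gemflux import toys
from gemflux.model import MetabolicModel, Metabolite, Reaction


@pytest.fixture(scope="session")
def toy_a():
    return toys.make_fixture("TOY-A")


@pytest.fixture(scope="session")
def toy_b():
    return toys.make_fixture("TOY-B")


@pytest.fixture(scope="session")
def toy_c():
    return toys.make_fixture("TOY-C")


@pytest.fixture(scope="session")
def toy_d():
    return toys.make_fixture("TOY-D")


@pytest.fixture(scope="session")
def toy_o2():
    return toys.make_fixture("TOY-O2")


def build_model(model_id, reactions, objective="BIOMASS"):
    """Assemble a model from reactions; compartment from the _e/_c id suffix."""
    met_ids = []
    for rxn in reactions:
        for mid in rxn.stoichiometry:
            if mid not in met_ids:
                met_ids.append(mid)
    mets = [
        Metabolite(id=m, name=m, compartment="e" if m.endswith("_e") else "c")
        for m in met_ids
    ]
    return MetabolicModel(
        id=model_id, metabolites=mets, reactions=reactions,
        objective_reaction_id=objective,
    )


@pytest.fixture
def p_consumer():
    """Tiny organism that grows by consuming extracellular P (for the
    interaction-matrix tests; TOY-D is the matching producer)."""
    return build_model(
        "P_EATER",
        [
            Reaction("EX_P", {"P_e": -1.0}, -10.0, 1000.0),
            Reaction("T_P", {"P_e": -1.0, "P_c": 1.0}, 0.0, 1000.0),
            Reaction("R1", {"P_c": -1.0, "B_c": 1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"B_c": -1.0}, 0.0, 1000.0),
        ],
    )
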