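import pytest

from orthoflux import (
    GPRExpression,
    MetabolicModel,
    Reaction,
    SyntheticSpec,
    generate_source_model,
)
from orthoflux.gpr import parse_gpr


@pytest.fixture(scope="session")
def synth():
    """Default-scale synthetic reconstruction with ground truth (seed 1)."""
    spec = SyntheticSpec(seed=1)
    model, truth = generate_source_model(spec)
    return spec, model, truth


@pytest.fixture(scope="session")
def small_synth():
    """A ~30-reaction reconstruction for exhaustive oracles."""
    spec = SyntheticSpec(
        n_pathways=3, chain_length=3, n_essential=2, n_decoys=4, n_blocked=1, seed=7
    )
    model, truth = generate_source_model(spec)
    return spec, model, truth


def make_chain_model(uptake: float = 10.0, internal_cap: float | None = None):
    """EX_a (uptake) -> transport -> a->b -> biomass consuming b."""
    m = MetabolicModel(id="chain", compartments=("c", "e"))
    m.add_reaction(Reaction("EX_a", {"a[e]": -1.0}, -uptake, 1000.0))
    m.add_reaction(Reaction("T_a", {"a[e]": -1.0, "a[c]": 1.0}, -1000.0, 1000.0))
    cap = internal_cap if internal_cap is not None else 1000.0
    m.add_reaction(Reaction("AtoB", {"a[c]": -1.0, "b[c]": 1.0}, 0.0, cap,
                            gpr=parse_gpr("g1")))
    m.add_reaction(Reaction("BIO", {"b[c]": -1.0}, 0.0, 1000.0))
    m.objective_id = "BIO"
    return m


@pytest.fixture
def chain_model():
    return make_chain_model()
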