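import pytest

from algaegem import MetabolicModel, Metabolite, Reaction
from algaegem.synthetic import ToySpec, make_fig2_toy, make_random_model


@pytest.fixture
def chain_model():
    """5-step linear chain, uptake 10, biomass yield 0.5 -> growth 5."""
    model, records = make_random_model(ToySpec(n_reactions=5, seed=1))
    return model, records


@pytest.fixture
def fig2_toy():
    return make_fig2_toy()


@pytest.fixture
def segment_model():
    """One free flux on [0, 10]: a 1-D sampling polytope."""
    model = MetabolicModel(id="segment")
    model.add_metabolite(Metabolite("x", compartment="c"))
    model.add_reaction(Reaction("v", {"x": 1.0}, lb=0.0, ub=10.0))
    model.add_reaction(Reaction("sink", {"x": -1.0}, lb=0.0, ub=10.0))
    return model


@pytest.fixture
def media_model(chain_model):
    from algaegem import attach_media

    model, _ = chain_model
    return attach_media(model)
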