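import pytest

from oxflux import MetabolicModel, Metabolite, Reaction, ToyModelSpec, build_toy_model


@pytest.fixture
def toy_model() -> MetabolicModel:
    """Minimal toy network: glucose cap 1, oxygen cap 6 (fully aerobic)."""
    return build_toy_model(ToyModelSpec(glucose_uptake_cap=1.0, oxygen_uptake_cap=6.0))


@pytest.fixture
def succinate_model() -> MetabolicModel:
    return build_toy_model(
        ToyModelSpec(variant="succinate", glucose_uptake_cap=1.0, oxygen_uptake_cap=6.0)
    )


@pytest.fixture
def two_species_model() -> MetabolicModel:
    """Tiny hand-built model: boundary species A feeds internal species B."""
    return MetabolicModel(
        metabolites=[
            Metabolite("A", compartment="e", is_boundary=True),
            Metabolite("B", compartment="c"),
        ],
        reactions=[
            Reaction("R_in", {"A": -1, "B": 1}, 0, 10),
            Reaction("R_out", {"B": -1}, 0, 1000),
        ],
        objective={"R_out": 1.0},
    )
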