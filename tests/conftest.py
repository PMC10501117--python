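import pytest

from opkin import (
    MechanismConfig,
    NetworkSpec,
    ReactionSpec,
    SpeciesSpec,
)


@pytest.fixture
def cfg():
    return MechanismConfig()


@pytest.fixture
def first_order_net():
    """A -> B, k = 0.01 s-1 (non-stiff toy with a closed form)."""
    return NetworkSpec(
        species=[SpeciesSpec("A", initial_conc=1e-6), SpeciesSpec("B")],
        reactions=[ReactionSpec("r1", {"A": 1}, {"B": 1}, 0.01)],
        name="first_order",
    )


@pytest.fixture
def rooh_homolysis_net():
    """ROOH -> OH + RO at the organic-peroxide homolysis rate 0.0015 s-1."""
    return NetworkSpec(
        species=[SpeciesSpec("ROOH", initial_conc=1e-6), SpeciesSpec("OH"),
                 SpeciesSpec("RO")],
        reactions=[ReactionSpec("hom", {"ROOH": 1}, {"OH": 1, "RO": 1},
                                0.0015, channel="OH")],
        name="rooh",
    )


@pytest.fixture
def three_species_toy():
    """A -> B -> C chain plus a bimolecular branch (non-stiff)."""
    return NetworkSpec(
        species=[
            SpeciesSpec("A", initial_conc=2e-6),
            SpeciesSpec("B", initial_conc=1e-7),
            SpeciesSpec("C"),
        ],
        reactions=[
            ReactionSpec("r1", {"A": 1}, {"B": 1}, 0.02),
            ReactionSpec("r2", {"B": 1}, {"C": 1}, 0.005),
            ReactionSpec("r3", {"A": 1, "B": 1}, {"C": 1}, 1e3),
        ],
        name="toy3",
    )
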