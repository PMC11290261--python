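import numpy as np
import pytest

from mgpflux.gem import MetabolicModel, Metabolite, Reaction
from mgpflux.simulate import CohortSimSpec, PlantedEffect, ToyGEMSpec, generate_toy_gem


def make_chain_model(ab_upper=1000.0):
    """Boundary -> A -> B -> boundary, with a GPR only on the middle step."""
    mets = {
        "A_c": Metabolite("A_c", compartment="c"),
        "B_c": Metabolite("B_c", compartment="c"),
    }
    rxns = {
        "R_in": Reaction("R_in", {"A_c": 1.0}, 0.0, 1000.0, pathway="boundary"),
        "R_ab": Reaction("R_ab", {"A_c": -1.0, "B_c": 1.0}, 0.0, ab_upper,
                         gpr="GAB", pathway="Glycolysis"),
        "R_out": Reaction("R_out", {"B_c": -1.0}, 0.0, 1000.0, pathway="boundary"),
    }
    return MetabolicModel(id="chain", metabolites=mets, reactions=rxns,
                          genes=("GAB",))


@pytest.fixture
def chain_model():
    return make_chain_model()


@pytest.fixture
def capped_chain_model():
    return make_chain_model(ab_upper=2.0)


@pytest.fixture
def toy_model():
    return generate_toy_gem(ToyGEMSpec(n_pathways=3, reactions_per_pathway=4, seed=7))


@pytest.fixture
def planted_cohort(toy_model):
    from mgpflux.simulate import simulate_cohort

    spec = CohortSimSpec(
        n_samples=20,
        planted={"G1_1": PlantedEffect(pathway="pathway_1", n_mutant=6,
                                       expression_multiplier=5.0)},
        missingness=0.1,
        seed=11,
    )
    return simulate_cohort(toy_model, spec)


def random_toy_model(rng):
    """A random small model (<=20 reactions) via seeded generator specs."""
    spec = ToyGEMSpec(
        n_pathways=int(rng.integers(2, 4)),
        reactions_per_pathway=int(rng.integers(2, 4)),
        n_shared_metabolites=int(rng.integers(1, 3)),
        isozyme_fraction=float(rng.uniform(0, 0.5)),
        seed=int(rng.integers(0, 2**31)),
    )
    return generate_toy_gem(spec)
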