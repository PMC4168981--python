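import sys
from pathlib import Path

import pytest
from cobra import Metabolite, Model, Reaction

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles importable

from oncoflux.context_models import apply_medium, toy_medium
from oncoflux.flux_sampling import achr_sample
from oncoflux.synthetic_data import (
    SyntheticScenario,
    generate_compound_library,
    generate_toy_model,
)


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(seed=7)


@pytest.fixture(scope="session")
def toy_model(scenario):
    """The packaged toy network under its growth medium."""
    return apply_medium(generate_toy_model(scenario), toy_medium())


@pytest.fixture(scope="session")
def compound_library(scenario):
    return generate_compound_library(scenario)


@pytest.fixture(scope="session")
def toy_samples(toy_model):
    """A modest reference sample of the toy model's 90%-optimal space."""
    return achr_sample(toy_model, n_points=800, thinning=25, seed=101)


@pytest.fixture(scope="session")
def sdh_deficient_samples(toy_model):
    from oncoflux.fss_lof import build_deficient_model

    verdict = build_deficient_model(toy_model, "g_sdh")
    assert verdict.feasible
    return achr_sample(verdict.model, n_points=800, thinning=25, seed=102)


def chain_model():
    """E_in ->(<=5) A ->(<=3) B -> biomass; optimum is min of the caps."""
    model = Model("chain")
    a = Metabolite("a_c", compartment="c")
    b = Metabolite("b_c", compartment="c")
    ex = Reaction("EX_a"); ex.add_metabolites({a: 1}); ex.bounds = (0, 5)
    r1 = Reaction("R1"); r1.add_metabolites({a: -1, b: 1}); r1.bounds = (0, 3)
    bm = Reaction("BM"); bm.add_metabolites({b: -1}); bm.bounds = (0, 1000)
    model.add_reactions([ex, r1, bm])
    model.objective = "BM"
    return model


@pytest.fixture()
def linear_chain():
    return chain_model()


BOX_RANGES = ((0.0, 4.0), (0.5, 2.5), (1.0, 3.0))


def box_model(ranges=BOX_RANGES):
    """Uncoupled flux 'box': one irreversible pass-through chain per interval.

    All bounds are non-negative so each reaction maps to a single solver
    variable and the sampled marginals are exactly uniform.
    """
    model = Model("box")
    rxns = []
    for i, (lo, hi) in enumerate(ranges):
        met = Metabolite(f"x{i}_c", compartment="c")
        r_in = Reaction(f"IN{i}"); r_in.add_metabolites({met: 1}); r_in.bounds = (lo, hi)
        r_out = Reaction(f"OUT{i}"); r_out.add_metabolites({met: -1}); r_out.bounds = (0.0, 1000.0)
        rxns += [r_in, r_out]
    model.add_reactions(rxns)
    model.objective = "OUT0"
    return model


@pytest.fixture()
def flux_box():
    return box_model()
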