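import numpy as np
import pytest

from dielgem import (
    FixtureSpec,
    make_toy_plant_gem,
    run_pipeline,
    sample_fluxes,
    solve_fba,
)


@pytest.fixture(scope="session")
def toy():
    """(non-diel toy model, matched pipeline config)."""
    return make_toy_plant_gem()


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_config(toy):
    return toy[1]


@pytest.fixture(scope="session")
def diel(toy):
    model, config = toy
    return run_pipeline(model, config)


@pytest.fixture(scope="session")
def diel_model(diel):
    return diel[0]


@pytest.fixture(scope="session")
def phase_map(diel):
    return diel[1]


@pytest.fixture(scope="session")
def diel_flux(diel_model):
    return solve_fba(diel_model)


@pytest.fixture(scope="session")
def diel_samples(diel_model):
    return sample_fluxes(diel_model, 100, seed=11, thinning=25)


@pytest.fixture(scope="session")
def two_tissue():
    return make_toy_plant_gem(FixtureSpec(include_two_tissues=True))


@pytest.fixture(scope="session")
def two_tissue_diel(two_tissue):
    model, config = two_tissue
    return run_pipeline(model, config)


def stoichiometric_residuals(model, flux_vector_by_rid):
    """Max |S·v| over metabolites, for mass-balance assertions."""
    balance = {m.id: 0.0 for m in model.metabolites}
    for rxn in model.reactions:
        v = flux_vector_by_rid[rxn.id]
        for mid, coef in rxn.stoichiometry.items():
            balance[mid] += coef * v
    return max(abs(b) for b in balance.values())
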