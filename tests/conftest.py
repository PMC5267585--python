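import numpy as np
import pytest

from peatlucas import (
    EventSchedule,
    LandscapeConfig,
    ModelConfig,
    SoilParams,
    load_species_params,
    run_historic,
    spinup_all,
)
from peatlucas.synthetic import generate_reference_scenario


@pytest.fixture(scope="session")
def species_params():
    return load_species_params()


@pytest.fixture(scope="session")
def soil():
    return SoilParams()


@pytest.fixture(scope="session")
def curves(species_params):
    return spinup_all(species_params)


@pytest.fixture(scope="session")
def reference_scenario(species_params, soil, curves):
    """1985 initial landscape, event schedule and perimeter masks (seed 1)."""
    cfg = LandscapeConfig(seed=1)
    return generate_reference_scenario(
        cfg, species_params=species_params, soil=soil, curves=curves
    )


@pytest.fixture(scope="session")
def reference_run(reference_scenario, species_params, soil):
    """Full 30-year historic run on the reference synthetic landscape."""
    land, schedule, masks = reference_scenario
    model = ModelConfig(species_params=species_params, soil=soil)
    ledger, final = run_historic(land, schedule, model, seed=1)
    return ledger, final


@pytest.fixture(scope="session")
def undisturbed_run(reference_scenario, species_params, soil):
    """Same landscape, empty schedule: growth and respiration only."""
    land, _schedule, _masks = reference_scenario
    model = ModelConfig(species_params=species_params, soil=soil)
    ledger, final = run_historic(land, EventSchedule(), model, seed=1)
    return ledger, final


@pytest.fixture
def rng():
    return np.random.default_rng(42)
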