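import pytest

from chimeradx.discovery import iterate_discovery
from chimeradx.simulate import ScenarioConfig, generate_scenario
from chimeradx.substitution import lg_model, poisson_model


@pytest.fixture(scope="session")
def poisson():
    return poisson_model()


@pytest.fixture(scope="session")
def lg():
    return lg_model()


@pytest.fixture(scope="session")
def chimera_scenario():
    """One seeded chimera scenario shared across the suite."""
    return generate_scenario(ScenarioConfig(seed=11, scenario_kind="chimera"))


@pytest.fixture(scope="session")
def chimera_discovery(chimera_scenario):
    """Converged discovery state on the shared chimera scenario."""
    scen = chimera_scenario
    return iterate_discovery(
        scen.database, scen.seed_alignment_A, scen.seed_alignment_B, seed=11
    )
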