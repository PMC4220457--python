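import pytest
from hypothesis import settings

from ecoflux import SyntheticConfig, run_study

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_study():
    """One full pipeline run on the default 32-site design (shared: read-only)."""
    return run_study(seed=20260919)


@pytest.fixture(scope="session")
def alt_study():
    """Same realisation solved under the no-animal-omnivory diet variant."""
    return run_study(seed=20260919, diet_model="no_animal_omnivory")


@pytest.fixture
def small_config():
    """A cut-down design for fast generator tests."""
    return SyntheticConfig(
        replicates_per_system_per_landscape=1,
        species_pool_size={"predator": 20, "omnivore": 20, "detritivore": 20, "herbivore": 20},
        base_density_per_m2={"predator": 8.0, "omnivore": 8.0, "detritivore": 10.0, "herbivore": 6.0},
    )
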