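import pytest
from hypothesis import HealthCheck, settings

from ckrna.pipeline import build_index, classify_origin
from ckrna.simulate import SimulationConfig, simulate_world

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: full fungal load, reduced host background."""
    return SimulationConfig(seed=11, host_genome_bp=120_000, background_reads_per_library=50_000)


@pytest.fixture(scope="session")
def small_world(small_config):
    return simulate_world(small_config)


@pytest.fixture(scope="session")
def small_indexes(small_world):
    return build_index(small_world.host), build_index(small_world.fungus)


@pytest.fixture(scope="session")
def small_classifications(small_world, small_indexes):
    host_index, fungal_index = small_indexes
    return {
        lib.sample_id: classify_origin(lib, host_index, fungal_index)
        for lib in small_world.libraries
    }
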