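import pytest
from hypothesis import settings

from bmirnet.synthetic import SimConfig, gen_genome

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def genome_truth(sim_config):
    return gen_genome(sim_config)
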