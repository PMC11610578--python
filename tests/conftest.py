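import pytest

from drrkit import Config, SimConfig, simulate_reference_pair


@pytest.fixture
def cfg():
    return Config()


@pytest.fixture(scope="session")
def small_pair():
    """One deterministic small template/query pair used across modules."""
    return simulate_reference_pair(SimConfig(seed=7))
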