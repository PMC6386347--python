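import pytest

from bioniceye import NetworkConfig, build_network


@pytest.fixture(scope="session")
def default_config():
    return NetworkConfig()


@pytest.fixture(scope="session")
def default_net(default_config):
    return build_network(default_config)
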