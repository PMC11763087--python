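import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from traumascore.config import default_config


@pytest.fixture(scope="session")
def tables_weights():
    return default_config()


@pytest.fixture(scope="session")
def tables(tables_weights):
    return tables_weights[0]


@pytest.fixture(scope="session")
def weights(tables_weights):
    return tables_weights[1]
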