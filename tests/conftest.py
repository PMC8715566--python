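import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

from icfkit import Model, default_registry, fixtures


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def empty_model():
    return Model()


@pytest.fixture(scope="module")
def all_fixtures():
    return fixtures()
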