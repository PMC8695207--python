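import pytest

from herblike import (
    default_rules,
    generate_library,
    herbicide_like_spec,
    published_reference,
    worked_fixture,
)


@pytest.fixture(scope="session")
def published_model():
    return published_reference()


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def worked_cases():
    return worked_fixture()


@pytest.fixture(scope="session")
def herbicide_library_500():
    return generate_library(herbicide_like_spec(n=500, seed=42))
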