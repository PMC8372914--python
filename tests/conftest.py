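import pytest

from ubtcea import PathwayPolicies, generate_reference_fixture


@pytest.fixture(scope="session")
def ref():
    """The packaged reference parameter registry (inputs + constants)."""
    return generate_reference_fixture()


@pytest.fixture(scope="session")
def policies():
    return PathwayPolicies()
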