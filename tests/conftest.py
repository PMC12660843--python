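import pytest

from phabkit.numbering import get_reference, number_chain


@pytest.fixture(scope="session")
def heavy_reference():
    return get_reference("H", "kabat")


@pytest.fixture(scope="session")
def light_reference():
    return get_reference("L", "kabat")


@pytest.fixture(scope="session")
def heavy_chain(heavy_reference):
    return number_chain(heavy_reference.sequence, "H", "kabat")


@pytest.fixture(scope="session")
def light_chain(light_reference):
    return number_chain(light_reference.sequence, "L", "kabat")
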