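import pytest

from hmwgs import (
    load_fixtures,
    packaged_mobility,
    packaged_pairing,
    packaged_reference,
)


@pytest.fixture(scope="session")
def table():
    return packaged_reference()


@pytest.fixture(scope="session")
def pairing():
    return packaged_pairing()


@pytest.fixture(scope="session")
def mobility():
    return packaged_mobility()


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()
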