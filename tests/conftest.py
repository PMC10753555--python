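import pytest

from thermoforge import fixtures


@pytest.fixture(scope="session")
def run1():
    """The one fully published bomb-combustion run."""
    return fixtures.load_combustion_runs()[0]


@pytest.fixture(scope="session")
def fusion_records():
    return fixtures.load_fusion_records()


@pytest.fixture(scope="session")
def tga_table():
    return fixtures.load_tga_table()


@pytest.fixture(scope="session")
def benson():
    return fixtures.load_benson_table()


@pytest.fixture(scope="session")
def crystal_descriptors():
    return fixtures.load_crystal_descriptors()


@pytest.fixture(scope="session")
def chain_config():
    return fixtures.load_chain_config()
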