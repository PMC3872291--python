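import pytest

from smybpc import (
    default_mass_model,
    fdb_preset,
    generate_fixture,
    load_architecture,
    load_catalog,
    mw_groups,
    soleus_preset,
)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def architecture():
    return load_architecture()


@pytest.fixture(scope="session")
def model(catalog):
    return default_mass_model(catalog)


@pytest.fixture(scope="session")
def groups(catalog):
    return mw_groups(catalog)


@pytest.fixture(scope="session")
def soleus_fixture():
    return generate_fixture(soleus_preset())


@pytest.fixture(scope="session")
def fdb_fixture():
    return generate_fixture(fdb_preset())
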