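import pytest

import parsimech as pm


@pytest.fixture(scope="session")
def default_config():
    return pm.EnumerationConfig()


@pytest.fixture(scope="session")
def aldol_case():
    return pm.get_case_study("aldol")


@pytest.fixture(scope="session")
def aldol_data():
    """Seeded noisy aldol dataset shared across tests."""
    return pm.generate_aldol(seed=42)


@pytest.fixture(scope="session")
def fructose_case():
    return pm.get_case_study("fructose")


@pytest.fixture(scope="session")
def fructose_data():
    return pm.generate_fructose(seed=42)
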