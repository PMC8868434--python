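import pytest

from lipidqi import reference_profiles


@pytest.fixture(scope="session")
def ano_rho():
    return reference_profiles()


@pytest.fixture(scope="session")
def ano(ano_rho):
    return ano_rho[0]


@pytest.fixture(scope="session")
def rho(ano_rho):
    return ano_rho[1]
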