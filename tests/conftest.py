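import pytest

from lutebg import (
    AttenuationTable,
    beta_pdf,
    default_decay_scheme,
    reference_absorption_probabilities,
)


@pytest.fixture(scope="session")
def scheme():
    return default_decay_scheme()


@pytest.fixture(scope="session")
def attenuation():
    return AttenuationTable.lyso()


@pytest.fixture(scope="session")
def ref_absprobs():
    return reference_absorption_probabilities()


@pytest.fixture(scope="session")
def beta(scheme):
    return beta_pdf(scheme)
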