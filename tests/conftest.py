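import pytest
from hypothesis import settings

import floralquant as fq

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def model():
    return fq.default_model()


@pytest.fixture(scope="session")
def contributions(model):
    return fq.derive_contributions(model)


@pytest.fixture(scope="session")
def reference():
    from floralquant.reference import reference_tables

    return reference_tables()
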