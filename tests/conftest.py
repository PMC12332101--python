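import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

import thermodev as td


@pytest.fixture(scope="session")
def remus_data():
    return td.telenomus_remus_development()


@pytest.fixture(scope="session")
def remus_params():
    return td.reference_parameters("telenomus_remus")


@pytest.fixture(scope="session")
def foersteri_params():
    return td.reference_parameters("trichogramma_foersteri")


@pytest.fixture(scope="session")
def all_reference_params(remus_params, foersteri_params):
    return {"telenomus_remus": remus_params,
            "trichogramma_foersteri": foersteri_params}
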