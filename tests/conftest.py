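import numpy as np
import pytest
from hypothesis import settings

from hor5s.repeat_model import default_reference, default_unit_library

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture(scope="session")
def library():
    return default_unit_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
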