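import numpy as np
import pytest

from popfam import SCENARIOS, simulate_null_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


@pytest.fixture
def null_dataset(rng):
    return simulate_null_dataset(0.2, 100, 100, rng)


@pytest.fixture(params=list(SCENARIOS))
def scenario(request):
    return request.param
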