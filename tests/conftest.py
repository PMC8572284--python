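import warnings

import numpy as np
import pytest

from raschval.pcm import estimate_items, estimate_persons
from raschval.simulate import SimulationConfig, evenly_spread_items, simulate


@pytest.fixture(scope="session")
def pcm_fit_1000():
    """One shared clean PCM fit: 10 five-category items, n=1000."""
    cfg = SimulationConfig(n_persons=1000, items=evenly_spread_items(10), seed=42)
    data, truth = simulate(cfg)
    items = estimate_items(data)
    persons = estimate_persons(data, items)
    return data, truth, items, persons


@pytest.fixture()
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
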