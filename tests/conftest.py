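import numpy as np
import pytest

from conbarrel.assembly import compose
from conbarrel.topology import catalog, get_preset


@pytest.fixture(scope="session")
def all_presets():
    return catalog()


@pytest.fixture(scope="session")
def composed():
    """Compose-on-demand cache shared across the session."""
    cache = {}

    def _get(name):
        if name not in cache:
            cache[name] = compose(get_preset(name))
        return cache[name]

    return _get


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
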