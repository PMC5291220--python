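import numpy as np
import pytest

import tempomem as tm


@pytest.fixture(scope="session")
def logistic_series():
    """Chaotic logistic orbit at the study length (2e4 after 4000 transient)."""
    return tm.generate("logistic", seed=1)


@pytest.fixture(scope="session")
def henon_series():
    return tm.generate("henon", seed=1)


@pytest.fixture(scope="session")
def period3_network():
    """Temporal network of a noise-free logistic orbit in the period-3 window."""
    orbit = tm.gen_logistic(3.835, n=10_000, n_transient=4000, seed=1)
    gt, part = tm.series_to_network(orbit, embed=(2, 1), per_dim=(900, 900))
    return gt, part


def random_symbols(rng, n=None, k=None):
    """A random symbol sequence for oracle comparisons."""
    n = n or int(rng.integers(20, 400))
    k = k or int(rng.integers(2, 8))
    return rng.integers(0, k, n)
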