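import numpy as np
import pytest

from nomas.core import Instance
from nomas.simulate import null_model, random_graph


@pytest.fixture(scope="session")
def small_graph():
    """Connected Erdős–Rényi graph, n=25, mean degree ~4."""
    return random_graph(25, 4.0, seed=101)


@pytest.fixture(scope="session")
def null_ds(small_graph):
    """Background-only dataset (no planted signal) on the small graph."""
    return null_model(small_graph, m=40, background_rate=0.1, seed=202)


@pytest.fixture(scope="session")
def null_instance(null_ds):
    return Instance(null_ds.graph, null_ds.matrix, null_ds.survival)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
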