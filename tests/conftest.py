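import numpy as np
import pytest

from connectoml import netbuild, syncon


@pytest.fixture(scope="session")
def tiny_spec():
    return syncon.default_spec(
        n_patients=8,
        n_controls=8,
        n_rois=16,
        n_timepoints=60,
        n_modules=4,
        edge_effect=0.8,
        noise_sd=0.6,
        n_affected_edges=8,
        n_hubs=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return syncon.generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def random_connectivity():
    """A random positive connectivity matrix with distinct weights."""
    rng = np.random.default_rng(11)
    n = 20
    v = rng.uniform(0.01, 0.99, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return netbuild.ConnectivityMatrix(v)


def random_binary_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < p).astype(np.int8)
    A = np.triu(A, k=1)
    return A + A.T
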