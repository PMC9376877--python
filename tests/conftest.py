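import numpy as np
import pytest

from mxad.build import BinaryLayer, BinaryMultiplex, WeightedLayer, WeightedMultiplex


def random_symmetric(n, rng, scale=1.0):
    w = rng.uniform(-1, 1, size=(n, n)) * scale
    w = np.triu(w, 1)
    w = w + w.T
    return w


def random_weighted_multiplex(n, rng):
    return WeightedMultiplex(
        (
            WeightedLayer(random_symmetric(n, rng), "gray_matter"),
            WeightedLayer(random_symmetric(n, rng), "amyloid"),
        )
    )


def random_binary_multiplex(n, rng, density=0.3):
    """Two independent G(n, p) layers forced to a common edge count."""
    n_pairs = n * (n - 1) // 2
    n_edges = max(1, int(round(density * n_pairs)))
    layers = []
    for tag in ("gray_matter", "amyloid"):
        iu, ju = np.triu_indices(n, k=1)
        pick = rng.choice(n_pairs, size=n_edges, replace=False)
        a = np.zeros((n, n), dtype=int)
        a[iu[pick], ju[pick]] = 1
        a += a.T
        layers.append(BinaryLayer(a, tag))
    return BinaryMultiplex(tuple(layers))


def adjacency_from_edges(n, edges, tag="gray_matter"):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryLayer(a, tag)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_cohort_arrays(rng):
    """20 subjects x 6 regions with age/sex covariates."""
    n, r = 20, 6
    age = rng.normal(73, 6, n)
    sex = (rng.random(n) < 0.5).astype(float)
    values = rng.normal(0, 1, (n, r)) + 0.05 * age[:, None] + 0.3 * sex[:, None]
    return values, age, sex
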