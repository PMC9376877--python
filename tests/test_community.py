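import numpy as np
import networkx as nx
import pytest

from conftest import random_symmetric
from mxad.build import WeightedLayer, WeightedMultiplex
from mxad.community import (
    DEFAULT_GAMMAS,
    DEFAULT_OMEGAS,
    ModularityConfig,
    louvain_multilayer,
    modularity,
    persistence,
    supra_modularity_matrix,
    sweep_gamma_omega,
    variation_of_information,
)


def two_clique_layer(tag="gray_matter"):
    """Two 6-node cliques joined by a single bridge edge, unit weights."""
    n = 12
    w = np.zeros((n, n))
    for block in (range(6), range(6, 12)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    w[5, 6] = w[6, 5] = 1.0
    return WeightedLayer(w, tag)


@pytest.fixture
def two_clique_multiplex():
    return WeightedMultiplex((two_clique_layer("gray_matter"), two_clique_layer("amyloid")))


class TestModularity:
    def test_single_community_reduces_to_coupling_term(self, rng):
        mx = WeightedMultiplex(
            (
                WeightedLayer(np.abs(random_symmetric(8, rng)), "gray_matter"),
                WeightedLayer(np.abs(random_symmetric(8, rng)), "amyloid"),
            )
        )
        omega = 0.7
        cfg = ModularityConfig(gamma=1.0, omega=omega, weight_mode="raw")
        labels = np.zeros((2, 8), dtype=int)
        m1 = mx.layers[0].weights.sum() / 2
        m2 = mx.layers[1].weights.sum() / 2
        expected = omega * 8 / (m1 + m2 + omega * 8)
        assert modularity(mx, labels, cfg) == pytest.approx(expected, abs=1e-12)

    def test_decoupled_cliques_match_networkx_single_layer_oracle(self):
        layer = two_clique_layer()
        mx = WeightedMultiplex((layer, two_clique_layer("amyloid")))
        cfg = ModularityConfig(gamma=1.0, omega=0.0)
        labels = np.array([[0] * 6 + [1] * 6] * 2)
        G = nx.from_numpy_array(layer.weights)
        q_nx = nx.community.modularity(G, [set(range(6)), set(range(6, 12))], weight="weight")
        m = layer.weights.sum() / 2
        # shared normalization: each layer contributes 2m_l * Q_l / (2 mu)
        expected = 2 * (2 * m * q_nx) / (2 * (2 * m))
        assert modularity(mx, labels, cfg) == pytest.approx(expected, abs=1e-12)

    def test_louvain_dominates_random_partitions(self, rng, two_clique_multiplex):
        cfg = ModularityConfig(seed=5, n_restarts=20)
        part = louvain_multilayer(two_clique_multiplex, cfg)
        for _ in range(10):
            random_labels = rng.integers(0, 3, size=(2, 12))
            assert modularity(two_clique_multiplex, random_labels, cfg) <= part.Q + 1e-12

    def test_invariant_under_global_relabeling(self, two_clique_multiplex):
        cfg = ModularityConfig()
        labels = np.array([[0] * 6 + [1] * 6] * 2)
        relabeled = 7 - labels * 3  # 0 -> 7, 1 -> 4
        assert modularity(two_clique_multiplex, labels, cfg) == pytest.approx(
            modularity(two_clique_multiplex, relabeled, cfg), abs=1e-14
        )

    def test_zero_weight_layer_rejected(self):
        mx = WeightedMultiplex(
            (WeightedLayer(np.zeros((5, 5)), "gray_matter"),
             WeightedLayer(np.zeros((5, 5)), "amyloid"))
        )
        with pytest.raises(ValueError, match="zero total weight"):
            supra_modularity_matrix(mx, 1.0, 1.0)


class TestLouvain:
    def test_recovers_planted_cliques_with_full_persistence(self, two_clique_multiplex):
        part = louvain_multilayer(two_clique_multiplex, ModularityConfig(seed=1))
        assert part.n_communities == 2
        assert np.array_equal(part.labels[0], part.labels[1])
        assert part.persistence == 1.0
        # the partition splits exactly at the bridge
        assert len(set(part.labels[0][:6])) == 1
        assert len(set(part.labels[0][6:])) == 1
        assert part.labels[0][0] != part.labels[0][6]

    def test_same_seed_same_partition(self, two_clique_multiplex):
        a = louvain_multilayer(two_clique_multiplex, ModularityConfig(seed=9))
        b = louvain_multilayer(two_clique_multiplex, ModularityConfig(seed=9))
        assert np.array_equal(a.labels, b.labels)
        assert a.Q == b.Q

    def test_strong_coupling_forces_cross_layer_agreement(self, rng):
        # different structure per layer; omega = 10 must align replicas
        l1 = WeightedLayer(np.abs(random_symmetric(10, rng)), "gray_matter")
        l2 = WeightedLayer(np.abs(random_symmetric(10, rng)), "amyloid")
        mx = WeightedMultiplex((l1, l2))
        part = louvain_multilayer(mx, ModularityConfig(omega=10.0, seed=2, n_restarts=20))
        assert part.persistence == 1.0

    def test_coupling_pulls_layers_together_on_average(self, rng):
        """Persistence under omega=1 exceeds omega=0 for discordant layers."""
        diffs = []
        for s in range(10):
            local = np.random.default_rng(s)
            w1 = np.zeros((12, 12))
            w2 = np.zeros((12, 12))
            # layer 1: blocks {0-5}{6-11}; layer 2: blocks {0-2,6-8}{rest}
            b1 = [list(range(6)), list(range(6, 12))]
            b2 = [[0, 1, 2, 6, 7, 8], [3, 4, 5, 9, 10, 11]]
            for w, blocks in ((w1, b1), (w2, b2)):
                for block in blocks:
                    for i in block:
                        for j in block:
                            if i != j:
                                w[i, j] = 1.0
                noise = np.abs(local.normal(0, 0.05, (12, 12)))
                noise = np.triu(noise, 1) + np.triu(noise, 1).T
                w += noise
            w1 = np.clip(w1, 0, 1); np.fill_diagonal(w1, 0)
            w2 = np.clip(w2, 0, 1); np.fill_diagonal(w2, 0)
            mx = WeightedMultiplex((WeightedLayer(w1, "gray_matter"),
                                    WeightedLayer(w2, "amyloid")))
            p0 = louvain_multilayer(mx, ModularityConfig(omega=0.0, seed=s, n_restarts=20))
            p1 = louvain_multilayer(mx, ModularityConfig(omega=1.0, seed=s, n_restarts=20))
            diffs.append(p1.persistence - p0.persistence)
        assert np.mean(diffs) > 0


class TestPersistence:
    def test_identical_layer_labels_give_one(self):
        labels = np.array([[0, 0, 1, 1, 2], [0, 0, 1, 1, 2]])
        assert persistence(labels) == 1.0

    def test_fully_discordant_labels_give_zero(self):
        labels = np.array([[0, 0, 1, 1], [1, 1, 0, 0]])
        assert persistence(labels) == 0.0

    def test_half_agreement(self):
        labels = np.array([[0, 0, 1, 1], [0, 0, 2, 2]])
        assert persistence(labels) == 0.5


class TestVariationOfInformation:
    def test_identical_partitions_give_zero(self):
        a = np.array([0, 0, 1, 1, 2])
        assert variation_of_information(a, a) == 0.0

    def test_relabeling_invariance(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([5, 5, 9, 9, 1, 1])
        assert variation_of_information(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_contingency_entropy_oracle(self):
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 1, 2])
        # oracle: 2x2 contingency with 1 in each cell
        pij = np.full((2, 2), 0.25)
        h = lambda p: -(p[p > 0] * np.log(p[p > 0])).sum()
        vi_expected = (2 * h(pij.ravel()) - h(pij.sum(0)) - h(pij.sum(1))) / np.log(4)
        assert variation_of_information(a, b) == pytest.approx(vi_expected, abs=1e-12)
        assert vi_expected == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            variation_of_information([0, 1], [0, 1, 2])


@pytest.fixture(scope="module")
def sweep():
    mx = WeightedMultiplex((two_clique_layer("gray_matter"), two_clique_layer("amyloid")))
    return sweep_gamma_omega(mx, config=ModularityConfig(seed=3, n_restarts=10))


class TestGammaOmegaSweep:

    def test_grid_has_28_points_and_symmetric_vi(self, sweep):
        assert len(sweep.grid) == len(DEFAULT_GAMMAS) * len(DEFAULT_OMEGAS) == 28
        assert len(sweep.partitions) == 28
        assert sweep.vi_matrix.shape == (28, 28)
        assert np.allclose(sweep.vi_matrix, sweep.vi_matrix.T)
        assert np.all(np.diag(sweep.vi_matrix) == 0)
        assert np.all(sweep.vi_matrix >= 0)

    def test_community_count_non_decreasing_in_gamma(self):
        """Resolution behaviour: higher gamma yields no fewer communities."""
        counts = {g: [] for g in DEFAULT_GAMMAS}
        for seed in range(10):
            mx = WeightedMultiplex(
                (two_clique_layer("gray_matter"), two_clique_layer("amyloid"))
            )
            sw = sweep_gamma_omega(mx, config=ModularityConfig(seed=seed, n_restarts=10))
            for (g, _), k in zip(sw.grid, sw.n_communities):
                counts[g].append(k)
        means = [np.mean(counts[g]) for g in sorted(DEFAULT_GAMMAS)]
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))

    def test_selected_point_minimizes_mean_vi(self, sweep):
        mean_vi = sweep.vi_matrix.sum(axis=1) / (len(sweep.grid) - 1)
        assert sweep.selected == sweep.grid[int(np.argmin(mean_vi))]

    def test_empty_grid_rejected(self, two_clique_multiplex):
        with pytest.raises(ValueError):
            sweep_gamma_omega(two_clique_multiplex, gammas=(), omegas=DEFAULT_OMEGAS)
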