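import numpy as np
import pytest

from conftest import adjacency_from_edges, random_binary_multiplex, random_weighted_multiplex
from mxad.build import BinaryLayer, BinaryMultiplex, WeightedLayer, WeightedMultiplex
from mxad.metrics import (
    binary_metrics,
    degree_overlap,
    metrics_over_sweep,
    multiplex_clustering,
    multiplex_participation,
    overlapping_degree,
    overlapping_strength,
    sweep_to_frame,
)


# ---- independent brute-force oracles ---------------------------------------

def strength_oracle(mx, mode="raw"):
    n = mx.n_nodes
    s = np.zeros(n)
    for i in range(n):
        for layer in mx.layers:
            for j in range(n):
                w = layer.weights[i, j]
                if mode == "positive":
                    w = max(w, 0.0)
                elif mode == "absolute":
                    w = abs(w)
                s[i] += w
    return s


def degree_overlap_oracle(mx):
    a1, a2 = (l.adjacency for l in mx.layers)
    n = mx.n_nodes
    out = np.zeros(n, dtype=int)
    for i in range(n):
        nb1 = {j for j in range(n) if a1[i, j]}
        nb2 = {j for j in range(n) if a2[i, j]}
        out[i] = len(nb1 & nb2)
    return out


def participation_oracle(mx):
    a1, a2 = (l.adjacency for l in mx.layers)
    n = mx.n_nodes
    out = np.zeros(n)
    for i in range(n):
        k1, k2 = a1[i].sum(), a2[i].sum()
        o = k1 + k2
        if o == 0:
            continue
        out[i] = 2.0 * (1.0 - (k1 / o) ** 2 - (k2 / o) ** 2)
    return out


def clustering_oracle(mx):
    a1, a2 = (np.asarray(l.adjacency, float) for l in mx.layers)
    n = mx.n_nodes
    out = np.zeros(n)
    for i in range(n):
        num = 0.0
        for A, B in ((a1, a2), (a2, a1)):  # ordered layer pairs (alpha, beta)
            for j in range(n):
                for m in range(n):
                    if j != m and j != i and m != i:
                        num += (A[i, j] * B[j, m] * A[m, i]) ** (1.0 / 3.0)
        k1, k2 = a1[i].sum(), a2[i].sum()
        den = k1 * (k1 - 1) + k2 * (k2 - 1)
        out[i] = num / den if den > 0 else 0.0
    return out


# ---- tests -----------------------------------------------------------------

class TestOverlappingStrength:
    def test_all_zero_layers(self):
        z = WeightedLayer(np.zeros((4, 4)), "gray_matter")
        mx = WeightedMultiplex((z, WeightedLayer(np.zeros((4, 4)), "amyloid")))
        assert np.all(overlapping_strength(mx) == 0)

    def test_identical_layers_double_single_layer_strength(self, rng):
        mx = random_weighted_multiplex(8, rng)
        w = np.abs(mx.layers[0].weights)
        np.fill_diagonal(w, 0)
        both = WeightedMultiplex((WeightedLayer(w, "gray_matter"), WeightedLayer(w, "amyloid")))
        assert np.allclose(overlapping_strength(both), 2 * w.sum(axis=1), atol=1e-12)

    @pytest.mark.parametrize("mode", ["raw", "positive", "absolute"])
    def test_matches_double_loop_oracle(self, rng, mode):
        for _ in range(20):
            mx = random_weighted_multiplex(6, rng)
            got = overlapping_strength(mx, weight_mode=mode)
            assert np.allclose(got, strength_oracle(mx, mode), atol=1e-12)

    def test_binary_strength_equals_overlapping_degree(self, rng):
        mx = random_binary_multiplex(12, rng, density=0.3)
        as_weighted = WeightedMultiplex(
            tuple(WeightedLayer(np.asarray(l.adjacency, float), l.layer_tag) for l in mx.layers)
        )
        assert np.allclose(overlapping_strength(as_weighted), overlapping_degree(mx))


class TestDegreeOverlap:
    def test_identical_layers_give_layer_degree(self, rng):
        mx = random_binary_multiplex(10, rng)
        a = mx.layers[0]
        same = BinaryMultiplex((a, BinaryLayer(a.adjacency.copy(), "amyloid")))
        assert np.array_equal(degree_overlap(same), a.degrees)

    def test_edge_disjoint_layers_give_zero(self):
        l1 = adjacency_from_edges(5, [(0, 1), (2, 3)], "gray_matter")
        l2 = adjacency_from_edges(5, [(0, 2), (1, 4)], "amyloid")
        assert np.all(degree_overlap(BinaryMultiplex((l1, l2))) == 0)

    def test_matches_neighbor_set_oracle(self, rng):
        for _ in range(20):
            mx = random_binary_multiplex(8, rng, density=0.4)
            assert np.array_equal(degree_overlap(mx), degree_overlap_oracle(mx))


class TestParticipation:
    def test_equal_nonzero_degrees_give_one(self):
        l1 = adjacency_from_edges(6, [(0, 1), (0, 2), (0, 3)], "gray_matter")
        l2 = adjacency_from_edges(6, [(0, 2), (0, 4), (0, 5)], "amyloid")
        p = multiplex_participation(BinaryMultiplex((l1, l2)))
        assert p[0] == pytest.approx(1.0)

    def test_single_layer_degree_gives_zero(self):
        l1 = adjacency_from_edges(6, [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2)], "gray_matter")
        l2 = adjacency_from_edges(6, [(1, 2), (2, 3), (3, 4), (1, 3), (2, 4)], "amyloid")
        p = multiplex_participation(BinaryMultiplex((l1, l2)))
        assert p[0] == pytest.approx(0.0)  # node 0 isolated in layer 2

    def test_degree_ratio_one_to_three(self):
        l1 = adjacency_from_edges(8, [(0, 1), (2, 3), (2, 4), (2, 5)], "gray_matter")
        l2 = adjacency_from_edges(8, [(0, 2), (0, 3), (0, 4), (5, 6)], "amyloid")
        p = multiplex_participation(BinaryMultiplex((l1, l2)))
        # k1 = 1, k2 = 3: p = 2 * (1 - (1/16 + 9/16)) = 0.75
        assert p[0] == pytest.approx(0.75)

    def test_matches_direct_oracle(self, rng):
        for _ in range(20):
            mx = random_binary_multiplex(9, rng, density=0.35)
            assert np.allclose(multiplex_participation(mx), participation_oracle(mx), atol=1e-12)


class TestClustering:
    def test_triangle_free_layers_give_zero(self):
        # forests with a bipartite union: no triangle can close in any
        # layer combination, so every 2-triangle count is zero
        l1 = adjacency_from_edges(6, [(0, 3), (1, 4), (2, 5), (0, 4)], "gray_matter")
        l2 = adjacency_from_edges(6, [(1, 5), (2, 3), (0, 5), (1, 3)], "amyloid")
        assert np.all(multiplex_clustering(BinaryMultiplex((l1, l2))) == 0)

    def test_complete_three_node_layers_give_one(self):
        tri = [(0, 1), (0, 2), (1, 2)]
        l1 = adjacency_from_edges(3, tri, "gray_matter")
        l2 = adjacency_from_edges(3, tri, "amyloid")
        c = multiplex_clustering(BinaryMultiplex((l1, l2)))
        # per node: 4 ordered 2-triangles over (alpha, beta) pairs; 1-triads
        # (M-1) * sum_a k(k-1) = 2*1 + 2*1 = 4
        assert np.allclose(c, 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(20):
            mx = random_binary_multiplex(7, rng, density=0.45)
            assert np.allclose(multiplex_clustering(mx), clustering_oracle(mx), atol=1e-12)


class TestInvariants:
    def test_layer_permutation_symmetry(self, rng):
        for _ in range(10):
            mx = random_binary_multiplex(10, rng, density=0.3)
            swapped = BinaryMultiplex((mx.layers[1], mx.layers[0]))
            assert np.array_equal(degree_overlap(mx), degree_overlap(swapped))
            assert np.allclose(multiplex_participation(mx), multiplex_participation(swapped))
            assert np.allclose(multiplex_clustering(mx), multiplex_clustering(swapped))
        wmx = random_weighted_multiplex(10, rng)
        wswapped = WeightedMultiplex((wmx.layers[1], wmx.layers[0]))
        assert np.allclose(overlapping_strength(wmx), overlapping_strength(wswapped))

    def test_bounds_on_random_multiplexes(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 21))
            d = float(rng.uniform(0.05, 0.5))
            mx = random_binary_multiplex(n, rng, density=d)
            p = multiplex_participation(mx)
            c = multiplex_clustering(mx)
            assert np.all((0 <= p) & (p <= 1))
            assert np.all((0 <= c) & (c <= 1))
            assert np.all(degree_overlap(mx) <= np.minimum(*(l.degrees for l in mx.layers)))


class TestSweepMetrics:
    def test_sweep_yields_29_records_consistent_with_direct_calls(self, rng):
        from conftest import random_symmetric
        from mxad.build import density_sweep

        mx = WeightedMultiplex(
            (
                WeightedLayer(random_symmetric(30, rng), "gray_matter"),
                WeightedLayer(random_symmetric(30, rng), "amyloid"),
            )
        )
        sweep = density_sweep(mx)
        metrics = metrics_over_sweep(sweep)
        assert len(metrics) == 29
        # spot-check one density against individually called operations
        probe = sweep[10]
        rec = metrics[float(probe.density)]
        assert np.array_equal(rec.d, degree_overlap(probe))
        assert np.allclose(rec.p, multiplex_participation(probe))
        assert np.allclose(rec.c, multiplex_clustering(probe))
        tidy = sweep_to_frame(metrics)
        assert set(tidy.columns) == {"density", "region", "measure", "value"}
        assert tidy["density"].nunique() == 29

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError):
            metrics_over_sweep([])
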