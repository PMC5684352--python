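import itertools

import numpy as np
import pytest

from costructure import detect_modules, modularity_q
from costructure.module_detection import Partition, canonical_membership
from costructure.net_model_io import layer_adjacency

from conftest import make_layer, random_layer


def q_oracle(adj, membership):
    """Modularity by the raw double sum over node pairs (independent oracle)."""
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    k = [sum(adj[i]) for i in range(n)]
    two_m = sum(k)
    if two_m == 0:
        return 0.0
    q = 0.0
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += adj[i, j] - k[i] * k[j] / two_m
    return q / two_m


def set_partitions(items):
    """All partitions of a small collection (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def best_partition_q(adj):
    """Exhaustive maximum modularity over all partitions (<= 8 nodes)."""
    n = adj.shape[0]
    best = -np.inf
    for blocks in set_partitions(range(n)):
        mem = np.empty(n, dtype=int)
        for g, block in enumerate(blocks):
            mem[block] = g
        best = max(best, q_oracle(adj, mem))
    return best


DISJOINT_EDGES = np.array([[1, 0], [0, 1]])  # 2 rows x 2 cols, two separate pairs


class TestDetectModules:
    def test_two_disjoint_edges(self):
        layer = make_layer(DISJOINT_EDGES)
        part = detect_modules(layer)
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5)
        # each module is one interacting pair
        assert sorted(sorted(part.members(g)) for g in range(2)) == [
            ["x0", "y0"],
            ["x1", "y1"],
        ]
        # exhaustive oracle: 0.5 is the global maximum
        assert best_partition_q(layer_adjacency(layer).astype(float)) == pytest.approx(0.5)

    def test_complete_block_is_one_module(self):
        part = detect_modules(make_layer(np.ones((2, 2), dtype=int)))
        assert part.n_modules == 1

    def test_isolated_species_become_singletons(self):
        inc = np.array(
            [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 0], [0, 0, 0, 0]]
        )
        part = detect_modules(make_layer(inc))
        mem = dict(zip(part.node_labels, part.membership))
        sizes = part.module_sizes()
        # rows x3, x4 and column y3 have no interactions -> singletons
        for species in ("x3", "x4", "y3"):
            assert sizes[mem[species]] == 1

    def test_deterministic(self, rng):
        layer = random_layer(rng, 15, 15, density=0.2)
        p1 = detect_modules(layer)
        p2 = detect_modules(layer)
        np.testing.assert_array_equal(p1.membership, p2.membership)
        assert p1.q == p2.q

    def test_modules_nest_in_connected_components(self, rng):
        from scipy.sparse.csgraph import connected_components

        layer = random_layer(rng, 12, 12, density=0.08)
        part = detect_modules(layer)
        _, comp = connected_components(layer_adjacency(layer) > 0, directed=False)
        for g in range(part.n_modules):
            comps = {comp[i] for i, m in enumerate(part.membership) if m == g}
            assert len(comps) == 1
        assert part.n_modules >= len(set(comp))

    def test_beats_components_and_positive_when_oracle_finds_gain(self, rng):
        from scipy.sparse.csgraph import connected_components

        for _ in range(5):
            layer = random_layer(rng, 4, 4, density=0.35)
            if layer.incidence.sum() == 0:
                continue
            adj = layer_adjacency(layer).astype(float)
            part = detect_modules(layer)
            _, comp = connected_components(adj > 0, directed=False)
            assert part.q >= q_oracle(adj, comp) - 1e-9
            if best_partition_q(adj) > 1e-9:
                assert part.q >= 0.0

    def test_fine_tune_never_decreases_q(self, rng):
        for _ in range(5):
            layer = random_layer(rng, 10, 10, density=0.25)
            q_plain = detect_modules(layer).q
            q_ref = detect_modules(layer, fine_tune=True).q
            assert q_ref >= q_plain - 1e-12

    def test_edgeless_layer_is_all_singletons(self):
        part = detect_modules(make_layer(np.zeros((3, 2), dtype=int)))
        assert part.n_modules == 5
        assert part.q == 0.0


class TestModularityQ:
    def test_all_in_one_partition_is_zero(self, rng):
        layer = random_layer(rng, 6, 5, density=0.4)
        part = Partition(layer.node_labels(), np.zeros(11, dtype=int))
        assert modularity_q(layer, part) == pytest.approx(0.0)

    def test_disjoint_edges_split(self):
        layer = make_layer(DISJOINT_EDGES)
        part = Partition(layer.node_labels(), np.array([0, 1, 0, 1]))
        assert modularity_q(layer, part) == pytest.approx(0.5)

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(5):
            layer = random_layer(rng, 5, 4, density=0.4)
            mem = rng.integers(0, 3, size=9)
            part = Partition(layer.node_labels(), mem)
            assert modularity_q(layer, part) == pytest.approx(
                q_oracle(layer_adjacency(layer), mem)
            )

    def test_matches_igraph(self, rng):
        igraph = pytest.importorskip("igraph")
        layer = random_layer(rng, 8, 7, density=0.3)
        adj = layer_adjacency(layer)
        mem = rng.integers(0, 4, size=15)
        g = igraph.Graph.Adjacency((adj > 0).tolist(), mode="undirected")
        part = Partition(layer.node_labels(), mem)
        if adj.sum() > 0:
            assert modularity_q(layer, part) == pytest.approx(
                g.modularity(mem.tolist())
            )

    def test_detected_beats_random_partitions(self, rng):
        from costructure import planted_pair

        layer = planted_pair(n_rows=12, n_cols=12, k_modules=2, p_in=0.6,
                             p_out=0.05, seed=7).pair.layer1
        detected = detect_modules(layer)
        n = len(layer.node_labels())
        for _ in range(100):
            mem = rng.integers(0, 4, size=n)
            part = Partition(layer.node_labels(), mem)
            assert detected.q >= modularity_q(layer, part) - 1e-12

    def test_node_mismatch_rejected(self):
        layer = make_layer(DISJOINT_EDGES)
        part = Partition(("a", "b", "c", "d"), np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="node sets differ"):
            modularity_q(layer, part)


class TestCanonicalForm:
    def test_ids_ordered_by_size_then_smallest_member(self):
        labels = ("a", "b", "c", "d", "e")
        mem = np.array([5, 5, 2, 2, 9])  # sizes 2, 2, 1
        canon = canonical_membership(labels, mem)
        # {a,b} and {c,d} tie on size; 'a' < 'c' so {a,b} gets id 0
        assert canon.tolist() == [0, 0, 1, 1, 2]

    def test_detect_output_is_canonical(self, rng):
        layer = random_layer(rng, 10, 8, density=0.2)
        part = detect_modules(layer)
        sizes = part.module_sizes()
        assert (np.diff(sizes) <= 0).all() or all(
            (sizes[i] > sizes[i + 1])
            or (sizes[i] == sizes[i + 1]
                and min(part.members(i)) < min(part.members(i + 1)))
            for i in range(part.n_modules - 1)
        )
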