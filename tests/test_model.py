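"""Unit and property tests for the multiplex data model and score."""

import numpy as np
import pytest

from conftest import random_layer, random_multiplex, random_partition
from _oracles import eq1_brute

from muxcom import (Layer, LayerWeights, MultiplexNetwork, Partition,
                    layer_stats, modularity_gain, multiplex_modularity,
                    subnetwork)


class TestLayerStats:
    def test_unit_triangle(self):
        lay = Layer.from_edges([(1, 2), (2, 3), (1, 3)])
        st = layer_stats(lay)
        assert st.m == 3
        assert all(st.strength[v] == 2 for v in (1, 2, 3))

    def test_empty_layer(self):
        assert layer_stats(Layer()).m == 0

    def test_weighted_path(self):
        lay = Layer.from_edges([("a", "b", 2.0), ("b", "c", 5.0)])
        st = layer_stats(lay)
        assert st.m == 7
        assert (st.strength["a"], st.strength["b"], st.strength["c"]) == (2, 7, 5)

    def test_strength_sums_to_twice_m(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            st = layer_stats(random_layer(rng, n=12, p=0.4, weighted=True))
            assert sum(st.strength.values()) == pytest.approx(2 * st.m)


class TestLayerConstruction:
    def test_self_loops_dropped_duplicates_summed(self, caplog):
        lay = Layer.from_edges([("a", "a"), ("a", "b", 1.0), ("a", "b", 2.5)])
        assert lay.weight("a", "b") == 3.5
        assert "a" not in dict(lay.graph.adj["a"]).keys() or \
            not lay.graph.has_edge("a", "a")

    def test_zero_weight_edges_absent_negative_rejected(self):
        lay = Layer.from_edges([("a", "b", 0.0), ("b", "c", 1.0)])
        assert not lay.graph.has_edge("a", "b")
        with pytest.raises(ValueError):
            Layer.from_edges([("a", "b", -1.0)])


class TestPartition:
    def test_canonical_labels_compare_equal(self):
        p1 = Partition({"a": "x", "b": "x", "c": "y"})
        p2 = Partition({"a": 7, "b": 7, "c": 0})
        assert p1 == p2 and hash(p1) == hash(p2)
        assert sorted(p1.communities) == [0, 1]

    def test_from_communities_rejects_overlap_and_empty(self):
        with pytest.raises(ValueError):
            Partition.from_communities([["a", "b"], ["b"]])
        with pytest.raises(ValueError):
            Partition.from_communities([["a"], []])

    def test_restrict(self):
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        sub = p.restrict(["a", "c"])
        assert sub["a"] != sub["c"] and len(sub) == 2


class TestMultiplexModularity:
    def test_all_singletons_scores_zero(self, two_triangles):
        net, _ = two_triangles
        assert multiplex_modularity(net, Partition.singletons(net.universe)) == 0.0

    def test_zero_layer_weight_scores_zero(self, two_triangles):
        net, part = two_triangles
        assert multiplex_modularity(net, part, layer_weights=[0.0, ]) == 0.0 \
            if net.n_layers == 1 else True

    def test_two_triangles_bridge_value(self, two_triangles):
        # term-by-term oracle value for the two-triangle partition, gamma=1
        net, part = two_triangles
        assert multiplex_modularity(net, part) == pytest.approx(13 / 49, abs=1e-15)
        assert eq1_brute(net, part) == pytest.approx(13 / 49, abs=1e-15)

    def test_zero_weight_layer_equals_layer_removal(self):
        rng = np.random.default_rng(1)
        net = random_multiplex(rng, n=8, n_layers=2, weighted=True)
        part = random_partition(rng, net.universe, 3)
        two = multiplex_modularity(net, part, layer_weights=[1.0, 0.0])
        one = multiplex_modularity(MultiplexNetwork([net.layers[0]]), part,
                                   layer_weights=[1.0])
        assert two == pytest.approx(one, abs=1e-15)

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            net = random_multiplex(rng, n=7, n_layers=2, weighted=True)
            part = random_partition(rng, net.universe, 3)
            assert multiplex_modularity(net, part, gamma=1.3) == pytest.approx(
                eq1_brute(net, part, gamma=1.3), abs=1e-12)

    def test_additivity_over_layers(self):
        rng = np.random.default_rng(3)
        net = random_multiplex(rng, n=9, n_layers=3, weighted=True)
        part = random_partition(rng, net.universe, 3)
        lw = [0.5, 2.0, 1.0]
        total = multiplex_modularity(net, part, layer_weights=lw)
        parts = sum(
            w * multiplex_modularity(
                MultiplexNetwork([lay]),
                Partition({v: part[v] for v in net.universe}))
            for lay, w in zip(net.layers, lw))
        assert total == pytest.approx(parts, abs=1e-12)

    @pytest.mark.parametrize("c", [2.0, 10.0])
    def test_layer_score_invariant_under_weight_rescaling(self, c):
        rng = np.random.default_rng(4)
        lay = random_layer(rng, n=10, p=0.4, weighted=True)
        part = random_partition(rng, tuple(lay.graph.nodes), 3)
        scaled = Layer.from_edges(
            [(u, v, c * d["weight"]) for u, v, d in lay.graph.edges(data=True)])
        q0 = multiplex_modularity(MultiplexNetwork([lay]), part)
        q1 = multiplex_modularity(MultiplexNetwork([scaled]), part)
        assert q1 == pytest.approx(q0, abs=1e-12)

    def test_partition_must_cover_universe(self, two_triangles):
        net, _ = two_triangles
        with pytest.raises(ValueError):
            multiplex_modularity(net, Partition({"a": 0}))

    def test_layer_weight_arity_checked(self, two_triangles):
        net, part = two_triangles
        with pytest.raises(ValueError):
            multiplex_modularity(net, part, layer_weights=[1.0, 1.0])
        with pytest.raises(ValueError):
            LayerWeights([0.0])  # no positive entry


class TestModularityGain:
    def test_noop_move_is_zero(self, two_triangles):
        net, part = two_triangles
        assert modularity_gain(net, part, "a", part["a"]) == 0.0

    def test_isolated_vertex_moves_freely(self):
        lay = Layer.from_edges([(1, 2)])
        lay.graph.add_node(3)
        net = MultiplexNetwork([lay])
        part = Partition({1: 0, 2: 0, 3: 1})
        assert modularity_gain(net, part, 3, 0) == pytest.approx(0.0, abs=1e-15)

    def test_unknown_vertex_rejected(self, two_triangles):
        net, part = two_triangles
        with pytest.raises(ValueError):
            modularity_gain(net, part, "zz", 0)

    def test_incremental_matches_full_recomputation(self):
        # move a random vertex to a random community (or a new singleton)
        # and compare with the difference of two full evaluations
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 1000:
            net = random_multiplex(rng, n=8, n_layers=2, weighted=True)
            part = random_partition(rng, net.universe, 3)
            for _ in range(25):
                v = net.universe[rng.integers(net.n_vertices)]
                labels = list(part.communities) + [None]
                target = labels[rng.integers(len(labels))]
                inc = modularity_gain(net, part, v, target, gamma=1.1)
                moved = dict(part.assignment)
                moved[v] = part[v] if target is None else target
                if target is None:
                    moved[v] = max(part.communities) + 1
                after = Partition(moved)
                full = (multiplex_modularity(net, after, gamma=1.1)
                        - multiplex_modularity(net, part, gamma=1.1))
                assert inc == pytest.approx(full, abs=1e-9)
                checked += 1


class TestSubnetwork:
    def test_full_subset_is_identity(self, two_triangles):
        net, _ = two_triangles
        sub = subnetwork(net, net.universe)
        assert sub.universe == net.universe
        assert sub.layers[0].graph.edges == net.layers[0].graph.edges

    def test_single_vertex_is_edgeless(self, two_triangles):
        net, _ = two_triangles
        sub = subnetwork(net, ["a"])
        assert sub.universe == ("a",)
        assert sub.layers[0].n_edges == 0

    def test_one_clique_of_two(self):
        edges = ([(i, j) for i in range(4) for j in range(i + 1, 4)]
                 + [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
                 + [(0, 4)])
        net = MultiplexNetwork([Layer.from_edges(edges)])
        sub = subnetwork(net, range(4))
        assert sub.layers[0].n_edges == 6  # C(4,2)

    def test_empty_subset_rejected(self, two_triangles):
        net, _ = two_triangles
        with pytest.raises(ValueError):
            subnetwork(net, [])
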