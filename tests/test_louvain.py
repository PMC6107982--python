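"""Tests for the (randomized) multiplex Louvain optimizer."""

import networkx as nx
import numpy as np
import pytest

from conftest import random_multiplex, random_partition
from _oracles import eq1_brute, exhaustive_argmax

from muxcom import (Layer, MultiplexNetwork, OptimizerConfig, Partition,
                    aggregate, internal_modularity, louvain_pass,
                    multiplex_modularity, run_louvain)


def _clique_pair_net():
    edges = ([(i, j) for i in range(4) for j in range(i + 1, 4)]
             + [(i, j) for i in range(4, 8) for j in range(i + 1, 8)])
    return MultiplexNetwork([Layer.from_edges(edges)])


class TestLouvainPass:
    def test_edgeless_network_stays_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(range(5))
        net = MultiplexNetwork([Layer(g)])
        part = Partition.singletons(net.universe)
        assert louvain_pass(net, part) == part

    def test_score_non_decreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            net = random_multiplex(rng, n=10, n_layers=2, weighted=True)
            part = Partition.singletons(net.universe)
            before = multiplex_modularity(net, part)
            after_part = louvain_pass(net, part)
            after = multiplex_modularity(net, after_part)
            assert after >= before - 1e-12


class TestDeterministicOptima:
    def test_two_disjoint_cliques_found_and_globally_optimal(self):
        net = _clique_pair_net()
        res = run_louvain(net, OptimizerConfig(n_runs=0, seed=0))
        expected = Partition.from_communities([range(4), range(4, 8)])
        assert res.partition == expected
        best, argmax = exhaustive_argmax(net)  # all 4140 partitions of 8
        assert res.score == pytest.approx(best, abs=1e-12)
        assert expected in argmax

    def test_triangle_merges_to_one_community(self, triangle_net):
        res = run_louvain(triangle_net, OptimizerConfig(n_runs=0))
        assert res.partition.n_communities == 1
        best, argmax = exhaustive_argmax(triangle_net)  # 5 partitions
        assert res.score == pytest.approx(best, abs=1e-12)


class TestAggregate:
    def test_singleton_partition_reproduces_network(self, two_triangles):
        net, _ = two_triangles
        agg = aggregate(net, Partition.singletons(net.universe))
        assert agg.layers[0].n_edges == net.layers[0].n_edges
        assert not any(u == v for u, v in agg.layers[0].graph.edges)

    def test_two_cliques_aggregate_by_hand(self):
        edges = ([(i, j) for i in range(4) for j in range(i + 1, 4)]
                 + [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
                 + [(0, 4, 2.0)])
        net = MultiplexNetwork([Layer.from_edges(edges)])
        part = Partition.from_communities([range(4), range(4, 8)])
        agg = aggregate(net, part)
        g = agg.layers[0].graph
        assert g.number_of_nodes() == 2
        assert g[0][0]["weight"] == 6.0  # intra-clique weight as self-loop
        assert g[1][1]["weight"] == 6.0
        assert g[0][1]["weight"] == 2.0  # the bridge

    def test_internal_modularity_preserved_under_aggregation(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            net = random_multiplex(rng, n=10, n_layers=2, weighted=True)
            fine = random_partition(rng, net.universe, 4)
            agg = aggregate(net, fine)
            # coarse partition of the supervertices and its refinement
            labels = sorted(fine.communities)
            coarse_of = {lab: lab % 2 for lab in labels}
            coarse = Partition({lab: coarse_of[lab] for lab in labels})
            refined = Partition({v: coarse_of[fine[v]] for v in net.universe})
            lw = [1.0, 0.5]
            assert internal_modularity(agg, coarse, 1.2, lw) == pytest.approx(
                internal_modularity(net, refined, 1.2, lw), abs=1e-9)


class TestRunLouvain:
    def test_best_of_n_takes_the_maximum_run(self):
        rng = np.random.default_rng(2)
        net = random_multiplex(rng, n=12, n_layers=2, p=0.4, weighted=True)
        res = run_louvain(net, OptimizerConfig(n_runs=5, seed=11))
        assert res.runs_performed == 5
        assert res.score == max(res.run_scores)
        assert res.run_scores[res.best_run_index] == res.score
        assert all(res.score >= s for s in res.run_scores)

    def test_fixed_seed_is_reproducible(self):
        rng = np.random.default_rng(3)
        net = random_multiplex(rng, n=15, n_layers=2, p=0.3, weighted=True)
        r1 = run_louvain(net, OptimizerConfig(n_runs=3, seed=42))
        r2 = run_louvain(net, OptimizerConfig(n_runs=3, seed=42))
        assert r1.partition == r2.partition
        assert r1.score == r2.score

    def test_reported_score_matches_recomputation(self):
        rng = np.random.default_rng(4)
        net = random_multiplex(rng, n=12, n_layers=2, weighted=True)
        res = run_louvain(net, OptimizerConfig(gamma=1.4, n_runs=4, seed=5))
        assert res.score == pytest.approx(
            multiplex_modularity(net, res.partition, gamma=1.4), abs=1e-9)
        assert res.score == pytest.approx(
            eq1_brute(net, res.partition, gamma=1.4), abs=1e-9)

    def test_zero_weight_layer_equals_deleting_it(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            net = random_multiplex(rng, n=12, n_layers=2, p=0.4, weighted=True)
            cfg = OptimizerConfig(n_runs=0, seed=1)
            with_zero = run_louvain(net, cfg, layer_weights=[1.0, 0.0])
            only_first = run_louvain(MultiplexNetwork([net.layers[0]]), cfg)
            # partitions agree on layer-1 vertices; extra vertices singleton
            sub = with_zero.partition.restrict(only_first.partition.vertices())
            assert sub == only_first.partition

    def test_all_layers_empty_yields_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        net = MultiplexNetwork([Layer(g)])
        res = run_louvain(net, OptimizerConfig(n_runs=3, seed=0))
        assert res.partition == Partition.singletons(net.universe)
        assert res.score == 0.0

    def test_planted_two_block_sbm_recovered(self):
        from muxcom import SBMSpec, simulate, adjusted_rand_index
        hits = 0
        for rep in range(20):
            inst = simulate(SBMSpec(n=60, k=2, n_layers=2,
                                    regime=(0.5, 0.02), seed=300 + rep))
            res = run_louvain(inst.network, OptimizerConfig(n_runs=5, seed=rep))
            if adjusted_rand_index(res.partition, inst.planted) == 1.0:
                hits += 1
        assert hits >= 19  # exact recovery in >=95% of instances
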