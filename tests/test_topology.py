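"""Degree/strength, hubs, transitivity, nulls, group comparison."""

import itertools

import numpy as np
import pytest

from micronet.core import AbundanceTable
from micronet.network import SignedNetwork, split_signs
from micronet.synthetic import generate_truth, sample_counts
from micronet.topology import (
    compare_groups,
    degree_strength,
    hubs,
    is_isomorphic,
    mean_interactions,
    rewire_null,
    transitivity,
)

from conftest import random_signed_network


def triangle(weight=0.5):
    w = np.full((3, 3), weight)
    np.fill_diagonal(w, 0.0)
    return SignedNetwork(list("abc"), w)


def path3():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 0.4
    w[1, 2] = w[2, 1] = 0.6
    return SignedNetwork(list("abc"), w)


def star(n=6):
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 0.5
    return SignedNetwork([f"n{i}" for i in range(n)], w)


class TestDegreeStrength:
    def test_triangle_and_empty(self):
        degree, strength = degree_strength(triangle(0.5))
        assert degree.tolist() == [2, 2, 2]
        assert np.allclose(strength, 1.0)
        empty = SignedNetwork(list("ab"), np.zeros((2, 2)))
        d, s = degree_strength(empty)
        assert d.tolist() == [0, 0] and s.tolist() == [0.0, 0.0]

    def test_matches_brute_force_row_scan(self, random_network):
        degree, strength = degree_strength(random_network)
        for i in range(random_network.n_nodes):
            manual_degree = sum(
                random_network.weights[i, j] != 0
                for j in range(random_network.n_nodes)
            )
            manual_strength = sum(
                abs(random_network.weights[i, j])
                for j in range(random_network.n_nodes)
            )
            assert degree[i] == manual_degree
            assert strength[i] == pytest.approx(manual_strength)

    def test_degree_sum_is_twice_edges(self, random_network):
        degree, _ = degree_strength(random_network)
        assert degree.sum() == 2 * random_network.n_edges


class TestMeanInteractions:
    def test_closed_forms(self):
        assert mean_interactions(triangle()) == pytest.approx(2.0)
        assert mean_interactions(SignedNetwork(list("ab"), np.zeros((2, 2)))) == 0.0


class TestHubs:
    def test_ceiling_rule_for_47_nodes(self):
        net = random_signed_network(47, 0.2, seed=3)
        assert len(hubs(net, 0.10)) == 5

    def test_tie_break_is_deterministic(self):
        net = triangle()  # all-equal degrees and strengths
        assert hubs(net, 0.34) == ["a", "b"]
        assert hubs(net, 0.34) == hubs(net, 0.34)

    def test_star_center_is_hub(self):
        assert hubs(star(), 0.10) == ["n0"]


class TestTransitivity:
    def test_triangle_and_path(self):
        assert transitivity(triangle()) == pytest.approx(1.0)
        assert transitivity(path3()) == 0.0

    def test_matches_triple_enumeration(self):
        net = random_signed_network(15, 0.35, seed=21)
        adj = net.weights != 0
        triangles = triples = 0
        for i, j, k in itertools.combinations(range(15), 3):  # O(N^3) oracle
            if adj[i, j] and adj[j, k] and adj[i, k]:
                triangles += 1
        # connected triples centred on each node
        for center in range(15):
            nbrs = [x for x in range(15) if adj[center, x]]
            triples += len(nbrs) * (len(nbrs) - 1) // 2
        expected = 3 * triangles / triples if triples else 0.0
        assert transitivity(net) == pytest.approx(expected, abs=1e-12)

    def test_bounds(self, random_network):
        assert 0.0 <= transitivity(random_network) <= 1.0


class TestRewireNull:
    def test_degree_sequence_preserved_every_replicate(self, random_network):
        observed_degrees = sorted(degree_strength(random_network)[0].tolist())
        seen = []

        def record_degrees(net):
            seen.append(sorted(degree_strength(net)[0].tolist()))
            return 0.0

        rewire_null(random_network, {"probe": record_degrees}, n=25, seed=1)
        assert all(d == observed_degrees for d in seen)

    def test_weight_multiset_preserved(self, random_network):
        original = sorted(round(w, 12) for _, _, w in random_network.edges())
        seen = []

        def record_weights(net):
            seen.append(sorted(round(w, 12) for _, _, w in net.edges()))
            return 0.0

        rewire_null(random_network, {"probe": record_weights}, n=10, seed=2)
        assert all(w == original for w in seen)

    def test_star_graph_flagged(self):
        result = rewire_null(star(), n=5, seed=0)
        assert all(e.swap_failed for e in result.values())

    def test_modular_network_beats_null_transitivity(self):
        # three dense blocks: observed transitivity far above rewired null
        rng = np.random.default_rng(5)
        n = 15
        w = np.zeros((n, n))
        for block in (range(0, 5), range(5, 10), range(10, 15)):
            for i, j in itertools.combinations(block, 2):
                w[i, j] = w[j, i] = rng.uniform(0.4, 0.9)
        net = SignedNetwork([f"n{i}" for i in range(n)], w)
        result = rewire_null(net, {"transitivity": transitivity}, n=200, seed=7)
        assert result["transitivity"].z_score > 2

    def test_empirical_p_in_unit_interval(self, random_network):
        result = rewire_null(random_network, n=50, seed=3)
        for ensemble in result.values():
            assert 0 < ensemble.p_value <= 1
            assert ensemble.n_replicates == 50


class TestCompareGroups:
    @staticmethod
    def _table(seed, group, n=20):
        truth = generate_truth(8, blocks=[3], seed=1)  # same structure
        return sample_counts(
            truth, n, seed=seed, sample_prefix=f"{group}_", group=group
        )

    def test_identical_samples_give_p_one(self):
        ta = self._table(3, "A")
        tb = AbundanceTable(
            ta.counts.rename(columns=lambda c: c.replace("A_", "B_")),
            {s.replace("A_", "B_"): "B" for s in ta.sample_ids},
        )
        stats_map = {"pos": lambda n: mean_interactions(split_signs(n)[0])}
        res = compare_groups(
            ta, tb, ta.taxon_ids, stats_map, n_perm=99, alpha=0.01, seed=0
        )
        assert res["pos"].observed_diff == 0.0
        assert res["pos"].p_value == 1.0

    def test_planted_density_difference_detected(self):
        # strongly different competition densities at n=60/group
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            truth_a = generate_truth(
                10, negative_pairs=[(0, 1), (2, 3), (4, 5)],
                effect_sizes=(0.8, 0.8), seed=2,
            )
            truth_b = generate_truth(10, effect_sizes=(0.8, 0.8), seed=2)
            ta = sample_counts(truth_a, 60, seed=40 + seed, sample_prefix="A_", group="A")
            tb = sample_counts(truth_b, 60, seed=80 + seed, sample_prefix="B_", group="B")
            stats_map = {"neg": lambda n: mean_interactions(split_signs(n)[1])}
            res = compare_groups(
                ta, tb, ta.taxon_ids, stats_map, n_perm=199, alpha=1e-4, seed=seed
            )
            hits += res["neg"].p_value < 0.05
        assert hits >= 4

    def test_small_n_perm_warns(self, caplog):
        ta = self._table(5, "A", n=8)
        tb = self._table(6, "B", n=8)
        with caplog.at_level("WARNING"):
            compare_groups(
                ta, tb, ta.taxon_ids,
                {"pos": lambda n: mean_interactions(split_signs(n)[0])},
                n_perm=50, seed=1,
            )
        assert "resolution" in caplog.text


class TestIsIsomorphic:
    def test_permuted_copy_is_isomorphic(self):
        net = random_signed_network(20, 0.25, seed=9)
        rng = np.random.default_rng(1)
        perm = rng.permutation(20)
        w = net.weights[np.ix_(perm, perm)]
        permuted = SignedNetwork([f"m{i}" for i in range(20)], w)
        assert is_isomorphic(net, permuted) is True

    def test_different_degree_sequences_fail_fast(self):
        assert is_isomorphic(triangle(), path3()) is False

    def test_single_moved_edge_breaks_isomorphism(self):
        net = random_signed_network(20, 0.25, seed=9)
        w = net.weights.copy()
        edges = [(i, j) for i in range(20) for j in range(i + 1, 20) if w[i, j] != 0]
        non_edges = [
            (i, j) for i in range(20) for j in range(i + 1, 20) if w[i, j] == 0
        ]
        (i, j), (k, l) = edges[0], non_edges[0]
        w[i, j] = w[j, i] = 0.0
        w[k, l] = w[l, k] = 0.5
        moved = SignedNetwork(list(net.taxon_ids), w)
        # moving one edge changes the degree sequence or the structure
        assert is_isomorphic(net, moved) in (False, None)
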