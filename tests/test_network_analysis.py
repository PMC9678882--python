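"""Centrality hand values, modularity oracles, greedy community detection."""

from __future__ import annotations

import numpy as np
import pytest

from morbinet.network_analysis import (
    centralities,
    fast_greedy_communities,
    label_patterns,
    modularity,
)


def star(p=5):
    A = np.zeros((p, p))
    A[0, 1:] = A[1:, 0] = 1.0
    return A


def path4():
    A = np.zeros((4, 4))
    for i in range(3):
        A[i, i + 1] = A[i + 1, i] = 1.0
    return A


def two_triangles():
    A = np.zeros((6, 6))
    for block in (range(3), range(3, 6)):
        nodes = list(block)
        for i in nodes:
            for j in nodes:
                if i != j:
                    A[i, j] = 1.0
    return A


def triangle():
    A = np.ones((3, 3)) - np.eye(3)
    return A


def all_partitions(p):
    """Enumerate all set partitions of range(p) as membership vectors
    (restricted growth strings)."""
    def rec(prefix, maxlab):
        if len(prefix) == p:
            yield list(prefix)
            return
        for lab in range(maxlab + 2):
            yield from rec(prefix + [lab], max(maxlab, lab))

    yield from rec([0], 0)


class TestCentralityHandValues:
    def test_star_degree(self):
        tab = centralities(star())
        assert tab["degree"].tolist() == [4, 1, 1, 1, 1]

    def test_star_betweenness_center_counts_leaf_pairs(self):
        tab = centralities(star())
        assert tab["betweenness"].tolist() == [6, 0, 0, 0, 0]

    def test_star_closeness(self):
        tab = centralities(star())
        assert tab["closeness"].iloc[0] == pytest.approx(1 / 4)
        assert tab["closeness"].iloc[1] == pytest.approx(1 / 7)

    def test_path_betweenness_matches_enumeration(self):
        # a-b-c-d: through b pass {a,c},{a,d}; through c pass {a,d},{b,d}
        tab = centralities(path4())
        assert tab["betweenness"].tolist() == [0, 2, 2, 0]

    def test_zscores_standardized(self):
        tab = centralities(star())
        for col in ("degree", "betweenness", "closeness"):
            z = tab[f"z_{col}"].to_numpy()
            assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
            assert np.std(z) == pytest.approx(1.0, abs=1e-12)

    def test_z_invariant_to_uniform_weight_rescaling(self):
        A = two_triangles()
        A[0, 3] = A[3, 0] = 0.5  # connect the components
        t1, t2 = centralities(A), centralities(10.0 * A)
        for col in ("z_degree", "z_betweenness", "z_closeness"):
            assert np.allclose(t1[col], t2[col])

    def test_single_edge_graph_zscore_missing_when_sd_zero(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        tab = centralities(A)
        assert tab["z_degree"].isna().all()


class TestModularity:
    def test_one_community_is_zero(self):
        assert modularity(two_triangles(), [0] * 6) == pytest.approx(0.0)

    def test_two_triangles_by_component_is_half(self):
        assert modularity(two_triangles(), [0, 0, 0, 1, 1, 1]) == pytest.approx(0.5)

    def test_triangle_singletons_minus_third(self):
        assert modularity(triangle(), [0, 1, 2]) == pytest.approx(-1 / 3)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity(np.zeros((3, 3)), [0, 1, 2])

    def test_matches_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(0)
        A = np.triu((rng.random((7, 7)) < 0.4) * rng.random((7, 7)), 1)
        A = A + A.T
        if A.sum() == 0:
            pytest.skip("empty random draw")
        G = nx.from_numpy_array(A)
        membership = [0, 0, 1, 1, 1, 2, 2]
        comms = [
            {i for i in range(7) if membership[i] == c} for c in range(3)
        ]
        expected = nx.algorithms.community.modularity(G, comms, weight="weight")
        assert modularity(A, membership) == pytest.approx(expected, abs=1e-12)


class TestFastGreedy:
    def test_two_triangles_recovered_with_q_half(self):
        part = fast_greedy_communities(two_triangles())
        assert part.n_communities == 2
        assert part.modularity == pytest.approx(0.5)
        assert len(set(part.membership[:3])) == 1
        assert len(set(part.membership[3:])) == 1

    def test_matches_igraph_on_two_triangles(self):
        import igraph as ig

        A = two_triangles()
        g = ig.Graph.Adjacency((A > 0).tolist(), mode="undirected")
        ref = g.community_fastgreedy().as_clustering()
        ours = fast_greedy_communities(A)
        assert sorted(map(sorted, (ref[0], ref[1]))) == sorted(
            map(sorted, (ours.members(1), ours.members(2)))
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_greedy_q_bounded_by_exhaustive_maximum(self, seed):
        rng = np.random.default_rng(seed)
        p = 6
        A = np.triu((rng.random((p, p)) < 0.5) * rng.random((p, p)), 1)
        A = A + A.T
        if A.sum() == 0:
            pytest.skip("empty random draw")
        best = max(modularity(A, m) for m in all_partitions(p))
        part = fast_greedy_communities(A)
        assert part.modularity <= best + 1e-12

    def test_exhaustive_equality_on_disconnected_cliques(self):
        A = two_triangles()
        best = max(modularity(A, m) for m in all_partitions(6))
        part = fast_greedy_communities(A)
        assert part.modularity == pytest.approx(best)

    def test_stored_q_equals_recomputed(self, small_network):
        _, _, net = small_network
        part = fast_greedy_communities(net)
        assert part.modularity == pytest.approx(
            modularity(net, part.membership), abs=1e-12
        )

    def test_isolated_nodes_stay_singletons(self):
        A = np.zeros((5, 5))
        A[0, 1] = A[1, 0] = 1.0  # nodes 2-4 isolated
        part = fast_greedy_communities(A)
        assert len({part.membership[i] for i in (2, 3, 4)}) == 3

    def test_planted_blocks_recovered(self, small_network):
        model, _, net = small_network
        part = fast_greedy_communities(net)
        # estimated partition should align with the 3 planted blocks
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(model.blocks, part.membership) > 0.9

    def test_components_not_merged_across_zero_separation(self):
        part = fast_greedy_communities(two_triangles())
        merged_across = any(
            part.membership[i] == part.membership[j]
            for i in range(3)
            for j in range(3, 6)
        )
        assert not merged_across


class TestLabelPatterns:
    def _partition(self, membership):
        from morbinet.network_analysis import CommunityPartition

        m = np.asarray(membership)
        return CommunityPartition(membership=m, modularity=0.0)

    def test_largest_community_is_mp1(self):
        part = self._partition([1] * 8 + [2] * 7 + [3] * 6 + [4] * 4 + [5] * 4 + [6] + [7])
        tab = label_patterns(part)
        sizes = tab.groupby("pattern").size()
        assert sizes["MP1"] == 8 and sizes["MP7"] == 1

    def test_equal_sizes_break_by_min_index(self):
        part = self._partition([2, 2, 1, 1])
        tab = label_patterns(part)
        # community containing node 0 (label 2) wins the tie
        assert tab.loc[0, "pattern"] == "MP1"
        assert tab.loc[2, "pattern"] == "MP2"

    def test_bijection(self):
        part = self._partition([1, 2, 1, 3, 2])
        tab = label_patterns(part)
        assert tab["pattern"].notna().all()
        assert len(tab) == 5
        assert tab.groupby("community")["pattern"].nunique().eq(1).all()
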