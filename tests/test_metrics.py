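"""Centrality and bridge centrality against hand arithmetic and enumeration."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import skillnet as sn
from skillnet.metrics import NetworkGraph

import oracles
from conftest import random_graph


class TestToyLine:
    """3-node line w12=0.5, w13=0.25: all values known by hand."""

    def test_strength(self, toy_graph):
        np.testing.assert_allclose(sn.strength(toy_graph), [0.75, 0.5, 0.25])

    def test_distances(self, toy_graph):
        D, sigma = sn.shortest_path_distances(toy_graph)
        np.testing.assert_allclose(D[0], [0, 2, 4])
        np.testing.assert_allclose(D[1], [2, 0, 6])  # b-c goes through a
        np.testing.assert_allclose(D[2], [4, 6, 0])
        assert sigma[1, 2] == 1.0

    def test_closeness(self, toy_graph):
        np.testing.assert_allclose(
            sn.closeness(toy_graph), [1 / 6, 1 / 8, 1 / 10]
        )

    def test_betweenness(self, toy_graph):
        np.testing.assert_allclose(sn.betweenness(toy_graph), [1, 0, 0])

    def test_bridge_strength(self, toy_graph):
        np.testing.assert_allclose(sn.bridge_strength(toy_graph), [0.25, 0.0, 0.25])

    def test_bridge_closeness(self, toy_graph):
        np.testing.assert_allclose(
            sn.bridge_closeness(toy_graph), [1 / 4, 1 / 6, 1 / 5]
        )

    def test_bridge_betweenness(self, toy_graph):
        np.testing.assert_allclose(sn.bridge_betweenness(toy_graph), [1, 0, 0])

    def test_centrality_table_composition(self, toy_graph):
        tab = sn.centrality_table(toy_graph)
        assert list(tab.index) == ["a", "b", "c"]
        np.testing.assert_allclose(tab["strength"], [0.75, 0.5, 0.25])
        np.testing.assert_allclose(tab["bridge_closeness"], [0.25, 1 / 6, 0.2])


class TestKnownShapes:
    def test_single_edge_distance(self):
        W = np.zeros((2, 2)); W[0, 1] = W[1, 0] = 0.4
        G = NetworkGraph(W=W, labels=("a", "b"), community_of={"a": "A", "b": "B"})
        D, _ = sn.shortest_path_distances(G)
        assert D[0, 1] == 2.5
        np.testing.assert_allclose(sn.bridge_closeness(G), [0.4, 0.4])

    def test_star_center_betweenness(self):
        p = 5
        W = np.zeros((p, p))
        for i in range(1, p):
            W[0, i] = W[i, 0] = 0.5
        G = NetworkGraph(
            W=W,
            labels=tuple("abcde"),
            community_of={l: "A" for l in "abcde"} | {"e": "B"},
        )
        bt = sn.betweenness(G)
        assert bt[0] == 6.0  # C(4,2) pairs routed through the center
        np.testing.assert_allclose(bt[1:], 0.0)

    def test_complete_graph_zero_betweenness(self):
        p = 5
        W = np.full((p, p), 0.3); np.fill_diagonal(W, 0.0)
        G = NetworkGraph(
            W=W,
            labels=tuple("abcde"),
            community_of={l: "A" for l in "abcde"} | {"e": "B"},
        )
        np.testing.assert_allclose(sn.betweenness(G), 0.0)

    def test_isolated_and_disconnected(self):
        W = np.zeros((3, 3)); W[0, 1] = W[1, 0] = 0.5
        G = NetworkGraph(
            W=W, labels=("a", "b", "c"),
            community_of={"a": "A", "b": "A", "c": "B"},
        )
        assert sn.strength(G)[2] == 0.0
        D, _ = sn.shortest_path_distances(G)
        assert np.isinf(D[0, 2])
        assert sn.closeness(G)[2] == 0.0
        assert sn.bridge_closeness(G)[0] == 0.0  # nothing reachable cross-community

    def test_distance_homogeneity(self, toy_graph):
        doubled = NetworkGraph(
            W=2 * toy_graph.W, labels=toy_graph.labels,
            community_of=toy_graph.community_of,
        )
        D1, _ = sn.shortest_path_distances(toy_graph)
        D2, _ = sn.shortest_path_distances(doubled)
        np.testing.assert_allclose(D2, D1 / 2)
        np.testing.assert_allclose(sn.closeness(doubled), 2 * sn.closeness(toy_graph))

    def test_tied_paths_share_credit(self):
        # diamond: two equal-length a-d routes through b and c
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (1, 3), (2, 3)]:
            W[i, j] = W[j, i] = 0.5
        G = NetworkGraph(
            W=W, labels=("a", "b", "c", "d"),
            community_of={"a": "A", "b": "A", "c": "A", "d": "B"},
        )
        # every node lies on one of two tied routes for the opposite pair:
        # (a,d) ties through b/c, and (b,c) ties through a/d
        bt = sn.betweenness(G)
        np.testing.assert_allclose(bt, [0.5, 0.5, 0.5, 0.5])
        bt_all = sn.betweenness(G, mode="count_all")
        np.testing.assert_allclose(bt_all, [1, 1, 1, 1])

    def test_single_community_bridge_fails(self):
        W = np.zeros((2, 2)); W[0, 1] = W[1, 0] = 0.5
        G = NetworkGraph(W=W, labels=("a", "b"), community_of={"a": "A", "b": "A"})
        with pytest.raises(sn.ValidationError):
            sn.bridge_strength(G)
        with pytest.raises(sn.ValidationError):
            sn.bridge_betweenness(G)


class TestOracleEquivalence:
    """Exhaustive simple-path enumeration on small random graphs."""

    @pytest.mark.parametrize("seed", range(25))
    def test_random_graphs_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 8))
        G = random_graph(rng, p)
        comm = G.communities
        D, _ = sn.shortest_path_distances(G)
        np.testing.assert_allclose(D, oracles.distance_matrix(G.W), rtol=1e-12)
        np.testing.assert_allclose(
            sn.betweenness(G), oracles.betweenness(G.W), rtol=1e-12, atol=1e-12
        )
        cross = lambda j, k: comm[j] != comm[k]
        np.testing.assert_allclose(
            sn.bridge_betweenness(G),
            oracles.betweenness(G.W, pair_ok=cross),
            rtol=1e-12, atol=1e-12,
        )
        np.testing.assert_allclose(
            sn.betweenness(G, mode="count_all"),
            oracles.betweenness(G.W, fractional=False),
            atol=1e-12,
        )
        np.testing.assert_allclose(sn.strength(G), oracles.strength(G.W), atol=1e-12)
        np.testing.assert_allclose(sn.closeness(G), oracles.closeness(G.W), rtol=1e-12)
        np.testing.assert_allclose(
            sn.bridge_strength(G), oracles.bridge_strength(G.W, comm), atol=1e-12
        )
        np.testing.assert_allclose(
            sn.bridge_closeness(G), oracles.bridge_closeness(G.W, comm), rtol=1e-12
        )


class TestInvariants:
    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_sign_flip_changes_nothing(self, seed):
        rng = np.random.default_rng(seed)
        G = random_graph(rng, 6)
        tab = sn.centrality_table(G)
        i, j = 0, 1
        W2 = G.W.copy()
        if W2[i, j] == 0:  # flip some existing edge instead, if any
            nz = np.argwhere(np.triu(W2, 1) != 0)
            if len(nz) == 0:
                return
            i, j = nz[0]
        W2[i, j] *= -1; W2[j, i] *= -1
        tab2 = sn.centrality_table(
            NetworkGraph(W=W2, labels=G.labels, community_of=G.community_of)
        )
        np.testing.assert_allclose(tab2.drop(columns="community"),
                                   tab.drop(columns="community"), rtol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        G = random_graph(rng, 6)
        perm = rng.permutation(6)
        Gp = NetworkGraph(
            W=G.W[np.ix_(perm, perm)],
            labels=tuple(G.labels[k] for k in perm),
            community_of=G.community_of,
        )
        tab = sn.centrality_table(G)
        tabp = sn.centrality_table(Gp)
        np.testing.assert_allclose(
            tabp.drop(columns="community").loc[list(G.labels)],
            tab.drop(columns="community"),
            rtol=1e-9, atol=1e-12,
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_strength_additivity(self, seed):
        rng = np.random.default_rng(seed)
        G = random_graph(rng, 7)
        comm = G.communities
        within = np.array([
            sum(abs(G.W[i, j]) for j in range(7) if comm[j] == comm[i])
            for i in range(7)
        ])
        np.testing.assert_allclose(
            sn.strength(G), within + sn.bridge_strength(G), atol=1e-12
        )
        assert (sn.bridge_betweenness(G) <= sn.betweenness(G) + 1e-12).all()
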