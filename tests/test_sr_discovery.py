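"""Successor representations, clustering, bottlenecks, and embedding."""

import itertools

import networkx as nx
import numpy as np
import pytest
import scipy.spatial.distance as ssd

from hrlplan.envs import CommunityGraph, load_edge_list
from hrlplan.options import detect_doorways, room_partition
from hrlplan.sr_discovery import (
    cluster_states,
    embed_mds,
    identify_bottlenecks,
    random_walk_transition_matrix,
    successor_representation,
    transition_model_from_exploration,
)


@pytest.fixture(scope="module")
def rooms_sr(rooms):
    T = random_walk_transition_matrix(rooms)
    return successor_representation(T, 0.95, states=rooms.free_states)


@pytest.fixture(scope="module")
def community_sr():
    g = load_edge_list("community15.edges")
    return g, successor_representation(
        g.transition_matrix(), 0.95, states=g.vertices
    )


class TestSuccessorRepresentation:
    def test_two_state_swap_chain_hand_values(self):
        """(I - 0.5 [[0,1],[1,0]])^-1 = [[4/3, 2/3], [2/3, 4/3]]."""
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        sr = successor_representation(T, 0.5)
        assert np.allclose(sr.matrix, [[4 / 3, 2 / 3], [2 / 3, 4 / 3]])

    def test_identity_chain(self):
        sr = successor_representation(np.eye(4), 0.8)
        assert np.allclose(sr.matrix, np.eye(4) / 0.2)

    def test_row_sums(self, rooms_sr):
        assert np.allclose(rooms_sr.matrix.sum(axis=1), 1 / (1 - 0.95), atol=1e-6)

    def test_fixed_point_identity(self, rooms, rooms_sr):
        T = random_walk_transition_matrix(rooms)
        M = rooms_sr.matrix
        assert np.abs(M - (np.eye(len(M)) + 0.95 * T @ M)).max() < 1e-6

    def test_matches_truncated_power_series(self, community_sr):
        g, sr = community_sr
        T = g.transition_matrix()
        M = np.zeros_like(T)
        term = np.eye(len(T))
        for _ in range(1000):
            M += term
            term = 0.95 * T @ term
        assert np.abs(M - sr.matrix).max() < 1e-6

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            successor_representation(np.ones((3, 3)), 0.9)

    def test_gamma_range_validated(self):
        with pytest.raises(ValueError):
            successor_representation(np.eye(2), 1.0)


class TestExplorationModel:
    def test_corridor_estimate_close_to_truth(self, corridor):
        T_true = random_walk_transition_matrix(corridor)
        T_hat, states = transition_model_from_exploration(corridor, 100_000, seed=0)
        assert states == corridor.free_states
        assert np.abs(T_hat - T_true).max() < 0.02

    def test_support_bound(self, rooms):
        T_hat, _ = transition_model_from_exploration(rooms, 150_000, seed=1)
        assert ((T_hat > 0).sum(axis=1) <= 5).all()

    def test_reproducible(self, corridor):
        a, _ = transition_model_from_exploration(corridor, 5000, seed=9)
        b, _ = transition_model_from_exploration(corridor, 5000, seed=9)
        assert np.array_equal(a, b)

    def test_unvisited_states_error(self, rooms):
        with pytest.raises(ValueError, match="unvisited"):
            transition_model_from_exploration(rooms, 10, seed=0)


class TestClustering:
    def test_disconnected_cliques_perfect_split(self):
        """Block-diagonal random-walk SR: silhouette picks k = 2 exactly."""
        T = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    if i != j:
                        T[i, j] = 0.5
        sr = successor_representation(T, 0.95)
        labels, k = cluster_states(sr, k_candidates=range(2, 5))
        assert k == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_rooms_clusters_align_with_rooms(self, rooms, rooms_sr):
        from sklearn.metrics import adjusted_rand_score

        labels, k = cluster_states(rooms_sr)
        assert k == 4
        room_of, doorways = room_partition(rooms)
        keep = [i for i, s in enumerate(rooms.free_states) if s not in set(doorways)]
        truth = [room_of[rooms.free_states[i]] for i in keep]
        assert adjusted_rand_score(truth, labels[keep]) >= 0.9

    def test_community_within_exceeds_between_similarity(self, community_sr):
        """Exhaustive: every within-community row pair is closer than every
        between-community pair."""
        g, sr = community_sr
        lab = g.community_labels
        M = sr.matrix
        within, between = [], []
        for i, j in itertools.combinations(range(len(M)), 2):
            d = np.linalg.norm(M[i] - M[j])
            (within if lab[g.vertices[i]] == lab[g.vertices[j]] else between).append(d)
        assert max(within) < min(between)

    def test_degenerate_matrix_rejected(self):
        sr = successor_representation(np.eye(5), 0.9)
        sr.matrix[:] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            cluster_states(sr, k_candidates=range(2, 4))


class TestBottlenecks:
    def test_bridge_vertex_found(self):
        """Two 3-cliques joined by one vertex: the bridge is the bottleneck,
        and it has the lowest brute-force silhouette."""
        from sklearn.metrics import silhouette_samples

        g = CommunityGraph(
            graph=nx.Graph(
                [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (4, 5), (4, 6), (5, 6)]
            )
        )
        sr = successor_representation(g.transition_matrix(), 0.95, states=g.vertices)
        labels, _ = cluster_states(sr, k_candidates=range(2, 6))
        found = identify_bottlenecks(sr, labels)
        assert found == [3]
        sil = silhouette_samples(sr.matrix, labels)
        assert np.argmin(sil) == 3

    def test_fully_connected_graph_empty(self):
        g = CommunityGraph(graph=nx.complete_graph(7))
        sr = successor_representation(g.transition_matrix(), 0.95)
        labels, _ = cluster_states(sr, k_candidates=range(2, 6))
        assert identify_bottlenecks(sr, labels) == []

    def test_rooms_bottlenecks_are_doorways(self, rooms, rooms_sr):
        labels, _ = cluster_states(rooms_sr)
        found = identify_bottlenecks(rooms_sr, labels)
        assert sorted(found) == detect_doorways(rooms)


class TestEmbedding:
    def test_equidistant_states_form_equilateral_triangle(self):
        sr = successor_representation(np.ones((3, 3)) / 3, 0.5)
        coords = embed_mds(sr)
        d = ssd.pdist(coords)
        assert np.allclose(d, d[0])
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-12)

    def test_block_structure_separates(self):
        T = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    if i != j:
                        T[i, j] = 0.5
        sr = successor_representation(T, 0.95)
        coords = embed_mds(sr)
        d = ssd.squareform(ssd.pdist(coords))
        within = max(d[0, 1], d[0, 2], d[3, 4], d[3, 5])
        between = min(d[i, j] for i in (0, 1, 2) for j in (3, 4, 5))
        assert between > within

    def test_full_dimensional_embedding_reconstructs_distances(self, rooms_sr):
        """Classical MDS with all positive-eigenvalue dimensions reproduces
        the row distances exactly (Euclidean input -> PSD Gram matrix)."""
        n = len(rooms_sr.states)
        coords = embed_mds(rooms_sr, n_components=n - 1)
        assert np.allclose(ssd.pdist(coords), ssd.pdist(rooms_sr.matrix), atol=1e-8)

    def test_planar_embedding_rank_preserving(self, rooms_sr):
        """The 2-D embedding keeps gross rank order of SR distances."""
        from scipy.stats import spearmanr

        coords = embed_mds(rooms_sr)
        rho = spearmanr(ssd.pdist(rooms_sr.matrix), ssd.pdist(coords)).statistic
        assert rho > 0.5

    def test_too_few_states_rejected(self):
        sr = successor_representation(np.eye(2), 0.9)
        with pytest.raises(ValueError):
            embed_mds(sr)


class TestSequenceSegmentation:
    def test_bridge_edges_have_largest_sr_dips(self, community_sr):
        """SR dissimilarity across each graph edge: every between-community
        bridge ranks above every within-community edge."""
        g, sr = community_sr
        idx = {v: i for i, v in enumerate(g.vertices)}
        lab = g.community_labels
        M = sr.matrix
        intra, bridge = [], []
        for u, v in g.graph.edges:
            d = np.linalg.norm(M[idx[u]] - M[idx[v]])
            (intra if lab[u] == lab[v] else bridge).append(d)
        assert min(bridge) > max(intra)
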