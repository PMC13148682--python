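"""Graph metrics on small graphs with enumerable answers, plus invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import netretest as nt
from oracles import (
    brute_betweenness,
    brute_clustering,
    brute_distances_and_counts,
    brute_global_efficiency,
    brute_mean_shortest_path,
)
from conftest import graph_from_weights


def star(n=5, w=0.5):
    W = np.zeros((n, n))
    W[0, 1:] = w
    W[1:, 0] = w
    return graph_from_weights(W)


def cycle4(w=0.5):
    W = np.zeros((4, 4))
    for i in range(4):
        W[i, (i + 1) % 4] = W[(i + 1) % 4, i] = w
    return graph_from_weights(W)


def complete(n=4, w=0.5):
    W = np.full((n, n), w)
    np.fill_diagonal(W, 0.0)
    return graph_from_weights(W)


def two_dyads():
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = 0.5
    W[2, 3] = W[3, 2] = 0.5
    return graph_from_weights(W)


class TestDegreeCentrality:
    def test_empty_graph_zero(self):
        G = graph_from_weights(np.zeros((3, 3)))
        assert np.all(nt.degree_centrality(G).values == 0.0)

    def test_triangle(self, triangle):
        assert np.allclose(nt.degree_centrality(triangle).values, 1.0)

    def test_signed_versus_absolute(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        W[0, 2] = W[2, 0] = -0.3
        G = graph_from_weights(W)
        assert nt.degree_centrality(G).values[0] == pytest.approx(0.1)
        assert nt.degree_centrality(G, absolute=True).values[0] == pytest.approx(0.7)


class TestClustering:
    def test_triangle_is_fully_clustered(self, triangle):
        assert np.allclose(nt.clustering_coefficient(triangle).values, 1.0)

    def test_star_has_no_triangles(self):
        assert np.all(nt.clustering_coefficient(star()).values == 0.0)

    def test_cycle4_has_no_triangles(self):
        assert np.all(nt.clustering_coefficient(cycle4()).values == 0.0)


class TestHopDistances:
    def test_complete_graph_all_ones(self):
        D, sigma = nt.shortest_hop_distances(complete(4))
        off = ~np.eye(4, dtype=bool)
        assert np.all(D[off] == 1.0)
        assert np.all(sigma[off] == 1.0)

    def test_path_graph(self, path3):
        D, sigma = nt.shortest_hop_distances(path3)
        assert D[0, 2] == 2.0
        assert sigma[0, 2] == 1.0

    def test_disconnected_pairs_infinite(self):
        D, sigma = nt.shortest_hop_distances(two_dyads())
        assert np.isinf(D[0, 2])
        assert sigma[0, 2] == 0.0

    def test_cycle_has_two_shortest_paths_across(self):
        _, sigma = nt.shortest_hop_distances(cycle4())
        assert sigma[0, 2] == 2.0


class TestBetweenness:
    def test_path_center_carries_all_traffic(self, path3):
        b = nt.betweenness_centrality(path3).values
        assert b[1] == pytest.approx(1.0)
        assert b[0] == b[2] == 0.0

    def test_complete_graph_zero(self):
        assert np.all(nt.betweenness_centrality(complete(5)).values == 0.0)

    def test_star_center_is_maximal(self):
        b = nt.betweenness_centrality(star(5)).values
        assert b[0] == pytest.approx(1.0)
        assert np.all(b[1:] == 0.0)


class TestGraphLevelMetrics:
    def test_complete_graph_efficiency_one(self):
        assert nt.global_efficiency(complete(4)) == pytest.approx(1.0)

    def test_empty_graph_efficiency_zero(self):
        assert nt.global_efficiency(graph_from_weights(np.zeros((4, 4)))) == 0.0

    def test_path3_efficiency(self, path3):
        assert nt.global_efficiency(path3) == pytest.approx(5.0 / 6.0)

    def test_complete_graph_path_length_one(self):
        mspl, excluded = nt.mean_shortest_path_length(complete(4))
        assert mspl == pytest.approx(1.0)
        assert excluded == 0

    def test_path3_path_length(self, path3):
        mspl, _ = nt.mean_shortest_path_length(path3)
        assert mspl == pytest.approx(4.0 / 3.0)

    def test_disconnected_pairs_excluded_and_counted(self):
        mspl, excluded = nt.mean_shortest_path_length(two_dyads())
        assert mspl == pytest.approx(1.0)
        assert excluded == 4

    def test_fully_disconnected_returns_zero(self, caplog):
        mspl, excluded = nt.mean_shortest_path_length(
            graph_from_weights(np.zeros((3, 3)))
        )
        assert mspl == 0.0
        assert excluded == 3


class TestScanSummary:
    def test_triangle_summary(self, triangle):
        rec = nt.scan_summary(triangle)
        assert rec.degree_centrality == pytest.approx(1.0)
        assert rec.clustering_coefficient == pytest.approx(1.0)
        assert rec.betweenness_centrality == 0.0
        assert rec.global_efficiency == pytest.approx(1.0)
        assert rec.mean_shortest_path_length == pytest.approx(1.0)
        assert rec.n_edges == 3

    def test_empty_graph_summary(self):
        rec = nt.scan_summary(graph_from_weights(np.zeros((3, 3))))
        for name in nt.METRIC_NAMES:
            assert getattr(rec, name) == 0.0
        assert rec.n_disconnected_pairs == 3

    def test_summary_equals_mean_of_nodal_vector(self, rng):
        W = random_graph(rng, 7)
        G = graph_from_weights(W)
        rec = nt.scan_summary(G)
        assert rec.degree_centrality == pytest.approx(
            nt.degree_centrality(G).values.mean(), abs=1e-12
        )
        assert rec.betweenness_centrality == pytest.approx(
            nt.betweenness_centrality(G).values.mean(), abs=1e-12
        )


def random_graph(rng, n, p=0.5, grid=(-0.5, 0.3, 0.7)):
    W = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p
    vals = rng.choice(grid, size=iu.size)
    W[iu[mask], ju[mask]] = vals[mask]
    W[ju[mask], iu[mask]] = vals[mask]
    return W


class TestAgainstOracles:
    """Spot checks against the brute-force enumeration oracle (the full
    sweep lives in the acceptance suite)."""

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_random_graphs_match_brute_force(self, n, rng):
        for _ in range(25):
            W = random_graph(rng, n)
            G = graph_from_weights(W)
            adj = G.support
            D, sigma = nt.shortest_hop_distances(G)
            bD, bsigma = brute_distances_and_counts(adj)
            assert np.array_equal(D, bD)
            assert np.array_equal(sigma, bsigma)
            assert np.allclose(
                nt.betweenness_centrality(G).values, brute_betweenness(adj),
                atol=1e-12,
            )
            assert np.allclose(
                nt.clustering_coefficient(G).values, brute_clustering(adj),
                atol=1e-12,
            )
            assert nt.global_efficiency(G) == pytest.approx(
                brute_global_efficiency(adj), abs=1e-12
            )
            mspl, exc = nt.mean_shortest_path_length(G)
            bmspl, bexc = brute_mean_shortest_path(adj)
            assert mspl == pytest.approx(bmspl, abs=1e-12)
            assert exc == bexc

    def test_networkx_cross_check(self, rng):
        nx = pytest.importorskip("networkx")
        for n in (5, 8, 12):
            W = random_graph(rng, n)
            G = graph_from_weights(W)
            H = nx.from_numpy_array(G.support.astype(int))
            nx_b = np.array([v for _, v in sorted(
                nx.betweenness_centrality(H, normalized=True).items())])
            assert np.allclose(nt.betweenness_centrality(G).values, nx_b, atol=1e-10)
            nx_c = np.array([v for _, v in sorted(nx.clustering(H).items())])
            assert np.allclose(nt.clustering_coefficient(G).values, nx_c, atol=1e-10)
            assert nt.global_efficiency(G) == pytest.approx(
                nx.global_efficiency(H), abs=1e-10)


@given(st.integers(0, 2**31 - 1), st.integers(4, 8))
def test_permutation_equivariance(seed, n):
    """Relabelling nodes permutes nodal vectors and fixes graph-level scalars."""
    rng = np.random.default_rng(seed)
    W = random_graph(rng, n)
    perm = rng.permutation(n)
    G = graph_from_weights(W)
    Gp = graph_from_weights(W[np.ix_(perm, perm)])
    for fn in (nt.degree_centrality, nt.clustering_coefficient,
               nt.betweenness_centrality):
        assert np.allclose(fn(G).values[perm], fn(Gp).values, atol=1e-12)
    assert nt.global_efficiency(G) == pytest.approx(nt.global_efficiency(Gp))
    assert nt.mean_shortest_path_length(G)[0] == pytest.approx(
        nt.mean_shortest_path_length(Gp)[0])


@given(st.integers(0, 2**31 - 1))
def test_efficiency_at_least_inverse_path_length(seed):
    """Jensen: mean(1/d) >= 1/mean(d) on connected graphs."""
    rng = np.random.default_rng(seed)
    W = random_graph(rng, 6, p=0.7)
    G = graph_from_weights(W)
    D, _ = nt.shortest_hop_distances(G)
    if np.isinf(D).any():
        return  # only a connected-graph property
    mspl, _ = nt.mean_shortest_path_length(G)
    assert nt.global_efficiency(G) >= 1.0 / mspl - 1e-12
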