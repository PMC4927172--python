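"""Graph metrics against exhaustive brute-force oracles."""

import numpy as np
import pytest

from conftest import (
    brute_clustering,
    brute_global_efficiency,
    brute_local_efficiency,
    brute_path_length,
    exhaustive_max_modularity,
    random_graph_adjacency,
    random_symmetric,
)
from waveconn.connectivity import ConnectivityMatrix
from waveconn.graphs import (
    BinaryGraph,
    Partition,
    characteristic_path_length,
    clustering_coefficient,
    compute_all_metrics,
    consensus_partition,
    global_efficiency,
    local_efficiency,
    louvain_modularity,
    modularity_q,
    threshold_to_density,
)


def _graph(edges, n):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryGraph(a, density=a.sum() / (n * (n - 1)))


TRIANGLE = _graph([(0, 1), (1, 2), (0, 2)], 3)
STAR4 = _graph([(0, 1), (0, 2), (0, 3)], 4)
PATH3 = _graph([(0, 1), (1, 2)], 3)
K5 = BinaryGraph(1 - np.eye(5, dtype=int), 1.0)
TWO_TRIANGLES = _graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6)


# -- thresholding -----------------------------------------------------------

def test_threshold_edge_counts(rng):
    w5 = random_symmetric(5, rng)
    assert threshold_to_density(w5, 0.3).n_edges == 3
    w90 = random_symmetric(90, rng)
    assert threshold_to_density(w90, 0.3).n_edges == 1202


def test_threshold_keeps_strongest_or_weakest(rng):
    w = random_symmetric(8, rng)
    gs = threshold_to_density(w, 0.25)
    gw = threshold_to_density(w, 0.25, mode="weakest")
    iu = np.triu_indices(8, k=1)
    kept_s = w[iu][gs.adjacency[iu] == 1]
    kept_w = w[iu][gw.adjacency[iu] == 1]
    assert kept_s.min() >= np.sort(w[iu])[-7]
    assert kept_w.max() <= np.sort(w[iu])[6]


def test_threshold_tie_determinism():
    w = np.ones((6, 6))
    g1 = threshold_to_density(w, 0.5)
    g2 = threshold_to_density(w, 0.5)
    np.testing.assert_array_equal(g1.adjacency, g2.adjacency)
    assert g1.n_edges == round(0.5 * 15)


def test_threshold_rejects_zero_edges():
    with pytest.raises(ValueError):
        threshold_to_density(np.eye(5), 0.01)


# -- closed-form metric examples --------------------------------------------

def test_metric_closed_forms():
    assert clustering_coefficient(TRIANGLE) == pytest.approx(1.0)
    assert clustering_coefficient(STAR4) == pytest.approx(0.0)
    assert characteristic_path_length(PATH3) == pytest.approx(4.0 / 3.0)
    assert characteristic_path_length(K5) == pytest.approx(1.0)
    assert characteristic_path_length(TWO_TRIANGLES) == pytest.approx(1.0)
    assert global_efficiency(K5) == pytest.approx(1.0)
    assert global_efficiency(PATH3) == pytest.approx(5.0 / 6.0)
    assert global_efficiency(_graph([], 4)) == 0.0
    assert local_efficiency(BinaryGraph(1 - np.eye(4, dtype=int), 1.0)) \
        == pytest.approx(1.0)
    assert local_efficiency(STAR4) == pytest.approx(0.0)
    assert np.isnan(characteristic_path_length(_graph([], 4)))


def test_metrics_match_bruteforce_on_random_graphs(rng):
    """200 random graphs, n <= 12: exact agreement with enumeration."""
    for _ in range(200):
        n = int(rng.integers(4, 13))
        p = float(rng.uniform(0.15, 0.8))
        adj = random_graph_adjacency(n, p, rng)
        g = BinaryGraph(adj, density=0.5)
        assert clustering_coefficient(g) == pytest.approx(
            brute_clustering(adj), abs=1e-12)
        cpl, ref = characteristic_path_length(g), brute_path_length(adj)
        assert (np.isnan(cpl) and np.isnan(ref)) or cpl == pytest.approx(ref)
        assert global_efficiency(g) == pytest.approx(
            brute_global_efficiency(adj), abs=1e-12)
        assert local_efficiency(g) == pytest.approx(
            brute_local_efficiency(adj), abs=1e-12)


def test_efficiency_monotone_in_edges(rng):
    """Adding an edge never decreases global efficiency."""
    for _ in range(20):
        adj = random_graph_adjacency(10, 0.3, rng)
        g = BinaryGraph(adj, 0.3)
        zeros = np.argwhere(np.triu(adj == 0, k=1))
        i, j = zeros[rng.integers(len(zeros))]
        adj2 = adj.copy()
        adj2[i, j] = adj2[j, i] = 1
        assert global_efficiency(BinaryGraph(adj2, 0.3)) >= \
            global_efficiency(g) - 1e-12


def test_metrics_invariant_under_relabeling(rng):
    adj = random_graph_adjacency(12, 0.4, rng)
    perm = rng.permutation(12)
    padj = adj[np.ix_(perm, perm)]
    for fn in (clustering_coefficient, characteristic_path_length,
               global_efficiency, local_efficiency):
        assert fn(BinaryGraph(adj, 0.4)) == pytest.approx(
            fn(BinaryGraph(padj, 0.4)), abs=1e-12)


# -- modularity --------------------------------------------------------------

def test_two_triangles_modularity():
    q, parts = louvain_modularity(TWO_TRIANGLES, n_restarts=20, seed=4)
    assert q == pytest.approx(0.5, abs=1e-12)
    assert all(p.n_communities == 2 for p in parts)


def test_complete_graph_modularity():
    g = BinaryGraph(1 - np.eye(6, dtype=int), 1.0)
    assert modularity_q(g.adjacency, np.zeros(6, dtype=int)) \
        == pytest.approx(0.0, abs=1e-12)
    q, _ = louvain_modularity(g, n_restarts=20, seed=0)
    assert q >= -1e-12


def test_louvain_bounded_by_exhaustive_maximum():
    """Mean Q never exceeds the exhaustive optimum; usually attains it."""
    rng = np.random.default_rng(20260924)  # fixed graph set
    hits = trials = 0
    for _ in range(15):
        adj = random_graph_adjacency(int(rng.integers(5, 9)), 0.5, rng)
        if adj.sum() == 0:
            continue
        qmax = exhaustive_max_modularity(adj)
        _, parts = louvain_modularity(BinaryGraph(adj, 0.5), n_restarts=20,
                                      seed=9)
        for p in parts:
            trials += 1
            assert p.quality <= qmax + 1e-10
            hits += p.quality >= qmax - 1e-10
    assert hits / trials >= 0.9


def test_louvain_seed_reproducible():
    g = TWO_TRIANGLES
    q1, p1 = louvain_modularity(g, n_restarts=5, seed=123)
    q2, p2 = louvain_modularity(g, n_restarts=5, seed=123)
    assert q1 == q2
    for a, b in zip(p1, p2):
        np.testing.assert_array_equal(a.community_ids, b.community_ids)


def test_louvain_rejects_edgeless():
    with pytest.raises(ValueError):
        louvain_modularity(_graph([], 4), 5, 0)


# -- consensus ----------------------------------------------------------------

def test_consensus_of_identical_partitions_is_fixed_point():
    labels = np.array([0, 0, 1, 1, 2, 2])
    parts = [Partition(labels.copy()) for _ in range(10)]
    cons = consensus_partition(parts, seed=0)
    assert cons.n_communities == 3
    same = labels[:, None] == labels[None, :]
    out = cons.community_ids
    np.testing.assert_array_equal(out[:, None] == out[None, :], same)


def test_consensus_recovers_planted_groups_under_label_noise(rng):
    """10% reassignment noise on two planted groups is averaged away."""
    truth = np.repeat([0, 1], 10)
    parts = []
    for _ in range(40):
        lab = truth.copy()
        flip = rng.random(20) < 0.1
        lab[flip] = rng.integers(0, 2, flip.sum())
        parts.append(Partition(lab))
    cons = consensus_partition(parts, seed=5)
    assert cons.n_communities == 2
    same = truth[:, None] == truth[None, :]
    out = cons.community_ids
    np.testing.assert_array_equal(out[:, None] == out[None, :], same)


def test_consensus_of_two_triangle_partitions():
    _, parts = louvain_modularity(TWO_TRIANGLES, n_restarts=10, seed=1)
    cons = consensus_partition(parts, seed=2)
    assert cons.n_communities == 2


# -- assembled record ---------------------------------------------------------

def test_compute_all_metrics_two_block_matrix():
    """Two perfectly correlated blocks give a two-community network."""
    n = 12
    labels = np.repeat([0, 1], n // 2)
    vals = np.where(labels[:, None] == labels[None, :], 0.9, 0.05)
    np.fill_diagonal(vals, 1.0)
    cm = ConnectivityMatrix(vals, scale=2)
    rec = compute_all_metrics(cm, density=0.4, seed=0)
    assert rec.n_communities == 2
    assert rec.mean_corr == pytest.approx(
        np.mean(vals[np.triu_indices(n, k=1)]))
    assert 0.0 <= rec.clustering <= 1.0


def test_compute_all_metrics_finite_on_random_matrices(rng):
    for _ in range(10):
        cm = ConnectivityMatrix(random_symmetric(20, rng), scale=1)
        rec = compute_all_metrics(cm, density=0.3, seed=1,
                                  n_null_permutations=5, n_restarts=5)
        vals = rec.as_dict()
        assert all(np.isfinite(v) for v in vals.values())
        assert 1 <= rec.n_communities <= 20
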