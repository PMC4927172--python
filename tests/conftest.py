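"""Shared fixtures and brute-force oracles for the test suite."""

from itertools import combinations

import numpy as np
import pytest

from waveconn.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 6+6-subject cohort sharing the default signal structure."""
    return generate_cohort(CohortSpec(n_per_group=6, n_regions=30, seed=11))


def random_symmetric(n, rng):
    w = rng.standard_normal((n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return w


def random_graph_adjacency(n, p, rng):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, k=1)
    return a + a.T


# ---------------------------------------------------------------------------
# Brute-force graph-metric oracles (independent of the implementation)

def brute_clustering(adj):
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        k = nbrs.size
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(adj[j, h] for j, h in combinations(nbrs, 2))
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def brute_distances(adj):
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for src in range(n):
        frontier = [src]
        dist = 0
        while frontier:
            dist += 1
            nxt = []
            for u in frontier:
                for v in np.nonzero(adj[u])[0]:
                    if d[src, v] == np.inf:
                        d[src, v] = dist
                        nxt.append(v)
            frontier = nxt
    return d


def brute_path_length(adj):
    d = brute_distances(adj)
    n = adj.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def brute_global_efficiency(adj):
    d = brute_distances(adj)
    n = adj.shape[0]
    tot = sum(1.0 / d[i, j] for i in range(n) for j in range(n)
              if i != j and np.isfinite(d[i, j]))
    return tot / (n * (n - 1))


def brute_local_efficiency(adj):
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        k = nbrs.size
        if k < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += brute_global_efficiency(sub)
    return total / n


def exhaustive_max_modularity(adj):
    """Maximum modularity over every partition of a tiny node set."""
    from waveconn.graphs import modularity_q

    n = adj.shape[0]

    def partitions(nodes):
        if not nodes:
            yield []
            return
        first, rest = nodes[0], nodes[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [first]] + part[i + 1:]
            yield part + [[first]]

    best = -np.inf
    for part in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for cid, block in enumerate(part):
            labels[block] = cid
        best = max(best, modularity_q(adj, labels))
    return best
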