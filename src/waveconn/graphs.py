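"""Density thresholding and graph-theoretic network summaries.

Connectivity matrices are binarised by keeping a fixed proportion of the
strongest edges (cumulative thresholding at 30% density by default) and
summarised by clustering coefficient, characteristic path length, global
and local efficiency, Louvain modularity (mean Q over seeded restarts)
and the number of communities in a consensus partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from waveconn.connectivity import ConnectivityMatrix, summary_weighted_metrics

__all__ = [
    "BinaryGraph",
    "Partition",
    "GraphMetricRecord",
    "threshold_to_density",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "modularity_q",
    "louvain_modularity",
    "consensus_partition",
    "compute_all_metrics",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "mean_corr",
    "var_corr",
    "clustering",
    "char_path_length",
    "global_eff",
    "local_eff",
    "modularity_q",
    "n_communities",
)


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    density: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_nodes))
        G.add_edges_from(zip(*np.nonzero(np.triu(self.adjacency, k=1))))
        return G

    def export_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("i\tj\n")
            for i, j in zip(*np.nonzero(np.triu(self.adjacency, k=1))):
                fh.write(f"{i}\t{j}\n")


@dataclass
class Partition:
    """Assignment of each node to a community, with its quality Q."""

    community_ids: np.ndarray
    quality: float = float("nan")

    def __post_init__(self):
        self.community_ids = _relabel_contiguous(np.asarray(self.community_ids))

    @property
    def n_communities(self) -> int:
        return int(self.community_ids.max()) + 1 if self.community_ids.size else 0

    def export(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node\tcommunity\n")
            for i, c in enumerate(self.community_ids):
                fh.write(f"{i}\t{c}\n")


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out.astype(int)


@dataclass
class GraphMetricRecord:
    """The eight scalar network summaries of one thresholded matrix."""

    mean_corr: float
    var_corr: float
    clustering: float
    char_path_length: float
    global_eff: float
    local_eff: float
    modularity_q: float
    n_communities: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def threshold_to_density(
    m: ConnectivityMatrix | np.ndarray, density: float, mode: str = "strongest"
) -> BinaryGraph:
    """Binarise by keeping a fixed fraction of the ranked edge weights.

    Keeps the ``round(density * M)`` most positive (``strongest``) or
    least positive (``weakest``) of the ``M = n(n-1)/2`` signed weights.
    Rounding is half-away-from-zero and ties between equal weights are
    broken by lexicographic (i, j) order, so the edge set is
    deterministic.
    """
    values = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m)
    n = values.shape[0]
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    M = w.size
    k = int(np.floor(density * M + 0.5))  # round half away from zero (all positive)
    if k == 0:
        raise ValueError(f"density {density} keeps zero of {M} edges")
    if mode == "strongest":
        order = np.lexsort((ju, iu, -w))
    elif mode == "weakest":
        order = np.lexsort((ju, iu, w))
    else:
        raise ValueError("mode must be 'strongest' or 'weakest'")
    keep = order[:k]
    adj = np.zeros((n, n), dtype=int)
    adj[iu[keep], ju[keep]] = 1
    adj += adj.T
    return BinaryGraph(adjacency=adj, density=density)


def clustering_coefficient(g: BinaryGraph) -> float:
    """Mean local clustering; nodes with degree < 2 contribute zero."""
    A = g.adjacency
    deg = g.degrees()
    triangles = np.diag(A @ A @ A)  # 2 * number of closed triples at each node
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return float(np.mean(c))


def _geodesics(adj: np.ndarray) -> np.ndarray:
    return shortest_path(adj.astype(float), method="D", unweighted=True)


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean geodesic over connected vertex pairs, pooled across components.

    Averages d_ij over ordered pairs of distinct vertices that lie in the
    same connected component (denominator sum_m n_m (n_m - 1)).  Returns
    NaN when no such pair exists (all nodes isolated).
    """
    d = _geodesics(g.adjacency)
    n = g.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        return float("nan")
    return float(d[finite].mean())


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse geodesic over all ordered pairs (1/inf = 0)."""
    n = g.n_nodes
    if n < 2:
        return 0.0
    d = _geodesics(g.adjacency)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def local_efficiency(g: BinaryGraph) -> float:
    """Mean over nodes of the efficiency of the neighbour-induced subgraph.

    Geodesics are computed inside the subgraph induced by each node's
    neighbours; nodes of degree < 2 contribute zero.
    """
    A = g.adjacency
    total = 0.0
    for i in range(g.n_nodes):
        nbrs = np.nonzero(A[i])[0]
        k = nbrs.size
        if k < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        d = _geodesics(sub)
        off = ~np.eye(k, dtype=bool)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        total += inv[off].sum() / (k * (k - 1))
    return float(total / g.n_nodes)


def modularity_q(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity Q = (1/2l) sum_ij (A_ij - k_i k_j / 2l) delta(c_i, c_j)."""
    A = np.asarray(adjacency, dtype=float)
    labels = np.asarray(labels)
    two_l = A.sum()
    if two_l == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    k = A.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((A - np.outer(k, k) / two_l) * same).sum() / two_l)


def louvain_modularity(
    g: BinaryGraph, n_restarts: int = 20, seed: int = 0, reducer: str = "mean"
) -> tuple[float, list[Partition]]:
    """Louvain community detection over seeded restarts.

    Runs the Louvain heuristic ``n_restarts`` times with distinct seeds,
    scores each partition with :func:`modularity_q`, and reduces the Q
    values by ``mean`` (default) or ``max``.
    """
    if g.n_edges == 0:
        raise ValueError("Louvain requires at least one edge")
    G = g.to_networkx()
    return _louvain_restarts(G, g.adjacency, n_restarts, seed, reducer)


def _louvain_restarts(G, adjacency, n_restarts, seed, reducer, weight=None):
    rng = np.random.default_rng(seed)
    partitions = []
    qs = []
    for _ in range(n_restarts):
        comms = nx.community.louvain_communities(
            G, weight=weight, seed=int(rng.integers(2**31 - 1))
        )
        labels = np.empty(adjacency.shape[0], dtype=int)
        for cid, nodes in enumerate(comms):
            for node in nodes:
                labels[node] = cid
        q = modularity_q(adjacency, labels)
        partitions.append(Partition(labels, q))
        qs.append(q)
    red = np.mean if reducer == "mean" else np.max
    return float(red(qs)), partitions


def allegiance_matrix(partitions: list[Partition]) -> np.ndarray:
    """Fraction of partitions assigning each node pair to one community."""
    mats = []
    for p in partitions:
        lab = p.community_ids
        mats.append((lab[:, None] == lab[None, :]).astype(float))
    return np.mean(mats, axis=0)


def consensus_partition(
    partitions: list[Partition],
    n_null_permutations: int = 100,
    seed: int = 0,
    max_iter: int = 20,
    n_restarts: int = 20,
) -> Partition:
    """Consensus community assignment across stochastic optimisations.

    Builds the module-allegiance matrix, zeroes entries at or below the
    expectation under randomly permuted community labels, re-clusters the
    thresholded matrix with Louvain, and iterates until every restart
    returns the same partition (or the iteration cap is reached, in
    which case the last iterate is returned with ``quality = nan`` left
    untouched and a warning flag on the instance).
    """
    if len(partitions) < 2:
        raise ValueError("need at least two partitions for a consensus")
    rng = np.random.default_rng(seed)
    n = partitions[0].community_ids.size

    # Null expectation of allegiance from label-permuted copies of the
    # same partitions: permuting node assignments preserves community
    # sizes but destroys identity, so the null level depends only on the
    # size distribution.
    null_vals = []
    for _ in range(n_null_permutations):
        permuted = [
            Partition(p.community_ids[rng.permutation(n)]) for p in partitions
        ]
        am = allegiance_matrix(permuted)
        null_vals.append(am[np.triu_indices(n, k=1)].mean())
    tau = float(np.mean(null_vals))

    current = partitions
    for _ in range(max_iter):
        am = allegiance_matrix(current)
        thresh = np.where(am > tau, am, 0.0)
        np.fill_diagonal(thresh, 0.0)
        if thresh.sum() == 0:  # fully fragmented: everyone their own community
            return Partition(np.arange(n))
        G = nx.from_numpy_array(thresh)
        _, current = _louvain_restarts(
            G, thresh, n_restarts, int(rng.integers(2**31 - 1)), "mean",
            weight="weight",
        )
        first = current[0].community_ids
        if all(np.array_equal(first, p.community_ids) for p in current[1:]):
            return current[0]
    out = current[0]
    out.converged = False
    return out


def compute_all_metrics(
    m: ConnectivityMatrix,
    density: float = 0.30,
    mode: str = "strongest",
    n_restarts: int = 20,
    seed: int = 0,
    reducer: str = "mean",
    n_null_permutations: int = 20,
) -> GraphMetricRecord:
    """Threshold a connectivity matrix and assemble all eight summaries."""
    mean_corr, var_corr = summary_weighted_metrics(m)
    g = threshold_to_density(m, density, mode)
    q, partitions = louvain_modularity(g, n_restarts=n_restarts, seed=seed,
                                       reducer=reducer)
    cons = consensus_partition(
        partitions, n_null_permutations=n_null_permutations, seed=seed + 1,
        n_restarts=n_restarts,
    )
    return GraphMetricRecord(
        mean_corr=mean_corr,
        var_corr=var_corr,
        clustering=clustering_coefficient(g),
        char_path_length=characteristic_path_length(g),
        global_eff=global_efficiency(g),
        local_eff=local_efficiency(g),
        modularity_q=q,
        n_communities=cons.n_communities,
    )
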