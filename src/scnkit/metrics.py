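"""Binary-graph measures and the degree-preserving random-network reference.

Conventions for disconnected graphs (FDR-thresholded covariance networks are
frequently disconnected):

* characteristic path length averages each node's mean distance to its
  *reachable* partners, then averages over nodes with at least one reachable
  partner; a fully edgeless graph has no defined path length and raises
  :class:`MetricUndefinedError`;
* efficiencies use the Latora-Marchiori convention 1/inf = 0 for
  unreachable pairs, so they are always defined (edgeless -> 0).

Small-worldness is assessed against degree-matched random networks obtained
by Maslov-Sneppen double-edge swaps: gamma = C/<C_rand>, lambda = L/<L_rand>,
sigma = gamma/lambda, with the means taken over the reference set.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .io import BinaryNetwork

__all__ = [
    "MetricUndefinedError",
    "GlobalMetrics",
    "NodalMetrics",
    "SmallWorld",
    "RandomReference",
    "clustering_coefficients",
    "mean_clustering",
    "distance_matrix",
    "characteristic_path_length",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "betweenness",
    "degree_preserving_randomization",
    "random_reference",
    "small_world",
    "global_metrics",
    "nodal_metrics",
]


class MetricUndefinedError(ValueError):
    """A graph metric is undefined for this input (e.g. edgeless graph)."""


def _adj(net) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency
    return np.asarray(net, dtype=np.int8)


# ---------------------------------------------------------------------------
# clustering

def clustering_coefficients(net) -> np.ndarray:
    """Per-node clustering coefficient: 2*triangles / (k*(k-1)); 0 if k < 2."""
    a = _adj(net).astype(np.float64)
    deg = a.sum(axis=0)
    tri = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def mean_clustering(net) -> float:
    return float(clustering_coefficients(net).mean())


# ---------------------------------------------------------------------------
# distances

def distance_matrix(net) -> np.ndarray:
    """All-pairs shortest-path lengths in edges; inf for unreachable pairs."""
    a = _adj(net)
    d = shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)
    return d


def characteristic_path_length(net, d: np.ndarray | None = None) -> float:
    """Mean over nodes of the mean distance to reachable partners.

    Unreachable pairs are excluded; nodes with no reachable partner are
    excluded from the outer mean. Raises :class:`MetricUndefinedError` on an
    edgeless graph.
    """
    if d is None:
        d = distance_matrix(net)
    n = d.shape[0]
    dd = d.copy()
    np.fill_diagonal(dd, np.inf)
    finite = np.isfinite(dd)
    reach = finite.sum(axis=1)
    has = reach > 0
    if not has.any():
        raise MetricUndefinedError("path length undefined for an edgeless graph")
    per_node = np.where(has, np.where(finite, dd, 0.0).sum(axis=1) / np.maximum(reach, 1), np.nan)
    return float(per_node[has].mean())


def _inverse_distances(d: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(d)
    mask = np.isfinite(d) & (d > 0)
    inv[mask] = 1.0 / d[mask]
    np.fill_diagonal(inv, 0.0)
    return inv


def nodal_efficiency(net, d: np.ndarray | None = None) -> np.ndarray:
    """Per-node mean inverse distance to every other node (1/inf = 0)."""
    if d is None:
        d = distance_matrix(net)
    n = d.shape[0]
    if n < 2:
        return np.zeros(n)
    return _inverse_distances(d).sum(axis=1) / (n - 1)


def global_efficiency(net, d: np.ndarray | None = None) -> float:
    """Mean inverse shortest-path length over all ordered node pairs."""
    if d is None:
        d = distance_matrix(net)
    n = d.shape[0]
    if n < 2:
        return 0.0
    return float(_inverse_distances(d).sum() / (n * (n - 1)))


def _bfs_distances(adj_bool: np.ndarray) -> np.ndarray:
    """All-pairs BFS distances of a small boolean adjacency (inf = unreachable)."""
    k = adj_bool.shape[0]
    dist = np.full((k, k), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(k, dtype=bool)
    frontier = np.eye(k, dtype=bool)
    d = 0
    while True:
        d += 1
        frontier = (frontier @ adj_bool) & ~reached
        if not frontier.any():
            return dist
        dist[frontier] = d
        reached |= frontier


def local_efficiency(net):
    """Per-node and mean local efficiency.

    The local efficiency of a node is the global efficiency of the subgraph
    induced by its neighbours (the node itself excluded); nodes with fewer
    than two neighbours score 0.
    """
    a = _adj(net)
    ab = a.astype(bool)
    n = a.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            continue
        sub = ab[np.ix_(nbrs, nbrs)]
        d = _bfs_distances(sub)
        inv = np.zeros_like(d)
        m = np.isfinite(d) & (d > 0)
        inv[m] = 1.0 / d[m]
        per_node[i] = inv.sum() / (k * (k - 1))
    return per_node, float(per_node.mean())


def betweenness(net) -> tuple[np.ndarray, np.ndarray]:
    """(normalized, raw) betweenness centrality per node.

    Raw values are Brandes' sum over unordered source/target pairs of the
    fraction of shortest paths through the node; normalization divides by
    (n-1)(n-2)/2 so values lie in [0, 1].
    """
    a = _adj(net)
    n = a.shape[0]
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=True)
    norm = np.array([bc[i] for i in range(n)])
    raw = norm * ((n - 1) * (n - 2) / 2.0)
    return norm, raw


# ---------------------------------------------------------------------------
# degree-preserving null model

def degree_preserving_randomization(net, rng: np.random.Generator, attempts: int | None = None):
    """One Maslov-Sneppen randomization of a binary undirected graph.

    Performs ``attempts`` double-edge-swap proposals (default 10*|edges|),
    rejecting any swap that would create a self-loop or a multi-edge.

    Returns ``(adjacency, n_successful_swaps)``.
    """
    a = _adj(net)
    n = a.shape[0]
    iu, ju = np.triu_indices(n, 1)
    sel = a[iu, ju] > 0
    edges = list(zip(iu[sel].tolist(), ju[sel].tolist()))
    m = len(edges)
    if m == 0:
        raise MetricUndefinedError("cannot randomize an edgeless graph")
    if attempts is None:
        attempts = 10 * m
    eset = set(edges)
    picks = rng.integers(0, m, size=(attempts, 2))
    flips = rng.random(attempts) < 0.5
    successes = 0
    for t in range(attempts):
        e1, e2 = picks[t]
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flips[t]:
            x, y = y, x
        # propose (u, x) and (v, y)
        if u == x or v == y:
            continue
        new1 = (u, x) if u < x else (x, u)
        new2 = (v, y) if v < y else (y, v)
        if new1 == new2 or new1 in eset or new2 in eset:
            continue
        eset.discard(edges[e1])
        eset.discard(edges[e2])
        eset.add(new1)
        eset.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        successes += 1
    out = np.zeros((n, n), dtype=np.int8)
    for u, v in eset:
        out[u, v] = 1
        out[v, u] = 1
    return out, successes


@dataclass
class RandomReference:
    """Clustering and path length of each degree-matched random network."""

    c_rand: np.ndarray
    l_rand: np.ndarray
    n_swaps: np.ndarray
    flagged: bool  # True if any reference could not be rewired at all


def random_reference(net, n_random: int = 100, seed=None, rng: np.random.Generator | None = None) -> RandomReference:
    """Distribution of (C, L) over degree-preserving random references.

    Each reference preserves node count, edge count and the exact degree
    sequence of the input. ``flagged`` is set when a reference underwent no
    successful swap (e.g. complete graphs admit none) and therefore equals
    the input.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    cs, ls, sw = [], [], []
    for _ in range(n_random):
        ar, n_sw = degree_preserving_randomization(net, rng)
        cs.append(mean_clustering(ar))
        ls.append(characteristic_path_length(ar))
        sw.append(n_sw)
    return RandomReference(
        c_rand=np.array(cs), l_rand=np.array(ls), n_swaps=np.array(sw),
        flagged=bool((np.array(sw) == 0).any()),
    )


@dataclass
class SmallWorld:
    gamma: float
    lambda_: float
    sigma: float
    c_rand_mean: float
    l_rand_mean: float
    flagged: bool


def small_world(net, n_random: int = 100, seed=None, rng=None) -> SmallWorld:
    """gamma = C/<C_rand>, lambda = L/<L_rand>, sigma = gamma/lambda."""
    ref = random_reference(net, n_random=n_random, seed=seed, rng=rng)
    c_rand = float(ref.c_rand.mean())
    l_rand = float(ref.l_rand.mean())
    if c_rand == 0:
        raise MetricUndefinedError("mean random-reference clustering is zero")
    c = mean_clustering(net)
    l = characteristic_path_length(net)
    gamma = c / c_rand
    lambda_ = l / l_rand
    return SmallWorld(
        gamma=gamma, lambda_=lambda_, sigma=gamma / lambda_,
        c_rand_mean=c_rand, l_rand_mean=l_rand, flagged=ref.flagged,
    )


# ---------------------------------------------------------------------------
# bundled metric suites

@dataclass
class GlobalMetrics:
    """Network-level metric suite.

    C and the efficiencies lie in [0, 1]; L is in edge counts; the
    small-world ratios are None unless a random reference was requested.
    """

    C: float
    L: float
    E_global: float
    E_local: float
    gamma: float | None = None
    lambda_: float | None = None
    sigma: float | None = None

    def to_dict(self) -> dict:
        return {
            "clustering": self.C,
            "path_length": self.L,
            "global_efficiency": self.E_global,
            "local_efficiency": self.E_local,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
        }


@dataclass
class NodalMetrics:
    degree: np.ndarray
    nodal_efficiency: np.ndarray
    betweenness: np.ndarray
    betweenness_raw: np.ndarray

    def to_dict(self, atlas) -> dict:
        return {
            name: {
                "degree": int(self.degree[i]),
                "nodal_efficiency": float(self.nodal_efficiency[i]),
                "betweenness": float(self.betweenness[i]),
                "betweenness_raw": float(self.betweenness_raw[i]),
            }
            for i, name in enumerate(atlas.names)
        }


def global_metrics(net, n_random: int | None = None, seed=None) -> GlobalMetrics:
    """Compute the full network-level suite; small-world ratios if n_random."""
    d = distance_matrix(net)
    _, e_loc = local_efficiency(net)
    gm = GlobalMetrics(
        C=mean_clustering(net),
        L=characteristic_path_length(net, d),
        E_global=global_efficiency(net, d),
        E_local=e_loc,
    )
    if n_random:
        try:
            sw = small_world(net, n_random=n_random, seed=seed)
        except MetricUndefinedError:
            # e.g. triangle-free references: C_rand = 0, ratios undefined
            return gm
        gm.gamma, gm.lambda_, gm.sigma = sw.gamma, sw.lambda_, sw.sigma
    return gm


def nodal_metrics(net) -> NodalMetrics:
    a = _adj(net)
    norm, raw = betweenness(net)
    return NodalMetrics(
        degree=a.sum(axis=0).astype(int),
        nodal_efficiency=nodal_efficiency(net),
        betweenness=norm,
        betweenness_raw=raw,
    )
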