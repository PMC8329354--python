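"""Brute-force reference implementations used to cross-check graph metrics.

Everything here is deliberately naive (exhaustive enumeration, Floyd-
Warshall, all-simple-path search) and shares no code with the package.
"""

from itertools import combinations

import numpy as np


def bf_distances(adj):
    """Floyd-Warshall on a binary adjacency; inf for unreachable."""
    n = len(adj)
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if adj[i][j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_clustering(adj):
    """Per-node clustering by exhaustive triangle enumeration."""
    a = np.asarray(adj)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i][j]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(1 for u, v in combinations(nbrs, 2) if a[u][v])
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


def bf_path_length(adj):
    """Mean over nodes of mean distance to reachable partners; None if edgeless."""
    d = bf_distances(adj)
    n = d.shape[0]
    per = []
    for i in range(n):
        vals = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        if vals:
            per.append(sum(vals) / len(vals))
    return sum(per) / len(per) if per else None


def bf_global_efficiency(adj):
    d = bf_distances(adj)
    n = d.shape[0]
    if n < 2:
        return 0.0
    tot = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    )
    return tot / (n * (n - 1))


def bf_nodal_efficiency(adj):
    d = bf_distances(adj)
    n = d.shape[0]
    return np.array([
        sum(1.0 / d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j]))
        / (n - 1)
        for i in range(n)
    ])


def bf_local_efficiency(adj):
    a = np.asarray(adj)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i][j]]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        out[i] = bf_global_efficiency(sub)
    return out


def _all_shortest_paths(adj, s, t):
    """All shortest simple paths s->t by exhaustive DFS."""
    n = len(adj)
    best = [np.inf]
    paths = []

    def dfs(node, visited, path):
        if len(path) - 1 > best[0]:
            return
        if node == t:
            d = len(path) - 1
            if d < best[0]:
                best[0] = d
                paths.clear()
            if d == best[0]:
                paths.append(list(path))
            return
        for nxt in range(n):
            if adj[node][nxt] and nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(nxt, visited, path)
                path.pop()
                visited.remove(nxt)

    dfs(s, {s}, [s])
    return paths


def bf_betweenness(adj):
    """Normalized betweenness by exhaustive shortest-path enumeration."""
    a = np.asarray(adj)
    n = a.shape[0]
    raw = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = _all_shortest_paths(a, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            raw[v] += through / sigma
    if n < 3:
        return raw
    return raw / ((n - 1) * (n - 2) / 2.0)


def bh_oracle(pvals, q):
    """Benjamini-Hochberg step-up by direct application of its definition."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    kstar = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            kstar = rank
    reject = [False] * m
    if kstar:
        thresh = p[order[kstar - 1]]
        reject = [pi <= thresh for pi in p]
    return reject


def random_connected_graph(rng, n_max=7):
    """A random connected graph with 3..n_max nodes (rejection sampling)."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        prob = rng.uniform(0.25, 0.9)
        a = (rng.random((n, n)) < prob).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        d = bf_distances(a)
        if np.isfinite(d).all():
            return a
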