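"""Independent brute-force oracles for graph topology metrics.

Everything here is deliberately naive — Floyd–Warshall distance matrices,
geodesic counting by dynamic programming over the distance matrix, direct
summation for Newman Q, exhaustive partition enumeration — so the fast
implementations in the package can be checked against code that shares
nothing with them.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest hop counts; inf where unreachable."""
    n = len(adj)
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def path_stats(adj: np.ndarray) -> tuple[float, float]:
    """(diameter, average path length) over reachable ordered pairs."""
    d = floyd_warshall(adj)
    finite = d[np.isfinite(d) & (d > 0)]
    if len(finite) == 0:
        return 0.0, 0.0
    return float(finite.max()), float(finite.mean())


def local_clustering(adj: np.ndarray) -> np.ndarray:
    n = len(adj)
    c = np.zeros(n)
    for i in range(n):
        nbrs = np.where(adj[i] > 0)[0]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(adj[u, v] > 0 for u, v in combinations(nbrs, 2))
        c[i] = 2.0 * links / (k * (k - 1))
    return c


def geodesic_counts(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(distance matrix, number-of-geodesics matrix) by DP over distances."""
    d = floyd_warshall(adj)
    n = len(adj)
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    for s in range(n):
        order = np.argsort(d[s])
        for t in order:
            if t == s or not np.isfinite(d[s, t]):
                continue
            preds = [u for u in range(n)
                     if adj[u, t] > 0 and d[s, u] == d[s, t] - 1]
            sigma[s, t] = sum(sigma[s, u] for u in preds)
    return d, sigma


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalised betweenness: fractional geodesic counts through each node,
    via sigma_st(v) = sigma_sv * sigma_vt when d(s,v) + d(v,t) = d(s,t)."""
    d, sigma = geodesic_counts(adj)
    n = len(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if d[s, v] + d[v, t] == d[s, t]:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def closeness_wf(adj: np.ndarray) -> np.ndarray:
    """Wasserman–Faust closeness: (reach/(N−1)) · (reach/Σd) per node."""
    d = floyd_warshall(adj)
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        reach = np.isfinite(d[i]) & (np.arange(n) != i)
        r = reach.sum()
        if r == 0:
            continue
        tot = d[i][reach].sum()
        out[i] = (r / (n - 1)) * (r / tot)
    return out


def modularity_q(adj: np.ndarray, labels: np.ndarray) -> float:
    """Newman Q by direct summation over the definition."""
    m = adj.sum() / 2.0
    if m == 0:
        return 0.0
    deg = adj.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        e_cc = adj[np.ix_(idx, idx)].sum() / 2.0
        d_c = deg[idx].sum()
        q += e_cc / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def set_partitions(items: list):
    """Every partition of ``items`` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_modularity(adj: np.ndarray) -> float:
    """Exhaustive-search maximum Q over all partitions (small graphs only)."""
    n = len(adj)
    best = -np.inf
    for part in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for cid, block in enumerate(part):
            labels[block] = cid
        best = max(best, modularity_q(adj, labels))
    return best


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    return a + a.T
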