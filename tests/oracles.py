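"""Independent brute-force oracles for small graphs.

Everything here is deliberately naive — exhaustive partition search,
direct triangle/triplet counting, simple-path enumeration — so the main
implementations can be checked against an implementation that shares no
code or algorithmic shortcuts with them.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def all_partitions(items: list):
    """Every set partition of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def partition_q(adj: np.ndarray, communities, resolution: float = 1.0) -> float:
    """Newman modularity of one partition, computed from first principles."""
    a = np.asarray(adj, dtype=float)
    m2 = a.sum()
    k = a.sum(axis=1)
    q = 0.0
    for comm in communities:
        idx = np.asarray(list(comm))
        q += a[np.ix_(idx, idx)].sum() - resolution * k[idx].sum() ** 2 / m2
    return q / m2


def exhaustive_modularity(adj: np.ndarray, resolution: float = 1.0) -> float:
    """Maximum modularity over all partitions (feasible for <= ~10 nodes)."""
    n = adj.shape[0]
    return max(partition_q(adj, p, resolution) for p in all_partitions(list(range(n))))


def transitivity_by_enumeration(adj: np.ndarray) -> float:
    """Triangles over connected triplets, counted pair by pair."""
    a = np.asarray(adj)
    n = a.shape[0]
    triangles = 0
    for i, j, k in combinations(range(n), 3):
        if a[i, j] and a[j, k] and a[i, k]:
            triangles += 1
    triplets = 0  # ordered open+closed triplets centred on each node
    for c in range(n):
        neighbors = [x for x in range(n) if a[c, x]]
        triplets += len(neighbors) * (len(neighbors) - 1)
    if triplets == 0:
        return 0.0
    return 6 * triangles / triplets  # each triangle closes 3 centred pairs x 2 orders


def simple_path_distances(adj: np.ndarray) -> np.ndarray:
    """Shortest hop counts by enumerating all simple paths (tiny n only)."""
    a = np.asarray(adj)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)

    def explore(path: list[int]) -> None:
        here = path[-1]
        d = len(path) - 1
        if d < dist[path[0], here]:
            dist[path[0], here] = d
        for nxt in range(n):
            if a[here, nxt] and nxt not in path:
                explore(path + [nxt])

    for start in range(n):
        explore([start])
    return dist


def global_efficiency_by_enumeration(adj: np.ndarray) -> float:
    d = simple_path_distances(adj)
    n = adj.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def random_binary_graph(rng: np.random.Generator, n: int, density: float = 0.5) -> np.ndarray:
    a = (rng.random((n, n)) < density).astype(int)
    a = np.triu(a, 1)
    return a + a.T
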