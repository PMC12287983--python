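"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive — dense matrices, exhaustive path
enumeration, O(n^3) loops — and shares no code with the package, so a
match between the two is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

REL_TOL = 1e-9


def adjacency(n: int, edges: dict[tuple[int, int], float]) -> np.ndarray:
    """Dense weighted adjacency; a[u, v] = weight of u->v."""
    a = np.zeros((n, n))
    for (u, v), w in edges.items():
        a[u, v] = w
    return a


def floyd_warshall(n: int, lengths: dict[tuple[int, int], float]) -> np.ndarray:
    """All-pairs shortest path lengths by the triple loop; inf = unreachable."""
    dist = np.full((n, n), math.inf)
    np.fill_diagonal(dist, 0.0)
    for (u, v), l in lengths.items():
        dist[u, v] = min(dist[u, v], l)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def closeness_incoming(dist: np.ndarray) -> np.ndarray:
    """(|R|-1)/sum of incoming distances, 0 for unreached nodes."""
    n = dist.shape[0]
    out = np.zeros(n)
    for x in range(n):
        d = [dist[y, x] for y in range(n) if y != x and math.isfinite(dist[y, x])]
        if d and sum(d) > 0:
            out[x] = len(d) / sum(d)
    return out


def enumerate_shortest_paths(n: int, lengths: dict[tuple[int, int], float], s: int, t: int):
    """All simple s->t paths achieving the minimal total length.

    Returns (min_length, list_of_paths); (inf, []) when unreachable.
    Exhaustive DFS over simple paths — only viable for tiny graphs.
    """
    adj: dict[int, list[int]] = {}
    for (u, v) in lengths:
        adj.setdefault(u, []).append(v)
    paths = []

    def dfs(node, visited, total, path):
        if node == t:
            paths.append((total, list(path)))
            return
        for nxt in adj.get(node, []):
            if nxt in visited:
                continue
            visited.add(nxt)
            path.append(nxt)
            dfs(nxt, visited, total + lengths[(node, nxt)], path)
            path.pop()
            visited.remove(nxt)

    dfs(s, {s}, 0.0, [s])
    if not paths:
        return math.inf, []
    best = min(p[0] for p in paths)
    keep = [p for l, p in paths if l <= best * (1 + REL_TOL) + 1e-15]
    return best, keep


def betweenness(n: int, lengths: dict[tuple[int, int], float]) -> np.ndarray:
    """Unnormalized directed betweenness by exhaustive path enumeration."""
    out = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            _, paths = enumerate_shortest_paths(n, lengths, s, t)
            if not paths:
                continue
            sigma = len(paths)
            for path in paths:
                for v in path[1:-1]:
                    out[v] += 1.0 / sigma
    return out


def dominant_eigenvector(mat: np.ndarray) -> np.ndarray:
    """Unit-L2 nonnegative eigenvector of the dominant eigenvalue."""
    vals, vecs = np.linalg.eig(mat)
    i = int(np.argmax(vals.real))
    v = vecs[:, i].real
    v = v / np.linalg.norm(v)
    if v.sum() < 0:
        v = -v
    return np.abs(v)


def local_clustering(n: int, und_edges: set[tuple[int, int]]) -> np.ndarray:
    """c(v) by explicit neighbor-pair enumeration on an undirected edge set."""
    neighbors = [set() for _ in range(n)]
    for u, v in und_edges:
        neighbors[u].add(v)
        neighbors[v].add(u)
    out = np.zeros(n)
    for v in range(n):
        nb = sorted(neighbors[v])
        k = len(nb)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nb, 2)
            if b in neighbors[a]
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def transitivity(n: int, und_edges: set[tuple[int, int]]) -> float:
    """3 * triangles / connected triples by enumeration."""
    neighbors = [set() for _ in range(n)]
    for u, v in und_edges:
        neighbors[u].add(v)
        neighbors[v].add(u)
    triples = 0
    closed = 0
    for v in range(n):
        for a, b in itertools.combinations(sorted(neighbors[v]), 2):
            triples += 1
            if b in neighbors[a]:
                closed += 1
    return closed / triples if triples else 0.0


def categorical_assortativity(edges: list[tuple[int, int]], category: dict[int, str]) -> float:
    """Newman's r from an explicitly tallied mixing matrix."""
    cats = sorted(set(category.values()))
    idx = {c: i for i, c in enumerate(cats)}
    e = np.zeros((len(cats), len(cats)))
    for u, v in edges:
        e[idx[category[u]], idx[category[v]]] += 1
    e /= e.sum()
    trace = float(np.trace(e))
    ab = float(e.sum(axis=1) @ e.sum(axis=0))
    if trace == 1.0:
        return 1.0
    return (trace - ab) / (1.0 - ab)


def nearest_rank_quantile(values, p: float) -> float:
    """Type-1 quantile: smallest value whose empirical CDF >= p."""
    ordered = sorted(values)
    rank = math.ceil(p * len(ordered))
    return float(ordered[max(rank, 1) - 1])


def union_find_components(n: int, und_edges) -> list[set[int]]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in und_edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())


def random_digraph(rng: np.random.Generator, n_min=2, n_max=6, p=0.45, max_w=10,
                   require_simple_dominant=False):
    """A random weighted digraph as (n, {(u, v): weight}).

    With ``require_simple_dominant`` the graph is resampled until its
    weighted adjacency has a simple dominant eigenvalue with a clear
    modulus gap, the regime where eigenvector centrality is well
    defined.
    """
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        edges = {}
        for u in range(n):
            for v in range(n):
                if u != v and rng.random() < p:
                    edges[(u, v)] = float(rng.integers(1, max_w + 1))
        if not edges:
            continue
        if require_simple_dominant:
            vals = np.abs(np.linalg.eigvals(adjacency(n, edges)))
            vals.sort()
            if vals[-1] < 1e-9 or (len(vals) > 1 and vals[-2] > 0.95 * vals[-1]):
                continue
        return n, edges
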