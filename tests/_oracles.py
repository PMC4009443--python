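"""Independent brute-force oracles for graph measures and modularity.

Everything here is deliberately naive: breadth-first search by hand,
exhaustive path and triangle enumeration, exhaustive set-partition
search.  These never call the package's own implementations.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(edges: set[tuple[int, int]], n: int) -> np.ndarray:
    """All-pairs shortest path lengths by textbook BFS."""
    adj = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    D = np.full((n, n), np.inf)
    for s in range(n):
        D[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if np.isinf(D[s, v]):
                    D[s, v] = D[s, u] + 1
                    q.append(v)
    return D


def char_path_length(edges: set[tuple[int, int]], n: int) -> tuple[float, int]:
    D = bfs_distances(edges, n)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    unreachable = int(off.sum() - finite.sum())
    if finite.sum() == 0:
        return float("nan"), unreachable
    return float(D[finite].mean()), unreachable


def global_efficiency(edges: set[tuple[int, int]], n: int) -> float:
    if n < 2:
        return 0.0
    D = bfs_distances(edges, n)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def node_efficiency(edges: set[tuple[int, int]], n: int) -> np.ndarray:
    D = bfs_distances(edges, n)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                out[i] += 1.0 / D[i, j]
    return out / max(n - 1, 1)


def local_efficiency(edges: set[tuple[int, int]], n: int) -> np.ndarray:
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out = np.zeros(n)
    for i in range(n):
        nbrs = sorted(adj[i])
        if len(nbrs) < 2:
            continue
        remap = {u: k for k, u in enumerate(nbrs)}
        sub = {(remap[a], remap[b]) for a, b in edges
               if a in remap and b in remap}
        out[i] = global_efficiency(sub, len(nbrs))
    return out


def clustering(edges: set[tuple[int, int]], n: int) -> np.ndarray:
    """Triangle-count local clustering coefficient."""
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out = np.zeros(n)
    for i in range(n):
        k = len(adj[i])
        if k < 2:
            continue
        tri = sum(1 for u, v in itertools.combinations(sorted(adj[i]), 2)
                  if v in adj[u])
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


def _all_paths(adj: dict[int, set[int]], s: int, t: int) -> list[list[int]]:
    """Every simple path from s to t by exhaustive DFS."""
    paths = []
    stack = [(s, [s])]
    while stack:
        u, path = stack.pop()
        if u == t:
            paths.append(path)
            continue
        for v in adj[u]:
            if v not in path:
                stack.append((v, path + [v]))
    return paths


def betweenness(edges: set[tuple[int, int]], n: int) -> np.ndarray:
    """Normalized betweenness by exhaustive shortest-path enumeration."""
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_paths(adj, s, t)
        if not paths:
            continue
        d = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == d]
        for p in shortest:
            for u in p[1:-1]:
                out[u] += 1.0 / len(shortest)
    if n > 2:
        out /= (n - 1) * (n - 2) / 2
    return out


def degrees(edges: set[tuple[int, int]], n: int) -> np.ndarray:
    out = np.zeros(n)
    for a, b in edges:
        out[a] += 1
        out[b] += 1
    return out


def random_edge_set(
    rng: np.random.Generator, n: int, p: float
) -> set[tuple[int, int]]:
    return {
        (i, j) for i, j in itertools.combinations(range(n), 2)
        if rng.random() < p
    }


def set_partitions(n: int):
    """All partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, maxlab: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(maxlab + 1):
            labels[i] = lab
            yield from rec(i + 1, max(maxlab, lab + 1))

    yield from rec(1, 1) if n > 0 else iter([np.zeros(0, int)])


def q_star_direct(W: np.ndarray, labels: np.ndarray) -> float:
    """Literal evaluation of the signed modularity formula, term by term."""
    W = np.asarray(W, float)
    n = W.shape[0]
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    vp, vn = Wp.sum(), Wn.sum()

    def part(M, v):
        if v == 0:
            return 0.0
        s = M.sum(axis=1)
        total = 0.0
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    total += M[i, j] - s[i] * s[j] / v
        return total / v

    return part(Wp, vp) - (vn / (vp + vn)) * part(Wn, vn)


def max_q_star_exhaustive(W: np.ndarray) -> tuple[float, np.ndarray]:
    """Exhaustive maximum of Q* over all set partitions (n <= 8)."""
    n = W.shape[0]
    best, best_labels = -np.inf, None
    for labels in set_partitions(n):
        q = q_star_direct(W, labels)
        if q > best:
            best, best_labels = q, labels
    return best, best_labels
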