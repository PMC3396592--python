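"""Independent brute-force oracles for graph measures on tiny graphs.

Everything here is written from first principles (BFS by hand, exhaustive
path/triangle/partition enumeration) and deliberately shares no code with
the package implementation, so oracle/implementation agreement is a real
cross-check.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def neighbors(A, i):
    return [j for j in range(A.shape[0]) if A[i, j]]


def bfs_distances(A, source):
    n = A.shape[0]
    dist = [None] * n
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in neighbors(A, u):
            if dist[v] is None:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def oracle_components(A):
    n = A.shape[0]
    seen = set()
    comps = []
    for s in range(n):
        if s in seen:
            continue
        comp = {i for i, d in enumerate(bfs_distances(A, s)) if d is not None}
        seen |= comp
        comps.append(sorted(comp))
    return comps


def oracle_clustering(A):
    n = A.shape[0]
    out = []
    for i in range(n):
        nb = neighbors(A, i)
        k = len(nb)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nb, 2) if A[a, b]
        )
        out.append(2.0 * links / (k * (k - 1)))
    return np.array(out)


def oracle_transitivity(A):
    n = A.shape[0]
    triangles = sum(
        1 for a, b, c in itertools.combinations(range(n), 3)
        if A[a, b] and A[b, c] and A[a, c]
    )
    triples = sum(
        1 for v in range(n)
        for _ in itertools.combinations(neighbors(A, v), 2)
    )
    return 3.0 * triangles / triples if triples else 0.0


def oracle_path_length(A):
    """Mean BFS distance over pairs of the largest component."""
    comps = oracle_components(A)
    comp = max(comps, key=len)
    if len(comp) < 2:
        return 0.0
    total, count = 0, 0
    for i in comp:
        d = bfs_distances(A, i)
        for j in comp:
            if j > i:
                total += d[j]
                count += 1
    return total / count


def oracle_global_efficiency(A):
    n = A.shape[0]
    total, count = 0.0, 0
    for i in range(n):
        d = bfs_distances(A, i)
        for j in range(i + 1, n):
            total += 0.0 if d[j] is None else 1.0 / d[j]
            count += 1
    return total / count if count else 0.0


def oracle_local_efficiency(A):
    out = []
    for i in range(A.shape[0]):
        nb = neighbors(A, i)
        if len(nb) < 2:
            out.append(0.0)
            continue
        sub = A[np.ix_(nb, nb)]
        out.append(oracle_global_efficiency(sub))
    return np.array(out)


def _all_shortest_paths(A, s, t):
    """Enumerate every geodesic from s to t by exhaustive DFS."""
    d = bfs_distances(A, s)
    if d[t] is None:
        return []
    target_len = d[t]
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        if len(path) - 1 >= target_len:
            return
        for v in neighbors(A, u):
            if v not in path and d[v] == len(path):
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def oracle_betweenness(A, normalized=True):
    n = A.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(A, s, t)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2
    return bc


def _set_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in _set_partitions(items[1:]):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
        yield [[first]] + smaller


def oracle_modularity_q(A, membership):
    n = A.shape[0]
    two_m = float(A.sum())
    k = A.sum(axis=0)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += A[i, j] - k[i] * k[j] / two_m
    return q / two_m


def oracle_best_modularity(A):
    """Max modularity over every partition (Bell-number enumeration)."""
    n = A.shape[0]
    best_q, best_part = -2.0, None
    for part in _set_partitions(list(range(n))):
        mem = [0] * n
        for m, block in enumerate(part):
            for v in block:
                mem[v] = m
        q = oracle_modularity_q(A, mem)
        if q > best_q:
            best_q, best_part = q, part
    return best_q, best_part


def oracle_assortativity(A):
    k = A.sum(axis=0)
    xs, ys = [], []
    for i, j in itertools.combinations(range(A.shape[0]), 2):
        if A[i, j]:
            xs += [k[i], k[j]]
            ys += [k[j], k[i]]
    xs, ys = np.array(xs, float), np.array(ys, float)
    if len(xs) == 0 or xs.std() == 0:
        return float("nan")
    return float(
        ((xs - xs.mean()) * (ys - ys.mean())).sum()
        / np.sqrt(((xs - xs.mean()) ** 2).sum() * ((ys - ys.mean()) ** 2).sum())
    )


def oracle_pearson(x, y):
    """Textbook sum-of-products Pearson correlation."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx**2) * (n * syy - sy**2)) ** 0.5
    return num / den
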