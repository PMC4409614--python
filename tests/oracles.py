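"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: shortest paths are found
by explicit enumeration of all simple paths, and the Kruskal-Wallis null
distribution by explicit enumeration of group assignments.  Tied path
lengths use the same documented convention as the package (1e-12 relative
tolerance), so agreement is expected to full float precision.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps


def _tol(d: float) -> float:
    return 1e-12 * (1.0 + abs(d))


def enumerate_shortest_paths(adj: dict, s: str, t: str) -> tuple[float, list[list[str]]]:
    """All shortest simple s->t paths by exhaustive DFS.

    ``adj`` maps node -> list of (neighbor, length).  Returns
    (distance, paths); (inf, []) when t is unreachable.  Edge lengths are
    positive, so shortest paths are simple and enumeration is complete.
    """
    best = float("inf")
    paths: list[list[str]] = []

    def dfs(node: str, dist: float, path: list[str]) -> None:
        nonlocal best, paths
        if dist > best + _tol(best):
            return
        if node == t:
            if dist < best - _tol(dist):
                best = dist
                paths = [list(path)]
            elif abs(dist - best) <= _tol(dist):
                paths.append(list(path))
            return
        for nbr, length in adj[node]:
            if nbr not in path:
                path.append(nbr)
                dfs(nbr, dist + length, path)
                path.pop()

    dfs(s, 0.0, [s])
    return best, paths


def brute_betweenness(nodes: list[str], adj: dict) -> dict[str, float]:
    """Normalized directed betweenness by full path enumeration."""
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    if n < 3:
        return bc
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            _, paths = enumerate_shortest_paths(adj, s, t)
            if not paths:
                continue
            sigma = len(paths)
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / sigma
    norm = (n - 1) * (n - 2)
    return {v: bc[v] / norm for v in bc}


def brute_closeness(nodes: list[str], adj: dict) -> dict[str, float]:
    """Component-scaled closeness from enumerated forward distances."""
    n = len(nodes)
    out = {}
    for u in nodes:
        dists = []
        for v in nodes:
            if v == u:
                continue
            d, paths = enumerate_shortest_paths(adj, u, v)
            if paths:
                dists.append(d)
        r = len(dists)
        out[u] = (r / (n - 1)) * (r / sum(dists)) if r else 0.0
    return out


def reverse_adj(adj: dict) -> dict:
    out: dict = {u: [] for u in adj}
    for u, nbrs in adj.items():
        for v, length in nbrs:
            out[v].append((u, length))
    return out


def kw_h_by_hand(groups: list[np.ndarray]) -> float:
    """Tie-corrected H computed directly from its defining formula."""
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    idx = 0
    acc = 0.0
    for g in groups:
        r = ranks[idx : idx + g.size]
        idx += g.size
        acc += g.size * r.mean() ** 2
    h = 12.0 / (N * (N + 1)) * acc - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    corr = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
    return 0.0 if corr == 0 else h / corr


def kw_exact_null(groups: list[np.ndarray], h_func) -> float:
    """Exact permutation p-value of an H-type statistic for small N.

    Enumerates every split of the pooled sample into groups of the
    observed sizes and returns the fraction with H >= observed.
    """
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    N = pooled.size
    assert N <= 8, "exact enumeration is only intended for tiny samples"
    observed = h_func([np.asarray(g, dtype=float) for g in groups])
    indices = set(range(N))
    count = 0
    total = 0

    def rec(remaining: frozenset, assigned: list[np.ndarray]) -> None:
        nonlocal count, total
        k = len(assigned)
        if k == len(sizes):
            total += 1
            if h_func(assigned) >= observed - 1e-12:
                count += 1
            return
        for combo in combinations(sorted(remaining), sizes[k]):
            rec(remaining - set(combo), assigned + [pooled[list(combo)]])

    rec(frozenset(indices), [])
    expected_total = 1
    rem = N
    for s in sizes:
        expected_total *= comb(rem, s)
        rem -= s
    assert total == expected_total
    return count / total
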