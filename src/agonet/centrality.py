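"""Centrality parameters of agonistic networks, binary and weighted.

Seven measures are computed per animal — degree, in-degree, out-degree,
betweenness, closeness, ingoing closeness and outgoing closeness — each in a
binary (presence/absence of a link) and a weighted (contact-frequency)
variant, giving 14 values per animal.

Conventions
-----------
* Binary degree counts distinct opponents / attackers / victims; weighted
  degree sums edge weights (fight counts, stand-offs counting 0.5 per
  direction).
* Shortest-path measures on the weighted network use edge length
  ``1 / weight``: frequent opponents are *closer*.  This is the only
  convention under which weighted closeness can exceed 1 while weighted
  betweenness, a path-count fraction, stays in [0, 1].
* Betweenness of node v is
  ``sum_{s != t != v} sigma_st(v) / sigma_st / ((n-1)(n-2))``
  over ordered pairs of the directed network (0 when no s->t path exists);
  computed with Brandes' path-counting accumulation, so tied shortest
  paths all count.  Networks with n < 3 have betweenness 0 everywhere.
* Closeness of u with r reachable others at total distance d is
  ``(r / (n-1)) * (r / d)`` — the component-scaled form, which is 0 for
  isolated animals and keeps binary values in [0, 1] on disconnected
  networks.  Ingoing closeness uses distances from the others to u,
  outgoing closeness distances from u to the others, plain closeness the
  undirected projection.
* Tied weighted path lengths are detected with a 1e-12 relative tolerance.
"""

from __future__ import annotations

from heapq import heappop, heappush
from typing import Iterable, Literal

import pandas as pd

from .network import PenNetwork, undirected_projection

_AGE_SORT = {"weaned": 0, "growing": 1, "gilt": 2}

#: relative tolerance for treating two weighted path lengths as equal
EPS = 1e-12

#: the 14 measure columns of a centrality table, in reporting order
MEASURE_COLUMNS = [
    f"{m}_{v}"
    for m in (
        "degree",
        "in_degree",
        "out_degree",
        "betweenness",
        "closeness",
        "in_closeness",
        "out_closeness",
    )
    for v in ("binary", "weighted")
]

Adjacency = dict[str, list[tuple[str, float]]]


def _lengths(adj_half: dict[str, list[tuple[str, int]]], weighted: bool) -> Adjacency:
    """Convert half-unit adjacency into shortest-path edge lengths."""
    if weighted:
        return {u: [(v, 2.0 / h) for v, h in nbrs] for u, nbrs in adj_half.items()}
    return {u: [(v, 1.0) for v, _ in nbrs] for u, nbrs in adj_half.items()}


def _tol(d: float) -> float:
    return EPS * (1.0 + abs(d))


def _sssp_unit(adj: Adjacency, source: str):
    """BFS single-source shortest paths with path counting (unit lengths)."""
    dist: dict[str, float] = {source: 0.0}
    sigma: dict[str, int] = {source: 1}
    preds: dict[str, list[str]] = {source: []}
    order = [source]
    frontier = [source]
    while frontier:
        nxt: list[str] = []
        for v in frontier:
            dv = dist[v]
            for w, _ in adj[v]:
                if w not in dist:
                    dist[w] = dv + 1.0
                    sigma[w] = sigma[v]
                    preds[w] = [v]
                    nxt.append(w)
                elif dist[w] == dv + 1.0:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        order.extend(nxt)
        frontier = nxt
    return order, dist, sigma, preds


def _sssp_weighted(adj: Adjacency, source: str):
    """Dijkstra single-source shortest paths with path counting.

    Edge lengths are positive, so predecessors always settle before their
    successors; tied path lengths are merged within the EPS tolerance.
    """
    dist: dict[str, float] = {}
    seen: dict[str, float] = {source: 0.0}
    sigma: dict[str, int] = {source: 1}
    preds: dict[str, list[str]] = {source: []}
    order: list[str] = []
    heap: list[tuple[float, str]] = [(0.0, source)]
    while heap:
        d, v = heappop(heap)
        if v in dist:
            continue
        dist[v] = seen[v]
        order.append(v)
        dv = dist[v]
        for w, length in adj[v]:
            if w in dist:
                continue
            nd = dv + length
            if w not in seen or nd < seen[w] - _tol(nd):
                seen[w] = nd
                sigma[w] = sigma[v]
                preds[w] = [v]
                heappush(heap, (nd, w))
            elif abs(nd - seen[w]) <= _tol(nd):
                sigma[w] += sigma[v]
                preds[w].append(v)
    return order, dist, sigma, preds


def _sssp(adj: Adjacency, source: str, weighted: bool):
    return (_sssp_weighted if weighted else _sssp_unit)(adj, source)


def _closeness_from_dist(dist: dict[str, float], n: int, scaling: str) -> float:
    r = len(dist) - 1  # reachable others
    if r <= 0 or n <= 1:
        return 0.0
    d = sum(dist.values())  # self contributes 0
    if scaling == "component":
        return (r / (n - 1)) * (r / d)
    if scaling == "off":
        return r / d
    raise ValueError(f"unknown closeness scaling {scaling!r}")


def degree(
    net: PenNetwork,
    mode: Literal["in", "out", "total"] = "total",
    weighted: bool = False,
    standardized: bool = False,
) -> dict[str, float]:
    """Degree centrality.

    Binary: number of distinct victims (``out``), attackers (``in``) or
    opponents (``total``).  Weighted: summed outgoing / incoming / incident
    edge weights.  ``standardized`` divides by n - 1.
    """
    values: dict[str, float] = {u: 0.0 for u in net.nodes}
    if mode == "total":
        und = net if not net.directed else undirected_projection(net)
        for u, v, w in und.edges():
            inc = w if weighted else 1.0
            values[u] += inc
            values[v] += inc
    else:
        if not net.directed:
            raise ValueError("in/out degree requires a directed network")
        for u, v, w in net.edges():
            node = u if mode == "out" else v
            values[node] += w if weighted else 1.0
    if standardized and net.n > 1:
        values = {u: val / (net.n - 1) for u, val in values.items()}
    return values


def betweenness(net: PenNetwork, weighted: bool = False) -> dict[str, float]:
    """Normalized betweenness centrality (Brandes accumulation).

    Pairs with no connecting path contribute 0; the divisor (n-1)(n-2)
    makes the maximum attainable value 1.  All values are 0 when n < 3.
    """
    n = net.n
    bc = {v: 0.0 for v in net.nodes}
    if n < 3:
        return bc
    adj = _lengths(net.adjacency(), weighted)
    for s in net.nodes:
        order, _, sigma, preds = _sssp(adj, s, weighted)
        delta = {v: 0.0 for v in order}
        for w in reversed(order):
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in preds[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    # ordered-pair accumulation: for undirected nets each unordered pair is
    # swept twice, which cancels against the doubled pair count, so the same
    # divisor keeps the maximum at 1 in both cases
    norm = (n - 1) * (n - 2)
    return {v: bc[v] / norm for v in bc}


def closeness(
    net: PenNetwork,
    direction: Literal["in", "out", "undirected"] = "undirected",
    weighted: bool = False,
    scaling: Literal["component", "off"] = "component",
) -> dict[str, float]:
    """Closeness centrality, component-scaled by default.

    ``out``: how quickly fights started by the focal animal can cascade to
    the rest of the pen (forward distances).  ``in``: how quickly the
    others' aggression reaches the focal animal (reversed distances).
    ``undirected``: distances on the undirected projection (directed input
    is projected with the summed-weight rule).
    """
    if direction == "undirected":
        work = undirected_projection(net) if net.directed else net
        adj = _lengths(work.adjacency(), weighted)
    elif direction in ("in", "out"):
        if not net.directed:
            raise ValueError("in/out closeness requires a directed network")
        adj = _lengths(net.adjacency(reverse=(direction == "in")), weighted)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    n = net.n
    out: dict[str, float] = {}
    for u in net.nodes:
        _, dist, _, _ = _sssp(adj, u, weighted)
        out[u] = _closeness_from_dist(dist, n, scaling)
    return out


def _pen_profile(
    net: PenNetwork,
    scaling: str = "component",
    standardize_degree: bool = False,
) -> dict[str, dict[str, float]]:
    """All 14 measures for one pen, sharing shortest-path sweeps.

    Per weight variant: one forward sweep per node feeds outgoing closeness
    and the betweenness accumulation, one reverse sweep feeds ingoing
    closeness, one undirected sweep feeds plain closeness.
    """
    n = net.n
    und = undirected_projection(net)
    profile: dict[str, dict[str, float]] = {}
    for variant, weighted in (("binary", False), ("weighted", True)):
        profile[f"degree_{variant}"] = degree(net, "total", weighted, standardize_degree)
        profile[f"in_degree_{variant}"] = degree(net, "in", weighted, standardize_degree)
        profile[f"out_degree_{variant}"] = degree(net, "out", weighted, standardize_degree)

        fwd = _lengths(net.adjacency(), weighted)
        rev = _lengths(net.adjacency(reverse=True), weighted)
        uadj = _lengths(und.adjacency(), weighted)
        bc = {v: 0.0 for v in net.nodes}
        out_clo: dict[str, float] = {}
        in_clo: dict[str, float] = {}
        u_clo: dict[str, float] = {}
        for s in net.nodes:
            order, dist, sigma, preds = _sssp(fwd, s, weighted)
            out_clo[s] = _closeness_from_dist(dist, n, scaling)
            if n >= 3:
                delta = {v: 0.0 for v in order}
                for w in reversed(order):
                    coeff = (1.0 + delta[w]) / sigma[w]
                    for v in preds[w]:
                        delta[v] += sigma[v] * coeff
                    if w != s:
                        bc[w] += delta[w]
            _, dist, _, _ = _sssp(rev, s, weighted)
            in_clo[s] = _closeness_from_dist(dist, n, scaling)
            _, dist, _, _ = _sssp(uadj, s, weighted)
            u_clo[s] = _closeness_from_dist(dist, n, scaling)
        norm = (n - 1) * (n - 2) if n >= 3 else 1
        profile[f"betweenness_{variant}"] = {v: bc[v] / norm for v in bc}
        profile[f"closeness_{variant}"] = u_clo
        profile[f"in_closeness_{variant}"] = in_clo
        profile[f"out_closeness_{variant}"] = out_clo
    return profile


def centrality_table(
    nets: Iterable[PenNetwork],
    scaling: str = "component",
    standardize_degree: bool = False,
) -> pd.DataFrame:
    """One row per (animal, pen) with all 14 centrality measures.

    Rows are ordered by (age level, pen id, animal id); ``n_pen`` is the
    roster size of the animal's pen.
    """
    rows = []
    for net in sorted(nets, key=lambda x: (_AGE_SORT[x.age_level.value], x.pen_id)):
        profile = _pen_profile(net, scaling=scaling, standardize_degree=standardize_degree)
        for animal in net.nodes:
            row = {
                "animal_id": animal,
                "pen_id": net.pen_id,
                "age_level": net.age_level.value,
                "n_pen": net.n,
            }
            for col in MEASURE_COLUMNS:
                row[col] = profile[col][animal]
            rows.append(row)
    return pd.DataFrame(
        rows, columns=["animal_id", "pen_id", "age_level", "n_pen", *MEASURE_COLUMNS]
    )
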