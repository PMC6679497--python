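"""Independent brute-force oracles used to cross-check the package.

Everything here is written from first principles on plain adjacency
dicts — exhaustive BFS for distances, shortest-path counting for
betweenness, dense power iteration for PageRank, parent-pointer walks
for ontology ancestors — deliberately avoiding the code paths (and
libraries) the package itself uses.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def bfs_distances(adj: dict, source) -> dict:
    """Hop distances from source by plain queue BFS."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def all_pairs(adj: dict) -> dict:
    return {v: bfs_distances(adj, v) for v in adj}


def path_counts(adj: dict, source) -> tuple[dict, dict]:
    """(distance, number of shortest paths) from source to every node."""
    dist = bfs_distances(adj, source)
    order = sorted(dist, key=dist.get)
    sigma = {v: 0 for v in dist}
    sigma[source] = 1
    for v in order:
        if v == source:
            continue
        sigma[v] = sum(sigma[u] for u in adj[v]
                       if u in dist and dist[u] == dist[v] - 1)
    return dist, sigma


def brute_betweenness(adj: dict) -> dict:
    """Pair-normalized betweenness via sigma(s,v)*sigma(v,t)/sigma(s,t)."""
    nodes = sorted(adj)
    n = len(nodes)
    dist = {}
    sigma = {}
    for v in nodes:
        dist[v], sigma[v] = path_counts(adj, v)
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            total = sigma[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    bc[v] += sigma[s][v] * sigma[t][v] / total
    norm = (n - 1) * (n - 2) / 2.0
    if norm > 0:
        for v in bc:
            bc[v] /= norm
    return bc


def brute_closeness(adj: dict) -> dict:
    """Wasserman-Faust component-scaled closeness from BFS distances."""
    nodes = sorted(adj)
    n = len(nodes)
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        r = len(dist)  # component size, including v
        total = sum(dist.values())
        if total == 0 or n == 1:
            out[v] = 0.0
        else:
            out[v] = (r - 1) / total * (r - 1) / (n - 1)
    return out


def dense_pagerank(adj: dict, damping: float = 0.85,
                   tol: float = 1e-12) -> dict:
    """PageRank by dense matrix power iteration."""
    nodes = sorted(adj)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for v in nodes:
        deg = len(adj[v])
        for u in adj[v]:
            m[idx[u], idx[v]] = 1.0 / deg
    x = np.full(n, 1.0 / n)
    for _ in range(100_000):
        x_new = damping * m @ x + (1.0 - damping) / n
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    return {v: float(x[idx[v]]) for v in nodes}


def brute_cs(adj: dict, damping: float = 0.85) -> dict:
    bn = brute_betweenness(adj)
    cn = brute_closeness(adj)
    pr = dense_pagerank(adj, damping)
    return {v: bn[v] + cn[v] + pr[v] for v in adj}


def set_distance(adj: dict, t, members: set) -> float:
    """min over the set of BFS hop distances; inf when unreachable."""
    if t in members:
        return 0.0
    if t not in adj:
        return math.inf
    dist = bfs_distances(adj, t)
    best = [d for v, d in dist.items() if v in members]
    return float(min(best)) if best else math.inf


def brute_s_tnetwork(tk: list, th: list, adj: dict, cs: dict,
                     decay: bool = True) -> float:
    """Direct evaluation of the two centrality-weighted kernel means."""
    mk = [t for t in tk if t in adj]
    mh = [t for t in th if t in adj]
    m, n = len(mk), len(mh)

    def term(sources, dest, denom):
        num = den = 0.0
        for t in sources:
            d = set_distance(adj, t, set(dest))
            kern = 0.0 if math.isinf(d) else math.exp(
                -d / denom if decay else d / denom)
            num += cs[t] * kern
            den += cs[t]
        return num / den

    return term(mk, mh, n * n) + term(mh, mk, m * m)


def walk_ancestors(parents: dict, term) -> set:
    """Reflexive ancestor set by iterated parent-pointer expansion."""
    out = {term}
    frontier = {term}
    while frontier:
        nxt = set()
        for t in frontier:
            for p in parents.get(t, ()):
                if p not in out:
                    out.add(p)
                    nxt.add(p)
        frontier = nxt
    return out


def brute_lin(parents: dict, p: dict, t1, t2) -> float:
    """Lin similarity by exhaustive common-ancestor enumeration."""
    if t1 == t2:
        return 1.0
    common = walk_ancestors(parents, t1) & walk_ancestors(parents, t2)
    common = {a for a in common if a in p}
    if not common:
        return 0.0
    p_mica = min(p[a] for a in common)
    denom = math.log2(p[t1]) + math.log2(p[t2])
    if denom == 0.0:
        return 0.0
    return 2.0 * math.log2(p_mica) / denom


def random_connected_adj(rng: np.random.Generator, max_nodes: int = 12
                         ) -> dict:
    """Random connected graph as an adjacency dict (spanning tree + extras)."""
    n = int(rng.integers(3, max_nodes + 1))
    names = [f"N{i}" for i in range(n)]
    adj = {v: set() for v in names}
    for i in range(1, n):
        j = int(rng.integers(0, i))
        adj[names[i]].add(names[j])
        adj[names[j]].add(names[i])
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            adj[names[int(i)]].add(names[int(j)])
            adj[names[int(j)]].add(names[int(i)])
    return adj
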