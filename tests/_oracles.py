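"""Independent brute-force oracles for the graph-metric suite.

These deliberately avoid the package's algorithms: betweenness comes
from explicit all-pairs shortest-path counting on BFS distance/count
matrices, closeness from raw BFS distance sums, clustering from a
cubic triple loop, components from union-find, and the eigenvector from
a dense symmetric eigendecomposition.
"""

from __future__ import annotations

import collections
import itertools

import numpy as np

from ddinet.network import DrugGraph, EdgeData
from ddinet.knowledge import Severity


def make_graph(edges, extra_nodes=()) -> DrugGraph:
    """Build a DrugGraph from (a, b) pairs; severities are immaterial to
    the topology metrics, so every edge is 'minor' with one occurrence."""
    g = DrugGraph()
    for a, b in edges:
        g.add_edge(str(a), str(b), EdgeData(Severity.MINOR, 1, 1.0))
    g.nodes.update(str(v) for v in extra_nodes)
    return g


def random_graph(rng: np.random.Generator, n: int, p: float) -> DrugGraph:
    """Erdos-Renyi G(n, p) with string labels; isolated nodes retained."""
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = [(a, b) for a, b in itertools.combinations(nodes, 2)
             if rng.random() < p]
    return make_graph(edges, extra_nodes=nodes)


def _bfs_matrices(g: DrugGraph) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Hop-distance matrix D (inf if unreachable) and shortest-path count
    matrix S, computed per source by BFS plus distance-ordered counting."""
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = g.adjacency()
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = index[s]
        dist[si, si] = 0.0
        sigma[si, si] = 1.0
        order = [s]
        queue = collections.deque([s])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if np.isinf(dist[si, index[w]]):
                    dist[si, index[w]] = dist[si, index[v]] + 1
                    queue.append(w)
                    order.append(w)
        for w in order[1:]:
            wi = index[w]
            sigma[si, wi] = sum(
                sigma[si, index[u]] for u in adj[w]
                if dist[si, index[u]] == dist[si, wi] - 1
            )
    return nodes, dist, sigma


def brute_betweenness(g: DrugGraph, normalized: bool = True) -> dict[str, float]:
    nodes, dist, sigma = _bfs_matrices(g)
    n = len(nodes)
    bc = {}
    for vi, v in enumerate(nodes):
        total = 0.0
        for si, ti in itertools.combinations(range(n), 2):
            if si == vi or ti == vi or np.isinf(dist[si, ti]):
                continue
            if dist[si, vi] + dist[vi, ti] == dist[si, ti]:
                total += sigma[si, vi] * sigma[vi, ti] / sigma[si, ti]
        if normalized and n > 2:
            total /= (n - 1) * (n - 2) / 2.0
        bc[v] = total
    return bc


def brute_closeness(g: DrugGraph) -> dict[str, float]:
    nodes, dist, _ = _bfs_matrices(g)
    n = len(nodes)
    out = {}
    for vi, v in enumerate(nodes):
        reach = np.isfinite(dist[vi])
        k = int(reach.sum())  # includes v itself
        total = float(dist[vi][reach].sum())
        if k <= 1 or total == 0:
            out[v] = 0.0
        else:
            out[v] = ((k - 1) / total) * ((k - 1) / (n - 1))
    return out


def brute_clustering(g: DrugGraph) -> dict[str, float]:
    nodes = sorted(g.nodes)
    adj = g.adjacency()
    out = {}
    for v in nodes:
        nbrs = sorted(adj[v])
        d = len(nbrs)
        if d < 2:
            out[v] = 0.0
            continue
        triangles = 0
        for i in range(d):
            for j in range(i + 1, d):
                if nbrs[j] in adj[nbrs[i]]:
                    triangles += 1
        out[v] = 2.0 * triangles / (d * (d - 1))
    return out


def brute_components(g: DrugGraph) -> list[set[str]]:
    """Union-find over the edge list."""
    parent = {v: v for v in g.nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in g.edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for v in g.nodes:
        groups.setdefault(find(v), set()).add(v)
    comps = list(groups.values())
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def dense_eigenvector(g: DrugGraph) -> dict[str, float]:
    """Per-component dominant eigenvector via numpy.linalg.eigh, each
    component's sub-vector non-negative with unit Euclidean norm."""
    out: dict[str, float] = {}
    for comp in brute_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            out[nodes[0]] = 0.0
            continue
        index = {v: i for i, v in enumerate(nodes)}
        a = np.zeros((len(nodes), len(nodes)))
        for (u, v) in g.edges:
            if u in index:
                a[index[u], index[v]] = a[index[v], index[u]] = 1.0
        vals, vecs = np.linalg.eigh(a)
        vec = np.abs(vecs[:, -1])
        vec /= np.linalg.norm(vec)
        for v, value in zip(nodes, vec):
            out[v] = float(value)
    return out
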