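"""Independent naive reference implementations used only by the tests.

These deliberately avoid the code paths of the package (and of networkx's
centrality routines): betweenness is accumulated from per-source BFS
shortest-path counts via the sigma-product rule, eigenvector centrality comes
from a dense symmetric eigendecomposition, closeness/LAC/NC from direct
neighbourhood counting, the hypergeometric tail from exact integer binomial
sums, and BH from the textbook O(m^2) step-up definition.
"""

from __future__ import annotations

from collections import deque
from math import comb

import networkx as nx
import numpy as np


def _bfs_counts(adj: dict, source):
    """Distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def naive_centralities(g: nx.Graph) -> dict[str, dict]:
    """All six metrics by direct evaluation of their definitions."""
    nodes = sorted(g.nodes)
    adj = {v: set(g.adj[v]) for v in nodes}
    deg = {v: len(adj[v]) for v in nodes}

    # closeness: reachable-set form
    cc = {}
    dists = {}
    sigmas = {}
    for v in nodes:
        dist, sigma = _bfs_counts(adj, v)
        dists[v], sigmas[v] = dist, sigma
        reach = [d for u, d in dist.items() if u != v]
        cc[v] = len(reach) / sum(reach) if reach else 0.0

    # betweenness: sigma-product rule over unordered pairs
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dists[s]:
                continue
            d_st = dists[s][t]
            total = sigmas[s][t]
            for v in nodes:
                if v in (s, t) or v not in dists[s] or v not in dists[t]:
                    continue
                if dists[s][v] + dists[t][v] == d_st:
                    bc[v] += sigmas[s][v] * sigmas[t][v] / total

    # eigenvector: dense eigh per connected component, unit 2-norm
    ec = {}
    for comp in nx.connected_components(g):
        cn = sorted(comp)
        if len(cn) == 1:
            ec[cn[0]] = 1.0
            continue
        a = nx.to_numpy_array(g, nodelist=cn, dtype=float)
        w, v = np.linalg.eigh(a)
        lead = np.abs(v[:, np.argmax(w)])
        lead /= np.linalg.norm(lead)
        ec.update(zip(cn, lead.tolist()))

    lac = {}
    nc = {}
    for v in nodes:
        nbrs = adj[v]
        if not nbrs:
            lac[v], nc[v] = 0.0, 0.0
            continue
        e = sum(1 for u in nbrs for w in nbrs if u < w and w in adj[u])
        lac[v] = 2.0 * e / len(nbrs)
        total = 0.0
        for u in nbrs:
            z = len(adj[u] & adj[v])
            denom = min(deg[u] - 1, deg[v] - 1)
            if denom > 0:
                total += z / denom
        nc[v] = total

    return {
        "DC": {v: float(deg[v]) for v in nodes},
        "BC": bc,
        "CC": cc,
        "EC": ec,
        "LAC": lac,
        "NC": nc,
    }


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by exact integer enumeration of the hypergeometric pmf."""
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1))
    return num / comb(N, n)


def bh_stepup_naive(pvalues) -> list[float]:
    """Textbook BH: q_i = min over {j : p_j >= p_i} of m*p_j/rank_j, capped at 1."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    rank = {}
    for r, i in enumerate(order, start=1):
        rank[i] = r
    q = []
    for i in range(m):
        candidates = [
            m * p[j] / rank[j] for j in range(m) if rank[j] >= rank[i]
        ]
        q.append(min(1.0, min(candidates)))
    return q


def connected_atlas_graphs(max_nodes: int = 7) -> list[nx.Graph]:
    """All non-isomorphic connected graphs with 1..max_nodes nodes."""
    from networkx.generators.atlas import graph_atlas_g

    out = []
    for g in graph_atlas_g():
        n = g.number_of_nodes()
        if 1 <= n <= max_nodes and nx.is_connected(g):
            out.append(nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes}))
    return out
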