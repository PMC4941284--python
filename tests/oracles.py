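"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and self-contained: plain BFS and
dynamic programming over shortest-path counts, exact integer arithmetic
for the hypergeometric tail, and the textbook Pearson formula.  None of
it shares code with the package under test.
"""

from __future__ import annotations

import math
from collections import deque


def bfs_dist_sigma(adj: dict, source) -> tuple[dict, dict]:
    """Unweighted shortest-path distances and path counts from ``source``."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def betweenness_oracle(adj: dict) -> dict:
    """Unnormalized betweenness, each unordered pair counted once.

    Uses the pair-counting identity sigma_st(v) = sigma_sv * sigma_vt
    when d(s,v) + d(v,t) = d(s,t); independent of Brandes' accumulation.
    """
    nodes = list(adj)
    dist, sigma = {}, {}
    for s in nodes:
        dist[s], sigma[s] = bfs_dist_sigma(adj, s)
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or t not in dist[v]:
                    continue
                if dist[s][v] + dist[v][t] == d_st:
                    bc[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return bc


def harmonic_oracle(adj: dict) -> dict:
    """Harmonic closeness: sum of reciprocal distances; 1/inf = 0."""
    out = {}
    for v in adj:
        dist, _ = bfs_dist_sigma(adj, v)
        out[v] = sum(1.0 / d for u, d in dist.items() if u != v)
    return out


def _k_core_members(adj: dict, k: int) -> set:
    """Node set surviving iterative removal of nodes with degree < k."""
    alive = {u: set(vs) for u, vs in adj.items()}
    changed = True
    while changed:
        changed = False
        for u in [u for u, vs in alive.items() if len(vs) < k]:
            for v in alive[u]:
                alive[v].discard(u)
            del alive[u]
            changed = True
    return set(alive)


def kcore_oracle(adj: dict) -> dict:
    """Coreness as the literal maximum k whose k-core still contains the node."""
    core = {u: 0 for u in adj}
    for k in range(1, len(adj) + 1):
        members = _k_core_members(adj, k)
        if not members:
            break
        for u in members:
            core[u] = k
    return core


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation: covariance over the product of sigmas."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    if sx == 0 or sy == 0:
        return 0.0
    return cov / (sx * sy)


def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct summation of exact binomial-coefficient terms."""
    denom = math.comb(N, n)
    total = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    )
    return total / denom
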