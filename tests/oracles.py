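"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written from definitions (Floyd–Warshall
distances, path-count dynamic programming, exhaustive k-core peeling, exact
binomial-coefficient summation, definition-formula Pearson) and shares no code
path with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

INF = float("inf")


def distance_matrix(nodes, edges):
    """All-pairs shortest paths by Floyd–Warshall on an unweighted graph."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for u, v in edges:
        d[idx[u]][idx[v]] = 1
        d[idx[v]][idx[u]] = 1
    for k in range(n):
        for i in range(n):
            dik = d[i][k]
            if dik == INF:
                continue
            for j in range(n):
                if dik + d[k][j] < d[i][j]:
                    d[i][j] = dik + d[k][j]
    return idx, d


def shortest_path_counts(nodes, edges, dist, idx):
    """nsp[i][j] = number of shortest i→j paths, by DP over distance."""
    n = len(nodes)
    adj = [[False] * n for _ in range(n)]
    for u, v in edges:
        adj[idx[u]][idx[v]] = adj[idx[v]][idx[u]] = True
    nsp = [[0] * n for _ in range(n)]
    for s in range(n):
        nsp[s][s] = 1
        order = sorted((j for j in range(n) if dist[s][j] < INF), key=lambda j: dist[s][j])
        for j in order:
            if j == s:
                continue
            nsp[s][j] = sum(
                nsp[s][w] for w in range(n) if adj[w][j] and dist[s][w] + 1 == dist[s][j]
            )
    return nsp


def brute_betweenness(nodes, edges):
    """Normalised betweenness: pair-dependency sums scaled per component."""
    idx, dist = distance_matrix(nodes, edges)
    nsp = shortest_path_counts(nodes, edges, dist, idx)
    n = len(nodes)
    comp_size = [sum(1 for j in range(n) if dist[i][j] < INF) for i in range(n)]
    raw = {v: 0.0 for v in nodes}
    for s, t in combinations(range(n), 2):
        if dist[s][t] == INF or nsp[s][t] == 0:
            continue
        for v in nodes:
            i = idx[v]
            if i in (s, t):
                continue
            if dist[s][i] + dist[i][t] == dist[s][t]:
                raw[v] += nsp[s][i] * nsp[i][t] / nsp[s][t]
    out = {}
    for v in nodes:
        nc = comp_size[idx[v]]
        out[v] = raw[v] / ((nc - 1) * (nc - 2) / 2.0) if nc > 2 else 0.0
    return out


def brute_closeness(nodes, edges, scale=100.0):
    """Wasserman–Faust corrected closeness: ((r-1)/(n-1)) * ((r-1)/farness)."""
    idx, dist = distance_matrix(nodes, edges)
    n = len(nodes)
    out = {}
    for v in nodes:
        i = idx[v]
        reach = [dist[i][j] for j in range(n) if dist[i][j] < INF and j != i]
        r = len(reach)
        if r == 0 or n == 1:
            out[v] = 0.0
        else:
            out[v] = scale * (r / (n - 1)) * (r / sum(reach))
    return out


def brute_kcore(nodes, edges):
    """K-core index by exhaustive peeling at every k."""
    out = {v: 0 for v in nodes}
    k = 0
    while True:
        k += 1
        alive = set(nodes)
        changed = True
        while changed:
            changed = False
            for v in list(alive):
                deg = sum(1 for u, w in edges if (u == v and w in alive) or (w == v and u in alive))
                if deg < k:
                    alive.discard(v)
                    changed = True
        if not alive:
            break
        for v in alive:
            out[v] = k
    return out


def brute_hypergeom_upper(k, K, n, N):
    """P(X >= k) by direct summation of the exact pmf."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def brute_pearson(x, y):
    """Pearson correlation straight from the definition formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    if sx == 0 or sy == 0:
        return None
    return cov / (sx * sy)


def brute_proximity(protein, targets, nodes, edges, kernel):
    """Σ kernel(d(protein, t)) over targets, distances from Floyd–Warshall."""
    idx, dist = distance_matrix(nodes, edges)
    total = 0.0
    for t in targets:
        if t not in idx:
            continue
        d = dist[idx[protein]][idx[t]]
        if d < INF:
            total += kernel(d)
    return total


def brute_rank_targets(compound_fp, panel, nodes, edges, kernel):
    """Full ranking by definition: Tanimoto vector vs proximity vectors.

    ``panel`` is a list of (fingerprint set, target set). Returns
    [(protein, score_or_None)] sorted undefined-last, score desc, symbol asc.
    """

    def tani(a, b):
        u = len(a | b)
        return len(a & b) / u if u else 0.0

    chem = [tani(set(compound_fp), set(fp)) for fp, _ in panel]
    results = []
    for prot in sorted(nodes):
        func = [brute_proximity(prot, tgts, nodes, edges, kernel) for _, tgts in panel]
        results.append((prot, brute_pearson(chem, func)))
    # ties rounded to 1e-12 so exact mathematical ties break by symbol
    results.sort(key=lambda r: (r[1] is None, -round(r[1], 12) if r[1] is not None else 0.0, r[0]))
    return results
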