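"""Independent straight-line oracles used only by the tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops, explicit formulas, no shared helpers. They exist so the pipeline can
be checked against a second, independently written implementation.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------- coupling

def rescale_oracle(u):
    lo, hi = min(u), max(u)
    return [(x - lo) / (hi - lo) for x in u]


def embed_oracle(u, m, tau):
    n = m * tau
    cols = []
    for i in range(len(u) - n):
        cols.append([u[i + k * tau] for k in range(m)])
    return cols


def distance_oracle(cols):
    size = len(cols)
    d = [[0.0] * size for _ in range(size)]
    for i in range(size):
        for j in range(size):
            d[i][j] = max(
                max(cols[i]) - min(cols[j]),
                max(cols[j]) - min(cols[i]),
            )
    return d


def joint_distance_oracle(d1, d2):
    size = len(d1)
    jd = [[0.0] * size for _ in range(size)]
    for i in range(size):
        for j in range(size):
            jd[i][j] = 1.0 - math.sqrt((1.0 - d1[i][j]) * (1.0 - d2[i][j]))
    return jd


def skewness_oracle(values):
    n = len(values)
    mu = sum(values) / n
    m2 = sum((v - mu) ** 2 for v in values) / n
    if m2 == 0:
        return 0.0
    m3 = sum((v - mu) ** 3 for v in values) / n
    return m3 / m2**1.5


def doane_oracle(values):
    n_obv = len(values)
    g1 = skewness_oracle(values)
    sigma = math.sqrt(6.0 * (n_obv - 2) / ((n_obv + 1) * (n_obv + 3)))
    b = 1.0 + math.log2(n_obv) + math.log2(1.0 + abs(g1) / sigma)
    return max(2, int(math.floor(b + 0.5)))


def histogram_oracle(values, bins):
    lo, hi = min(values), max(values)
    counts = [0] * bins
    if hi == lo:
        # numpy convention: degenerate range expands to [lo-0.5, lo+0.5]
        counts[bins // 2] = len(values)
        return counts
    edges = [lo + (hi - lo) * k / bins for k in range(bins + 1)]
    for v in values:
        placed = False
        for k in range(bins - 1):
            if edges[k] <= v < edges[k + 1]:
                counts[k] += 1
                placed = True
                break
        if not placed:
            counts[bins - 1] += 1  # rightmost bin closed
    return counts


def jdisten_pair_oracle(u1, u2, m=2, tau=1):
    """Full coupling of one raw channel pair, straight from the formulas."""
    c1 = embed_oracle(rescale_oracle(list(u1)), m, tau)
    c2 = embed_oracle(rescale_oracle(list(u2)), m, tau)
    jd = joint_distance_oracle(distance_oracle(c1), distance_oracle(c2))
    size = len(jd)
    values = [jd[i][j] for i in range(size) for j in range(size) if i != j]
    bins = doane_oracle(values)
    counts = histogram_oracle(values, bins)
    total = sum(counts)
    ent = 0.0
    for c in counts:
        if c > 0:
            rho = c / total
            ent -= rho * math.log2(rho)
    return ent / math.log2(bins)


def coupling_matrix_oracle(raw, m=2, tau=1):
    """raw: list of channels (lists of samples); returns nested list."""
    n_ch = len(raw)
    out = [[0.0] * n_ch for _ in range(n_ch)]
    for a in range(n_ch):
        for b in range(a + 1, n_ch):
            v = jdisten_pair_oracle(raw[a], raw[b], m, tau)
            out[a][b] = out[b][a] = v
    return out


# ------------------------------------------------------------------ graphs

INF = float("inf")


def floyd_warshall_oracle(n, edges):
    dist = [[INF] * n for _ in range(n)]
    for i in range(n):
        dist[i][i] = 0
    for a, b in edges:
        dist[a][b] = dist[b][a] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                alt = dist[i][k] + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    return dist


def components_oracle(n, dist):
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if dist[i][j] < INF}
        seen |= comp
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def clustering_oracle(n, edges):
    eset = {frozenset(e) for e in edges}
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    per_node = []
    for v in range(n):
        nb = sorted(adj[v])
        k = len(nb)
        if k < 2:
            per_node.append(0.0)
            continue
        links = sum(
            1
            for x in range(k)
            for y in range(x + 1, k)
            if frozenset((nb[x], nb[y])) in eset
        )
        per_node.append(2.0 * links / (k * (k - 1)))
    return per_node, sum(per_node) / n


def path_length_oracle(n, edges):
    dist = floyd_warshall_oracle(n, edges)
    comp = components_oracle(n, dist)[0]
    nodes = sorted(comp)
    if len(nodes) < 2:
        raise ValueError("largest component too small")
    total = count = 0
    for i in nodes:
        for j in nodes:
            if i != j:
                total += dist[i][j]
                count += 1
    return total / count


def eccentricity_oracle(n, edges):
    dist = floyd_warshall_oracle(n, edges)
    per_node = []
    for i in range(n):
        finite = [dist[i][j] for j in range(n) if j != i and dist[i][j] < INF]
        per_node.append(max(finite) if finite else 0)
    comp = sorted(components_oracle(n, dist)[0])
    mean_lcc = sum(per_node[v] for v in comp) / len(comp)
    return per_node, mean_lcc
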