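"""Independent brute-force oracles used only by the tests.

Each oracle is written from the definition of the quantity, in a style
deliberately different from the package implementation (explicit loops,
no shared helpers), so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def brute_force_es(gene_ids, metric_values, gene_set, exponent):
    """Weighted KS enrichment score by explicit position-by-position walk."""
    hits = [g in gene_set for g in gene_ids]
    n = len(gene_ids)
    n_hit = sum(hits)
    assert n_hit > 0
    denom = 0.0
    for g, m, h in zip(gene_ids, metric_values, hits):
        if h:
            denom += abs(m) ** exponent
    best = 0.0
    running = 0.0
    for g, m, h in zip(gene_ids, metric_values, hits):
        if h:
            if denom > 0:
                running += abs(m) ** exponent / denom
            else:
                running += 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def bfs_shortest_paths(adj, source):
    """(distance, path-count) dicts from one BFS."""
    dist = {source: 0}
    sigma = {source: 1}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0
                    nxt.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        frontier = nxt
    return dist, sigma


def pairwise_betweenness(nodes, edges):
    """Unnormalized betweenness by explicit all-pairs accumulation.

    For every unordered pair (s, t) each interior node v on some shortest
    path receives sigma_s(v) * sigma_t(v) / sigma_s(t) credit.
    """
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    bfs = {n: bfs_shortest_paths(adj, n) for n in nodes}
    score = {n: 0.0 for n in nodes}
    node_list = list(nodes)
    for i, s in enumerate(node_list):
        dist_s, sig_s = bfs[s]
        for t in node_list[i + 1 :]:
            if t not in dist_s:
                continue
            dist_t, sig_t = bfs[t]
            d = dist_s[t]
            for v in nodes:
                if v == s or v == t or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == d:
                    score[v] += sig_s[v] * sig_t[v] / sig_s[t]
    return score


def dense_pagerank(nodes, weighted_edges, alpha, tol=1e-14, max_iter=100000):
    """Weighted PageRank by dense power iteration on the transition matrix."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for a, b, weight in weighted_edges:
        w[idx[a], idx[b]] += weight
        w[idx[b], idx[a]] += weight
    out = w.sum(axis=1)
    p = np.zeros((n, n))
    for i in range(n):
        if out[i] > 0:
            p[i] = w[i] / out[i]
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        dangling = x[out == 0].sum()
        x_new = alpha * (x @ p) + alpha * dangling / n + (1 - alpha) / n
        if np.abs(x_new - x).sum() < tol:
            return dict(zip(nodes, x_new))
        x = x_new
    raise RuntimeError("oracle power iteration did not converge")
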