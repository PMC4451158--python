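"""Independent oracles used by the test suite.

These deliberately avoid the package's own dynamic programming / NJ code
paths: alignment scores come from exhaustive enumeration over monotone
matchings, and additive distance matrices are forward-simulated from
random trees built edge by edge.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_global_score(a: str, b: str, match, mismatch, gap_open, gap_extend) -> float:
    """Exhaustive optimum of affine-gap global alignment.

    Every global alignment induces a monotone matching of positions of
    *a* to positions of *b*; between consecutive matched pairs the
    unmatched characters of each sequence form gap runs, and (since
    gap_open <= gap_extend <= 0) arranging each run as one contiguous
    block is optimal. Enumerating all matchings therefore covers the
    optimum. Feasible for sequences up to ~length 7.
    """
    n, m = len(a), len(b)
    best = None
    for k in range(0, min(n, m) + 1):
        for ai in combinations(range(n), k):
            for bi in combinations(range(m), k):
                s = sum(match if a[x] == b[y] else mismatch for x, y in zip(ai, bi))
                prev_a = prev_b = -1
                for x, y in list(zip(ai, bi)) + [(n, m)]:
                    ga, gb = x - prev_a - 1, y - prev_b - 1
                    if ga:
                        s += gap_open + (ga - 1) * gap_extend
                    if gb:
                        s += gap_open + (gb - 1) * gap_extend
                    prev_a, prev_b = x, y
                if best is None or s > best:
                    best = s
    return float(best)


def random_additive_case(rng: np.random.Generator, n_taxa: int):
    """A random unrooted binary tree with positive edge lengths and the
    exact path-length distance matrix it induces.

    Returns ``(ids, D, bipartition_lengths, leaf_lengths)`` where
    ``bipartition_lengths`` maps each internal edge's canonical leaf-side
    (the side not containing the lexicographically smallest leaf) to its
    length, and ``leaf_lengths`` maps leaf name -> pendant edge length.
    """
    ids = [f"T{k:02d}" for k in range(n_taxa)]
    # adjacency with edge length; internal node names start with '#'
    adj: dict[str, dict[str, float]] = {}

    def add_edge(u, v):
        adj.setdefault(u, {})[v] = 0.0
        adj.setdefault(v, {})[u] = 0.0

    def drop_edge(u, v):
        del adj[u][v]
        del adj[v][u]

    add_edge("#0", ids[0])
    add_edge("#0", ids[1])
    add_edge("#0", ids[2])
    n_internal = 1
    for leaf in ids[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(0, len(edges))]
        w = f"#{n_internal}"
        n_internal += 1
        drop_edge(u, v)
        add_edge(u, w)
        add_edge(w, v)
        add_edge(w, leaf)
    for u in adj:
        for v in adj[u]:
            if u < v:
                ln = float(rng.uniform(0.05, 1.0))
                adj[u][v] = ln
                adj[v][u] = ln

    def leafset_below(u, parent) -> frozenset:
        if not u.startswith("#"):
            return frozenset([u])
        out = frozenset()
        for v in adj[u]:
            if v != parent:
                out |= leafset_below(v, u)
        return out

    all_leaves = frozenset(ids)
    ref = min(all_leaves)
    bip_lengths: dict[frozenset, float] = {}
    leaf_lengths: dict[str, float] = {}
    for u in adj:
        for v in adj[u]:
            if u < v:
                if not u.startswith("#") or not v.startswith("#"):
                    leaf = u if not u.startswith("#") else v
                    leaf_lengths[leaf] = adj[u][v]
                else:
                    side = leafset_below(v, u)
                    canon = all_leaves - side if ref in side else side
                    bip_lengths[canon] = adj[u][v]

    def dist_from(src) -> dict[str, float]:
        out = {src: 0.0}
        stack = [(src, None)]
        while stack:
            u, parent = stack.pop()
            for v, ln in adj[u].items():
                if v != parent:
                    out[v] = out[u] + ln
                    stack.append((v, u))
        return out

    D = np.zeros((n_taxa, n_taxa))
    for i, leaf in enumerate(ids):
        d = dist_from(leaf)
        for k, other in enumerate(ids):
            D[i, k] = d[other]
    return ids, D, bip_lengths, leaf_lengths
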