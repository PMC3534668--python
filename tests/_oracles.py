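"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, nested loops, union-find)
and shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def union_find_components(edges):
    """Partition nodes into connected components via plain union-find."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    return sorted((frozenset(g) for g in groups.values()), key=len, reverse=True)


def brute_force_curve(degrees):
    """curve(k) = #lines with usage >= k, by nested loops."""
    degrees = list(degrees)
    kmax = max(degrees)
    return {k: sum(1 for d in degrees if d >= k) for k in range(1, kmax + 1)}


def brute_force_curve_distance(deg_a, deg_b):
    ca, cb = brute_force_curve(deg_a), brute_force_curve(deg_b)
    kmax = max(max(ca), max(cb))
    return sum(abs(ca.get(k, 0) - cb.get(k, 0)) for k in range(1, kmax + 1))


def grid_search_alpha(values, xmin, lo=1.0001, hi=6.0, step=1e-4):
    """Maximize the discrete power-law log-likelihood on a dense alpha grid."""
    from scipy.special import zeta  # independent of the package's call path

    tail = np.asarray([v for v in values if v >= xmin], dtype=float)
    s = np.log(tail).sum()
    alphas = np.arange(lo, hi + step, step)
    ll = -alphas * s - len(tail) * np.log(zeta(alphas, xmin))
    return float(alphas[np.argmax(ll)])


def hypergeom_tail_enumeration(population, successes, draws, observed):
    """P(X >= observed) by exhaustive enumeration of all draws."""
    items = [1] * successes + [0] * (population - successes)
    total = hits = 0
    for combo in itertools.combinations(range(population), draws):
        total += 1
        if sum(items[i] for i in combo) >= observed:
            hits += 1
    return hits / total


def rank_pearson_distance(a, b):
    """1 - Spearman via explicit mid-ranking then Pearson correlation."""

    def midrank(x):
        x = np.asarray(x, dtype=float)
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(len(x), dtype=float)
        i = 0
        sx = x[order]
        while i < len(x):
            j = i
            while j + 1 < len(x) and sx[j + 1] == sx[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    ra, rb = midrank(a), midrank(b)
    return 1.0 - float(np.corrcoef(ra, rb)[0, 1])


def naive_upgma(labels, dist_matrix):
    """O(n^3) UPGMA recomputing every cluster distance as the mean of raw
    leaf-pair distances (the defining identity of average linkage)."""
    d = np.asarray(dist_matrix, dtype=float)
    idx = {l: i for i, l in enumerate(labels)}
    clusters = [tuple([l]) for l in labels]
    merges = []

    def cdist(a, b):
        return float(np.mean([[d[idx[x], idx[y]] for y in b] for x in a]))

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            cand = (cdist(a, b), a, b)
            if best is None or cand < best:
                best = cand
        h, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        node = tuple(sorted(a + b))
        clusters.append(node)
        merges.append((a, b, h, len(node)))
    return merges
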