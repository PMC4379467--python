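"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and direct
formula application — and shares no code with the package implementations
it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def all_simple_paths(adj: dict, s, t) -> list[list]:
    """Every self-avoiding path from s to t, by explicit DFS."""
    out: list[list] = []
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            out.append(path)
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))
    return out


def brute_betweenness(graph) -> tuple[dict, dict]:
    """Node and edge betweenness by enumerating all shortest paths.

    Unordered pairs counted once, path endpoints excluded for nodes; each
    pair contributes (paths through element) / (total shortest paths).
    """
    nodes = list(graph.nodes())
    adj = {v: sorted(graph.neighbors(v)) for v in nodes}
    node_b = {v: 0.0 for v in nodes}
    edge_b = {frozenset(e): 0.0 for e in graph.edges()}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_simple_paths(adj, s, t)
        if not paths:
            continue
        shortest_len = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == shortest_len]
        sigma = len(shortest)
        for p in shortest:
            for v in p[1:-1]:
                node_b[v] += 1.0 / sigma
            for e in zip(p, p[1:]):
                edge_b[frozenset(e)] += 1.0 / sigma
    return node_b, edge_b


def naive_benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """O(m^2) step-up adjustment straight from the definition."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def exact_upper_hypergeom(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) via exact rational arithmetic."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


def exact_fisher_two_sided(table) -> float:
    """Two-sided Fisher p: sum of all fixed-margin tables with probability
    at most the observed table's (exact rational arithmetic)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(N, c1))

    observed = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    cutoff = observed * (1 + Fraction(1, 10**9))
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= cutoff))


def best_two_partition(dist: np.ndarray) -> frozenset:
    """Exhaustive best split of n items into two non-empty clusters,
    minimizing the total within-cluster pairwise distance."""
    n = dist.shape[0]
    best, best_cost = None, np.inf
    for mask in range(1, 2 ** (n - 1)):
        left = [i for i in range(n) if (mask >> i) & 1]
        right = [i for i in range(n) if not (mask >> i) & 1]
        if not left or not right:
            continue
        cost = sum(dist[i, j] for g in (left, right) for i, j in itertools.combinations(g, 2))
        if cost < best_cost:
            best_cost = cost
            best = frozenset([frozenset(left), frozenset(right)])
    return best


def spearman_rho_from_ranks(y: np.ndarray, x: np.ndarray) -> float:
    """Textbook tie-free Spearman: 1 - 6 sum d^2 / (n(n^2-1))."""
    y_rank = np.argsort(np.argsort(y)) + 1
    x_rank = np.argsort(np.argsort(x)) + 1
    n = len(y)
    d2 = float(np.sum((y_rank - x_rank) ** 2))
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))
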