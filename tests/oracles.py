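"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and scipy's
graph routines): distances come from a hand-written Floyd-Warshall,
overlap from explicit set enumeration, and the CV ranking from plain
Python statistics.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def local_efficiency_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    scores = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            scores.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        scores.append(global_efficiency_oracle(sub))
    return float(np.mean(scores))


def edge_overlap_oracle(adj_a: np.ndarray, adj_b: np.ndarray) -> float:
    n = adj_a.shape[0]
    ea = {(i, j) for i, j in combinations(range(n), 2) if adj_a[i, j]}
    eb = {(i, j) for i, j in combinations(range(n), 2) if adj_b[i, j]}
    return 2.0 * len(ea & eb) / (len(ea) + len(eb))


def consistency_ranking_oracle(stacked, labels):
    """Rank node pairs by (CV asc, mean desc, lexicographic pair)."""
    n = len(labels)
    pairs = list(combinations(range(n), 2))
    keyed = []
    for m, (i, j) in enumerate(pairs):
        vals = [row[m] for row in stacked]
        mu = sum(vals) / len(vals)
        if mu == 0:
            cv = math.inf
        else:
            var = sum((v - mu) ** 2 for v in vals) / (len(vals) - 1)
            cv = math.sqrt(var) / mu
        keyed.append((cv, -mu, tuple(sorted((labels[i], labels[j]))), m))
    keyed.sort()
    return [m for *_, m in keyed]


def random_binary_adjacency(rng: np.random.Generator, n: int, p: float = 0.5):
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return a | a.T
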