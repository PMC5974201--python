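"""Slow reference implementations used to validate the fast paths.

These deliberately use the most literal formulation of each definition —
triple loops, exhaustive path enumeration, exact combinatorial sums — and
share no code with the production implementations they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np


def tom_reference(adj: np.ndarray) -> np.ndarray:
    """Topological overlap by the literal triple-loop definition."""
    A = np.array(adj, dtype=float)
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    k = [sum(A[i, u] for u in range(n)) for i in range(n)]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n))
            tom[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1.0 - A[i, j])
    return tom


def hypergeom_tail_reference(k: int, n_universe: int, n_set: int, n_draw: int) -> float:
    """Exact upper tail P(X >= k) for the hypergeometric, by combinatorial sum."""
    total = comb(n_universe, n_draw)
    acc = Fraction(0)
    for i in range(k, min(n_set, n_draw) + 1):
        acc += Fraction(comb(n_set, i) * comb(n_universe - n_set, n_draw - i), total)
    return float(min(acc, Fraction(1)))


def edge_betweenness_reference(
    edges: list[tuple[str, str, float]],
    directed: bool = False,
    tol: float = 1e-12,
) -> dict[tuple[str, str], float]:
    """Weighted edge betweenness by exhaustive simple-path enumeration.

    *edges* are (source, target, weight>0) triples; weights act as distances.
    All simple paths between each pair are enumerated, the minimum-cost ones
    identified (cost ties within *tol*), and each tied path's edges credited
    1/#ties for that pair.  Pairs are ordered for directed graphs and
    unordered for undirected ones.  Returns scores keyed by the input edge
    (as given).
    """
    g = nx.DiGraph() if directed else nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    scores: dict[tuple[str, str], float] = {(u, v): 0.0 for u, v, _ in edges}

    def credit(u: str, v: str, amount: float) -> None:
        if (u, v) in scores:
            scores[(u, v)] += amount
        elif not directed and (v, u) in scores:
            scores[(v, u)] += amount

    nodes = list(g.nodes)
    for i, s in enumerate(nodes):
        for t in nodes:
            if s == t:
                continue
            if not directed and nodes.index(t) < i:
                continue  # unordered pairs once
            if not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_simple_paths(g, s, t))
            costs = [
                sum(g[a][b]["weight"] for a, b in zip(p, p[1:])) for p in paths
            ]
            best = min(costs)
            tied = [p for p, c in zip(paths, costs) if c <= best + tol]
            share = 1.0 / len(tied)
            for p in tied:
                for a, b in zip(p, p[1:]):
                    credit(a, b, share)
    return scores
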