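"""Independent reference implementations used only to check the package.

These are deliberately naive (exhaustive recursion, Floyd-Warshall over a
dense matrix) and share no code with songsyntax.
"""

from __future__ import annotations

import itertools
import sys
from functools import lru_cache

import numpy as np

sys.setrecursionlimit(10000)


def recursive_levenshtein(a: tuple, b: tuple) -> int:
    """Plain textbook recursion over edit scripts, memoized on suffixes."""

    @lru_cache(maxsize=None)
    def rec(x: tuple, y: tuple) -> int:
        if not x:
            return len(y)
        if not y:
            return len(x)
        cost = 0 if x[0] == y[0] else 1
        return min(
            rec(x[1:], y[1:]) + cost,  # match / substitute
            rec(x[1:], y) + 1,  # delete from x
            rec(x, y[1:]) + 1,  # insert into x
        )

    return rec(tuple(a), tuple(b))


def floyd_warshall_metrics(n: int, edges: list[tuple[int, int]]) -> tuple[float, float]:
    """(average path length over reachable pairs, density) of a simple
    undirected graph given as an edge list on nodes 0..n-1."""
    inf = float("inf")
    d = np.full((n, n), inf)
    np.fill_diagonal(d, 0.0)
    for u, v in edges:
        if u != v:
            d[u, v] = d[v, u] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    vals = [d[i, j] for i, j in itertools.combinations(range(n), 2) if d[i, j] < inf]
    apl = sum(vals) / len(vals) if vals else float("nan")
    simple_edges = {frozenset(e) for e in edges if e[0] != e[1]}
    density = len(simple_edges) / (n * (n - 1) / 2) if n >= 2 else float("nan")
    return apl, density


def random_graph(rng: np.random.Generator, max_nodes: int = 8) -> tuple[int, list[tuple[int, int]]]:
    n = int(rng.integers(2, max_nodes + 1))
    p = rng.uniform(0.1, 0.9)
    edges = [(i, j) for i, j in itertools.combinations(range(n), 2) if rng.random() < p]
    return n, edges
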