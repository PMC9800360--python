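"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms: coreness is
decided per candidate k by repeated deletion, and Kendall counts are
accumulated with explicit pair loops.
"""

from __future__ import annotations

import networkx as nx


def kcore_members(graph: nx.Graph, k: int) -> set:
    """Nodes of the maximal subgraph with minimum degree >= k."""
    h = graph.copy()
    while True:
        drop = [v for v in h if h.degree(v) < k]
        if not drop:
            return set(h)
        h.remove_nodes_from(drop)


def brute_coreness(graph: nx.Graph) -> dict:
    """Coreness of every node: the largest k whose k-core contains it."""
    out = {v: 0 for v in graph}
    max_deg = max((d for _, d in graph.degree()), default=0)
    for k in range(1, max_deg + 1):
        for v in kcore_members(graph, k):
            out[v] = k
    return out


def brute_kendall(x, y):
    """(n, nc, nd, tau) by exhaustive enumeration of all unordered pairs."""
    n = len(x)
    nc = nd = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = int(x[i] > x[j]) - int(x[i] < x[j])
            dy = int(y[i] > y[j]) - int(y[i] < y[j])
            if dx * dy > 0:
                nc += 1
            elif dx * dy < 0:
                nd += 1
    return n, nc, nd, 2.0 * (nc - nd) / (n * (n - 1))
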