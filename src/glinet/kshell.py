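"""K-shell (coreness) decomposition and the global-influence term.

The K-shell index of a node is the largest ``k`` such that the node
survives in the maximal subgraph of minimum degree ``k`` (the k-core).
It is computed by iterative peeling: for k = 0, 1, 2, ... repeatedly
delete every node whose current degree is at most k until none remain,
assigning the deleted nodes shell k.  Peeling uses a bucket-by-degree
structure, so the decomposition runs in O(|V| + |E|).

Within the influence score the shell index is used unchanged as the
node's *global* influence: nodes deep in the core occupy structurally
central positions regardless of their raw degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx


@dataclass(frozen=True)
class ShellAssignment:
    """Node -> shell index ``Ks(v)`` from the core decomposition.

    Invariants: ``0 <= ks(v) <= degree(v)``, and every node with
    ``ks(v) >= 1`` has at least ``ks(v)`` neighbours of shell >= ``ks(v)``
    (the coreness property).  Isolated nodes receive shell 0, which is
    forced by peeling at k = 0 and keeps the combined score well-defined
    on networks with degree-0 nodes.
    """

    ks: Mapping[object, int]

    def __getitem__(self, node) -> int:
        return self.ks[node]

    def __contains__(self, node) -> bool:
        return node in self.ks

    def __len__(self) -> int:
        return len(self.ks)


def kshell_decompose(graph: nx.Graph) -> ShellAssignment:
    """Assign every node its K-shell index by iterative minimum-degree peeling.

    A lazy min-heap keyed by current degree yields the next node to peel;
    stale heap entries (left behind when a neighbour's degree drops) are
    skipped on pop.  The running shell index is the largest degree floor
    seen so far, which is exactly the layer-by-layer peeling rule.
    """
    import heapq

    degree = {v: d for v, d in graph.degree()}
    # tie-break on an insertion counter so labels never need comparing
    counter = 0
    heap: list[tuple[int, int, object]] = []
    for v, d in degree.items():
        heap.append((d, counter, v))
        counter += 1
    heapq.heapify(heap)

    ks: dict = {}
    k = 0
    while heap:
        d, _, v = heapq.heappop(heap)
        if v in ks or degree[v] != d:
            continue  # stale entry
        k = max(k, d)
        ks[v] = k
        for u in graph[v]:
            if u not in ks:
                degree[u] -= 1
                heapq.heappush(heap, (degree[u], counter, u))
                counter += 1
    return ShellAssignment(ks=ks)


def global_influence(shells: ShellAssignment, v) -> int:
    """Global influence of ``v``: its shell index, unchanged."""
    if v not in shells:
        raise KeyError(f"node {v!r} not in shell assignment")
    return shells[v]
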