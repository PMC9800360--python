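"""The GLI influence score: local structure + coreness, per node.

For an undirected simple graph the score of node ``vi`` combines

* **personal influence** ``P(vi) = d(vi)`` — the node's own degree;
* **neighbour contributions**: each neighbour ``vj`` donates a *given
  value* ``П(vj) = d(vj) * Jacc(vi, vj) + Ks(vj)``, its degree weighted by
  the closed-neighbourhood Jaccard similarity of the pair plus its shell
  index, so structurally similar, well-connected, deeply cored neighbours
  contribute most;
* **normalisation**: the sum of given values is divided by the network
  maximum degree ``maxD`` (the largest number of neighbours any node
  could collect contributions from), giving ``N(vi) = Sum(vi)/maxD``;
* **local influence** ``Local(vi) = P(vi) + N(vi)``;
* **global influence** ``Global(vi) = Ks(vi)`` (see :mod:`glinet.kshell`);
* **total influence** ``I(vi) = Local(vi) + Global(vi)``.

Jaccard similarity uses *closed* neighbourhoods (the node together with
its neighbours), so the ratio is always defined and two endpoints of an
isolated edge have similarity 1.  Degree-0 nodes score exactly 0 in every
component, so the method runs unmodified on networks with isolated nodes.

The identities ``Local = P + N`` and ``I = Local + Global`` hold exactly
(they are definitions, not fits).  All arithmetic is double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .graph import _label_sort_key, degree_map
from .kshell import ShellAssignment, kshell_decompose

#: column order of a GLI score table
SCORE_COLUMNS = ("P", "Sum", "N", "Local", "Global", "I")


@dataclass(frozen=True)
class GivenValue:
    """Influence donated to a focal node by one adjacent node."""

    from_node: object
    value: float


def closed_neighborhood(graph: nx.Graph, v) -> frozenset:
    """``{v}`` together with the neighbours of ``v``."""
    if v not in graph:
        raise KeyError(f"node {v!r} not in graph")
    return frozenset(graph[v]) | {v}


def jaccard(graph: nx.Graph, vi, vj) -> float:
    """Closed-neighbourhood Jaccard similarity of ``vi`` and ``vj``.

    ``|n(vi) ∩ n(vj)| / |n(vi) ∪ n(vj)|`` with ``n(v)`` the closed
    neighbourhood; the union always contains both nodes, so the ratio is
    defined for every pair, and ``jaccard(v, v) == 1``.
    """
    ni = closed_neighborhood(graph, vi)
    nj = closed_neighborhood(graph, vj)
    return len(ni & nj) / len(ni | nj)


def given_value(graph: nx.Graph, shells: ShellAssignment, vi, vj) -> GivenValue:
    """Given value ``П(vj) = d(vj) * Jacc(vi, vj) + Ks(vj)`` of neighbour ``vj``.

    ``vj`` must be adjacent to ``vi``; the contribution is defined only
    along edges.
    """
    if not graph.has_edge(vi, vj):
        raise ValueError(f"{vj!r} is not adjacent to {vi!r}")
    value = graph.degree(vj) * jaccard(graph, vi, vj) + shells[vj]
    return GivenValue(from_node=vj, value=value)


def neighbor_sum(graph: nx.Graph, shells: ShellAssignment, vi) -> float:
    """Sum of given values over all neighbours of ``vi`` (0 if isolated).

    Terms are added in deterministic (sorted-label) order so the result
    does not depend on adjacency iteration order.
    """
    if vi not in graph:
        raise KeyError(f"node {vi!r} not in graph")
    neighbors = sorted(graph[vi], key=_label_sort_key)
    return float(sum(given_value(graph, shells, vi, vj).value for vj in neighbors))


def local_influence(
    graph: nx.Graph, shells: ShellAssignment, vi, maxD: int
) -> tuple[float, float, float]:
    """Return ``(P, N, Local)`` for node ``vi``.

    ``maxD`` is the network-wide maximum degree; when the graph is
    edgeless (``maxD == 0``) the normalised term is 0.
    """
    p = float(graph.degree(vi))
    s = neighbor_sum(graph, shells, vi)
    n = s / maxD if maxD > 0 else 0.0
    return p, n, p + n


def gli_score(graph: nx.Graph) -> pd.DataFrame:
    """Score every node; returns a table with columns P, Sum, N, Local, Global, I.

    The table is indexed by node label in deterministic order and is
    identical (up to the label mapping) for any relabelling or edge-order
    permutation of the input graph.
    """
    shells = kshell_decompose(graph)
    dm = degree_map(graph)
    maxD = dm.max_degree
    nodes = sorted(graph.nodes, key=_label_sort_key)
    rows = []
    for vi in nodes:
        p = float(dm[vi])
        s = neighbor_sum(graph, shells, vi)
        n = s / maxD if maxD > 0 else 0.0
        local = p + n
        g = float(shells[vi])
        rows.append((p, s, n, local, g, local + g))
    return pd.DataFrame(rows, index=pd.Index(nodes, name="node"), columns=list(SCORE_COLUMNS))


def rank_nodes(scores: pd.DataFrame | pd.Series | dict) -> list:
    """Nodes in non-increasing score order; ties broken by ascending label.

    ``scores`` may be a GLI table (the ``I`` column is used), a Series, or
    a plain mapping node -> score.
    """
    series = _as_series(scores)
    return sorted(
        series.index,
        key=lambda v: (-float(series[v]),) + (_label_sort_key(v),),
    )


def _as_series(scores) -> pd.Series:
    if isinstance(scores, pd.DataFrame):
        return scores["I"] if "I" in scores.columns else scores.iloc[:, -1]
    if isinstance(scores, pd.Series):
        return scores
    return pd.Series(dict(scores))
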