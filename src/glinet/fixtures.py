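"""Packaged worked-example data and seeded synthetic-network generators.

The worked example is a 15-node network (``v1`` .. ``v15``) used to walk
through the influence score one quantity at a time: per-node degrees,
shell indices, the similarity and given values of ``v1``'s neighbourhood,
and the final influence table.  The published description prints those
per-node values but not the edge list; the packaged topology was
reconstructed offline by constraint search over all 15-node graphs
consistent with the printed values (the constraints force a K4 3-core on
``v1..v4``, six pendant leaves with uniquely determined hosts, and
degree-2 ``v9``/``v10``; exactly one of the six admissible completions
also reproduces the full published influence ordering).  The test suite
asserts the constraints, not the search.

One published cell is internally inconsistent: the influence of ``v6``
is printed as 5.54, but no graph satisfying the degree/shell/similarity
tables can produce it (the three admissible neighbourhoods of ``v6``
give 5.64, 5.68 or 5.85).  The packaged graph yields 5.64, which
preserves the printed ranking; ``influence_recomputed`` carries the
self-consistent values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import networkx as nx

from .graph import read_edge_list


@dataclass(frozen=True)
class WorkedExampleConstants:
    """Published per-node values of the 15-node walkthrough.

    ``degrees``, ``ks``: for ``v1`` and its six neighbours.
    ``jaccard_v1``, ``given_values_v1``: similarity and given value of
    each neighbour of ``v1``.
    ``max_degree``, ``local_v1``, ``influence_v1``: the scalar steps of
    the walkthrough.
    ``influence``: the published influence of all 15 nodes at two
    decimals, in ranking order; ``influence[\"v6\"]`` is the misprinted
    cell (see module docstring).
    ``influence_recomputed``: the self-consistent two-decimal values
    produced by the packaged graph.
    """

    degrees: Mapping[str, int]
    ks: Mapping[str, int]
    jaccard_v1: Mapping[str, float]
    given_values_v1: Mapping[str, float]
    max_degree: int
    local_v1: float
    influence_v1: float
    influence: Mapping[str, float]
    influence_recomputed: Mapping[str, float]


_CONSTANTS = WorkedExampleConstants(
    degrees={"v1": 6, "v2": 5, "v3": 4, "v4": 5, "v5": 3, "v6": 2, "v8": 5},
    ks={"v1": 3, "v2": 3, "v3": 3, "v4": 3, "v5": 2, "v6": 2, "v8": 2},
    jaccard_v1={
        "v2": 0.625,
        "v3": 0.5,
        "v4": 0.444444,
        "v5": 0.375,
        "v6": 0.4285714,
        "v8": 0.3,
    },
    given_values_v1={
        "v2": 6.125,
        "v3": 5.0,
        "v4": 5.222222,
        "v5": 3.125,
        "v6": 2.857143,
        "v8": 3.5,
    },
    max_degree=6,
    local_v1=10.304894,
    influence_v1=13.304894,
    influence={
        "v1": 13.30,
        "v2": 12.17,
        "v4": 11.18,
        "v3": 10.18,
        "v8": 9.70,
        "v5": 6.71,
        "v9": 5.67,
        "v6": 5.54,  # misprint; self-consistent value is 5.64
        "v10": 3.85,
        "v13": 2.78,
        "v14": 2.78,
        "v15": 2.77,
        "v11": 2.61,
        "v7": 2.58,
        "v12": 2.39,
    },
    influence_recomputed={
        "v1": 13.30,
        "v2": 12.17,
        "v4": 11.19,
        "v3": 10.19,
        "v8": 9.70,
        "v5": 6.71,
        "v9": 5.67,
        "v6": 5.64,
        "v10": 3.85,
        "v13": 2.78,
        "v14": 2.78,
        "v15": 2.77,
        "v11": 2.61,
        "v7": 2.58,
        "v12": 2.39,
    },
)


def worked_example_constants() -> WorkedExampleConstants:
    """The published walkthrough values, verbatim."""
    return _CONSTANTS


def worked_example_graph() -> nx.Graph:
    """The reconstructed 15-node walkthrough network."""
    ref = resources.files("glinet") / "data" / "worked_example.edgelist"
    with ref.open("r") as fh:
        return read_edge_list(fh)


def synthetic_network(
    model: str,
    n: int,
    p: float | None = None,
    m: int | None = None,
    seed: int | None = None,
) -> nx.Graph:
    """Seeded generator for test and benchmark networks.

    model : ``er`` (Erdős–Rényi G(n, p)), ``ba`` (Barabási–Albert with
        ``m`` attachments per new node), or the deterministic topologies
        ``ring``, ``star``, ``complete``, ``path``.
    n : number of nodes (the star has ``n - 1`` leaves).
    p, m : model-specific parameters (``er`` and ``ba`` respectively).
    seed : RNG seed for the stochastic models; same seed, same edge set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model == "er":
        if p is None or not (0.0 <= p <= 1.0):
            raise ValueError("er requires edge probability p in [0, 1]")
        return nx.gnp_random_graph(n, p, seed=seed)
    if model == "ba":
        if m is None or not (1 <= m < n):
            raise ValueError("ba requires attachment count 1 <= m < n")
        return nx.barabasi_albert_graph(n, m, seed=seed)
    if model == "ring":
        return nx.cycle_graph(n)
    if model == "star":
        return nx.star_graph(n - 1)
    if model == "complete":
        return nx.complete_graph(n)
    if model == "path":
        return nx.path_graph(n)
    raise ValueError(
        f"unknown model {model!r}; expected er, ba, ring, star, complete or path"
    )
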