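"""Rank agreement (Kendall tau-a), baseline centralities and benchmark protocols.

The agreement between a centrality and the epidemic ground truth is the
Kendall coefficient over all unordered node pairs,

    tau(X, Y) = 2 * (nc - nd) / (n * (n - 1)),

where ``nc`` counts pairs ordered the same strict way by both score
sequences and ``nd`` pairs ordered strictly opposite.  This is the tau-a
convention: pairs tied in either sequence count in neither ``nc`` nor
``nd`` and the denominator is the total pair count, so heavy tying pulls
tau towards zero.  (Library defaults usually compute tau-b, which
rescales for ties; :func:`kendall_tau_b` exposes it as a cross-check.)

Baseline centralities (degree, closeness, betweenness, eigenvector,
PageRank, K-shell) use their standard textbook definitions via networkx;
they are comparison material, not part of the scoring method itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .gli import gli_score, rank_nodes, _as_series
from .kshell import kshell_decompose
from .spread import SpreadParams, all_spreading_powers

#: recognised baseline method keys
BASELINE_METHODS = ("dc", "cc", "bc", "ec", "pr", "kshell")

#: iteration tolerance for the eigenvector-style baselines
_ITER_TOL = 1e-8
#: PageRank damping factor
_PR_DAMPING = 0.85


@dataclass(frozen=True)
class RankComparison:
    """Pairwise agreement between two score sequences over the same items."""

    n: int
    concordant: int
    discordant: int
    tau: float


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> RankComparison:
    """Kendall tau-a between two aligned score sequences.

    ``x[i]`` and ``y[i]`` must score the same item.  Requires ``n >= 2``.
    Ties in either sequence make the pair neither concordant nor
    discordant; the denominator stays ``n * (n - 1) / 2`` pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("score sequences must be 1-D and aligned")
    n = x.size
    if n < 2:
        raise ValueError("need at least two items")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    upper = np.triu_indices(n, k=1)
    nc = int(np.sum(prod[upper] > 0))
    nd = int(np.sum(prod[upper] < 0))
    tau = 2.0 * (nc - nd) / (n * (n - 1))
    return RankComparison(n=n, concordant=nc, discordant=nd, tau=tau)


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected tau-b via scipy, as an optional cross-check only."""
    from scipy.stats import kendalltau

    return float(kendalltau(x, y).statistic)


def baseline_scores(graph: nx.Graph, method: str) -> pd.Series:
    """One scalar score per node under a standard centrality definition.

    method is one of ``dc`` (degree, raw edge count), ``cc`` (closeness;
    on disconnected graphs computed within the node's component and
    scaled by the component's size fraction), ``bc`` (betweenness),
    ``ec`` (eigenvector, power iteration to 1e-8), ``pr`` (PageRank,
    damping 0.85, tolerance 1e-8) or ``kshell`` (shell index).
    """
    if method == "dc":
        return pd.Series(dict(graph.degree()), name="dc").astype(float)
    if method == "cc":
        # wf_improved scales closeness by (reachable - 1)/(n - 1)
        return pd.Series(nx.closeness_centrality(graph, wf_improved=True), name="cc")
    if method == "bc":
        return pd.Series(nx.betweenness_centrality(graph, normalized=True), name="bc")
    if method == "ec":
        return pd.Series(
            nx.eigenvector_centrality(graph, max_iter=10_000, tol=_ITER_TOL),
            name="ec",
        )
    if method == "pr":
        return pd.Series(
            nx.pagerank(graph, alpha=_PR_DAMPING, tol=_ITER_TOL), name="pr"
        )
    if method == "kshell":
        return pd.Series(dict(kshell_decompose(graph).ks), name="kshell").astype(float)
    raise ValueError(f"unknown method {method!r}; expected one of {BASELINE_METHODS}")


def method_scores(graph: nx.Graph, method: str) -> pd.Series:
    """Scores for ``method``, which may be ``gli`` or any baseline key."""
    if method == "gli":
        return gli_score(graph)["I"].rename("gli")
    return baseline_scores(graph, method)


def alpha_sweep_kendall(
    graph: nx.Graph,
    scorers: Mapping[str, Mapping | pd.Series],
    alphas: Iterable[float] = tuple(np.round(np.arange(0.01, 0.101, 0.01), 2)),
    params: SpreadParams = SpreadParams(),
    model: str = "sir",
) -> pd.DataFrame:
    """Kendall tau of each scorer against simulated spreading power, per alpha.

    For every infection probability in ``alphas`` (default 0.01..0.10 in
    steps of 0.01) the spreading power of every node is estimated by
    Monte-Carlo simulation and tau-a is computed between each scorer's
    values and the spreading powers.  Row ``alpha`` x column ``scorer``.

    Reproducibility: the ground truth at the i-th alpha uses substreams
    derived from ``(params.seed, i)``, so any sub-grid of the sweep
    recomputes identically under the same experiment seed.
    """
    nodes = None
    series = {}
    for name, sc in scorers.items():
        s = _as_series(sc)
        series[name] = s
        if nodes is None:
            nodes = list(s.index)
        elif set(s.index) != set(nodes):
            raise ValueError(f"scorer {name!r} does not cover the node set")
    if nodes is None:
        raise ValueError("at least one scorer is required")

    rows = {}
    base_seed = params.seed
    for i, alpha in enumerate(alphas):
        sub_seed = None if base_seed is None else int(base_seed) * 1000 + i
        p = SpreadParams(
            alpha=float(alpha),
            beta=params.beta,
            max_steps=params.max_steps,
            iterations=params.iterations,
            seed=sub_seed,
        )
        truth = all_spreading_powers(graph, model=model, params=p)
        truth = truth.loc[nodes]
        rows[float(alpha)] = {
            name: kendall_tau(s.loc[nodes].to_numpy(), truth.to_numpy()).tau
            for name, s in series.items()
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "alpha"
    return out[list(scorers)]


def top_k(scores, k: int = 15) -> list:
    """First ``k`` nodes of the ranking (ties broken by ascending label).

    ``k`` larger than the node count is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = rank_nodes(scores)
    if k > len(ranked):
        import warnings

        warnings.warn(
            f"k={k} exceeds node count {len(ranked)}; returning full ranking",
            stacklevel=2,
        )
        k = len(ranked)
    return ranked[:k]
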