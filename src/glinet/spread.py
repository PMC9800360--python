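"""Stochastic SIR/SI spreading on graphs — the epidemic ground truth.

A node ranking is validated by seeding an epidemic at each node and
measuring how far it spreads; the mean outbreak size is the node's
*spreading power*, and rank correlation between a centrality and the
spreading powers is the figure of merit.

Dynamics are discrete and synchronous.  At each step every currently
infectious node independently infects each susceptible neighbour with
probability ``alpha`` (a node reached by several infectious neighbours in
one step becomes infected once); afterwards every node that was
infectious at the start of the step recovers with probability ``beta``.
Newly infected nodes start transmitting the following step, so with
``beta = 1`` each node transmits during exactly one step — the standard
convention in this literature.  The SI model uses the same transmission
rule with no recovery; infection is irreversible.

Alongside the node-level simulators, :func:`meanfield_sir` iterates the
deterministic compartment increments

    dS = -alpha * S * I,   dI = alpha * S * I - beta * I,   dR = beta * I

with unit time step; the increments sum to zero, so the population total
is conserved exactly.

Reproducibility: every stochastic entry point takes an explicit RNG or a
seed; batch helpers derive one independent substream per node from the
experiment seed and a node counter, so results are bit-reproducible and
insensitive to evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph import _label_sort_key

#: SI infection rate used in the SI benchmark: (1/2)**theta with theta = 3
SI_DEFAULT_THETA = 3


def si_infection_rate(theta: int = SI_DEFAULT_THETA) -> float:
    """Benchmark SI infection probability ``(1/2)**theta`` (0.125 for theta=3)."""
    return 0.5**theta


@dataclass(frozen=True)
class SpreadParams:
    """Simulation parameters.

    alpha : per-contact, per-step infection probability in [0, 1]
    beta : per-step recovery probability in [0, 1] (ignored by SI)
    max_steps : step cap; SIR usually terminates earlier on its own
    iterations : Monte-Carlo repetitions for averaged quantities
    seed : experiment seed for derived substreams
    """

    alpha: float = 0.01
    beta: float = 1.0
    max_steps: int = 30
    iterations: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.max_steps < 1 or self.iterations < 1:
            raise ValueError("max_steps and iterations must be >= 1")


@dataclass(frozen=True)
class SpreadTrajectory:
    """Per-step compartment counts of one run (or a deterministic iteration)."""

    t: np.ndarray
    susceptible: np.ndarray
    infected: np.ndarray
    removed: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.susceptible + self.infected + self.removed

    @property
    def ever_infected(self) -> np.ndarray:
        """Cumulative outbreak size per step (infected + removed)."""
        return self.infected + self.removed

    @property
    def final_size(self) -> float:
        return float(self.ever_infected[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "S": self.susceptible, "I": self.infected, "R": self.removed}
        )


# ---------------------------------------------------------------------------
# internal engine on dense integer indices


class _Indexed:
    """Graph compiled to per-node neighbour index arrays for fast runs."""

    def __init__(self, graph: nx.Graph):
        self.nodes = sorted(graph.nodes, key=_label_sort_key)
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.adj = [
            np.fromiter((self.index[u] for u in graph[v]), dtype=np.int64)
            for v in self.nodes
        ]

    def __len__(self):
        return len(self.nodes)


_S, _I, _R = 0, 1, 2


def _run(
    indexed: _Indexed,
    seed_idx: Sequence[int],
    alpha: float,
    beta: float,
    max_steps: int,
    rng: np.random.Generator,
    recover: bool,
    record: bool,
):
    """One stochastic run; returns (trajectory lists or None, ever-infected count)."""
    n = len(indexed)
    state = np.zeros(n, dtype=np.int8)
    frontier = list(seed_idx)
    state[frontier] = _I
    ever = len(frontier)
    n_inf = len(frontier)
    n_rem = 0
    traj = [(n - ever, n_inf, 0)] if record else None

    adj = indexed.adj
    for _ in range(max_steps):
        if not frontier:
            break
        new: list[int] = []
        if alpha > 0.0:
            for u in frontier:
                nb = adj[u]
                if nb.size == 0:
                    continue
                hits = nb[rng.random(nb.size) < alpha]
                for w in hits:
                    if state[w] == _S:
                        state[w] = _I
                        new.append(int(w))
        if recover:
            if beta >= 1.0:
                recovered = len(frontier)
                for u in frontier:
                    state[u] = _R
                frontier = new
            else:
                keep = rng.random(len(frontier)) >= beta
                recovered = 0
                nxt = []
                for u, k in zip(frontier, keep):
                    if k:
                        nxt.append(u)
                    else:
                        state[u] = _R
                        recovered += 1
                frontier = nxt + new
            n_rem += recovered
            n_inf = n_inf - recovered + len(new)
        else:
            frontier = frontier + new
            n_inf += len(new)
            # stop once no susceptible node is adjacent to the infection
            if not new and not any(
                np.any(state[adj[u]] == _S) for u in frontier
            ):
                ever += 0
                if record:
                    traj.append((n - n_inf - n_rem, n_inf, n_rem))
                break
        ever += len(new)
        if record:
            traj.append((n - n_inf - n_rem, n_inf, n_rem))
    return traj, ever


def _as_rng(rng, seed) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is not None:
        return np.random.default_rng(rng)
    return np.random.default_rng(seed)


def _check_seeds(graph: nx.Graph, seeds: Iterable) -> list:
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed set must be non-empty")
    missing = [s for s in seeds if s not in graph]
    if missing:
        raise KeyError(f"seed node(s) not in graph: {missing!r}")
    return seeds


def _trajectory(traj: list[tuple[int, int, int]]) -> SpreadTrajectory:
    arr = np.asarray(traj, dtype=np.int64)
    return SpreadTrajectory(
        t=np.arange(arr.shape[0]),
        susceptible=arr[:, 0],
        infected=arr[:, 1],
        removed=arr[:, 2],
    )


# ---------------------------------------------------------------------------
# public simulators


def simulate_sir(
    graph: nx.Graph,
    seeds: Iterable,
    params: SpreadParams = SpreadParams(),
    rng: np.random.Generator | int | None = None,
) -> SpreadTrajectory:
    """One stochastic SIR run seeded at ``seeds``; per-step S/I/R counts."""
    seeds = _check_seeds(graph, seeds)
    indexed = _Indexed(graph)
    r = _as_rng(rng, params.seed)
    traj, _ = _run(
        indexed,
        sorted({indexed.index[s] for s in seeds}),
        params.alpha,
        params.beta,
        params.max_steps,
        r,
        recover=True,
        record=True,
    )
    return _trajectory(traj)


def simulate_si(
    graph: nx.Graph,
    seeds: Iterable,
    params: SpreadParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> SpreadTrajectory:
    """One stochastic SI run; no recovery, infection counts non-decreasing.

    When ``params`` is omitted, the benchmark infection rate
    ``(1/2)**3 = 0.125`` is used.
    """
    if params is None:
        params = SpreadParams(alpha=si_infection_rate())
    seeds = _check_seeds(graph, seeds)
    indexed = _Indexed(graph)
    r = _as_rng(rng, params.seed)
    traj, _ = _run(
        indexed,
        sorted({indexed.index[s] for s in seeds}),
        params.alpha,
        0.0,
        params.max_steps,
        r,
        recover=False,
        record=True,
    )
    return _trajectory(traj)


def meanfield_sir(
    s0: float,
    i0: float,
    r0: float,
    alpha: float,
    beta: float,
    steps: int,
) -> SpreadTrajectory:
    """Deterministic compartment iteration with unit time step.

    The three increments sum to zero at every step, so ``S + I + R`` is
    conserved exactly.  Counts are real-valued (mean-field populations).
    """
    if min(s0, i0, r0) < 0:
        raise ValueError("initial compartment counts must be non-negative")
    S = np.empty(steps + 1)
    I = np.empty(steps + 1)
    R = np.empty(steps + 1)
    S[0], I[0], R[0] = s0, i0, r0
    for t in range(steps):
        inf = alpha * S[t] * I[t]
        rec = beta * I[t]
        S[t + 1] = S[t] - inf
        I[t + 1] = I[t] + inf - rec
        R[t + 1] = R[t] + rec
    return SpreadTrajectory(
        t=np.arange(steps + 1), susceptible=S, infected=I, removed=R
    )


def spreading_power(
    graph: nx.Graph,
    v,
    model: Literal["sir", "si"] = "sir",
    params: SpreadParams = SpreadParams(),
    rng: np.random.Generator | int | None = None,
    _indexed: _Indexed | None = None,
) -> float:
    """Mean outbreak size over repeated runs seeded at the single node ``v``.

    The outbreak size of a run counts every node ever infected, seed
    included (infected + removed at termination for SIR, infected for
    SI), so an isolated node scores exactly 1.  This per-node value is
    the epidemic ground truth for rank comparison.
    """
    if v not in graph:
        raise KeyError(f"node {v!r} not in graph")
    indexed = _indexed if _indexed is not None else _Indexed(graph)
    r = _as_rng(rng, params.seed)
    i0 = [indexed.index[v]]
    recover = model == "sir"
    if model not in ("sir", "si"):
        raise ValueError(f"unknown model {model!r}")
    total = 0
    for _ in range(params.iterations):
        _, ever = _run(
            indexed,
            i0,
            params.alpha,
            params.beta if recover else 0.0,
            params.max_steps,
            r,
            recover=recover,
            record=False,
        )
        total += ever
    return total / params.iterations


def all_spreading_powers(
    graph: nx.Graph,
    model: Literal["sir", "si"] = "sir",
    params: SpreadParams = SpreadParams(),
) -> pd.Series:
    """Spreading power of every node, one independent RNG substream per node.

    Node ``i`` (in deterministic label order) uses the stream seeded by
    ``(params.seed, i)``, so the table is bit-reproducible and independent
    of evaluation order.
    """
    indexed = _Indexed(graph)
    base = params.seed if params.seed is not None else np.random.SeedSequence().entropy
    values = {}
    for i, v in enumerate(indexed.nodes):
        rng = np.random.default_rng(np.random.SeedSequence([int(base) % (2**63), i]))
        values[v] = spreading_power(graph, v, model, params, rng, _indexed=indexed)
    return pd.Series(values, name=f"{model}_spreading_power")


def topk_infection_curve(
    graph: nx.Graph,
    top_nodes: Sequence,
    params: SpreadParams = SpreadParams(),
    rng: np.random.Generator | int | None = None,
) -> pd.Series:
    """Mean cumulative outbreak curve F(t) with all ``top_nodes`` seeded at once.

    F(t) is the ever-infected count at step t under SIR, averaged over
    ``params.iterations`` runs; defaults follow the benchmark protocol
    (alpha = 0.01, beta = 1, t = 0..30, 1000 iterations).  Runs that
    terminate early are continued at their final value, so F is defined
    on the full horizon and non-decreasing.
    """
    seeds = _check_seeds(graph, top_nodes)
    indexed = _Indexed(graph)
    r = _as_rng(rng, params.seed)
    idx = sorted({indexed.index[s] for s in seeds})
    horizon = params.max_steps
    acc = np.zeros(horizon + 1)
    for _ in range(params.iterations):
        traj, _ = _run(
            indexed, idx, params.alpha, params.beta, horizon, r,
            recover=True, record=True,
        )
        ever = np.asarray([i + rr for _, i, rr in traj], dtype=float)
        if ever.size < horizon + 1:
            ever = np.concatenate(
                [ever, np.full(horizon + 1 - ever.size, ever[-1])]
            )
        acc += ever
    curve = acc / params.iterations
    return pd.Series(curve, index=pd.RangeIndex(horizon + 1, name="t"), name="F")
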