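# Methods

## Scope and model

`glinet` scores the influence of nodes in undirected, unweighted simple
graphs and benchmarks such scores against stochastic spreading ground
truth. Directed, weighted, bipartite and temporal graphs are out of
scope, as are second-order (two-hop) neighbour contributions — the
score deliberately uses only each node's immediate neighbourhood plus
a global coreness term.

The score of node `v_i` is

    I(v_i) = d(v_i) + Sum(v_i) / maxD + Ks(v_i)

with `Sum(v_i) = Σ_j d(v_j)·Jacc(v_i,v_j) + Ks(v_j)` over neighbours
`v_j`. Interpretation: coreness `Ks` captures global position but is
coarse (whole shells tie); the degree term and the similarity-weighted
neighbour sum break those ties using local structure. A neighbour
contributes more when it is itself well connected, sits deep in the
core, and shares much of its neighbourhood with the focal node.

### Definitional choices

* **Closed neighbourhoods in the Jaccard term.** `n(v) = {v} ∪ Γ(v)`.
  The union of two closed neighbourhoods of adjacent nodes always
  contains both endpoints, so the ratio is defined for every pair and
  `Jacc(v, v) = 1`; two endpoints of an isolated edge have similarity 1.
  The packaged walkthrough values (e.g. `Jacc(v1, v2) = 5/8 = 0.625`)
  require this convention.
* **The given value uses the neighbour's own degree** (`d(v_j)`, not
  `d(v_i)`): only this form reproduces the walkthrough's given-value
  table (`5 × 0.625 + 3 = 6.125`), and it is the natural reading — the
  donor's connectivity scales the donor's contribution.
* **`maxD` is the global maximum degree** of the analysed graph,
  computed once, not per component: the normalisation argument (a node
  can collect at most `maxD` neighbour contributions) is network-wide.
* **Isolated nodes.** Peeling at k = 0 forces shell 0, and every local
  term vanishes, so `I = 0`. This keeps the method total on graphs
  with degree-0 nodes, where some competing neighbourhood-ratio methods
  divide by zero.
* **Ranking ties** are broken by ascending node label (natural order:
  `v2` before `v10`), documented and stable.

## K-shell decomposition

Iterative minimum-degree peeling with a lazy min-heap keyed by current
degree (stale entries skipped on pop), O(m log n). The running shell
index is the largest degree floor encountered, which is exactly the
layer-by-layer peeling rule; the test suite checks the result against
an independent per-k maximal-subgraph membership oracle and against
the coreness property itself.

## Spreading simulators

Discrete, synchronous dynamics. Per step: every currently infectious
node attempts to infect each susceptible neighbour independently with
probability α (multiple attempts on one target in the same step infect
it once); then every node infectious *at the start of the step*
recovers with probability β. Newly infected nodes transmit from the
next step. With β = 1 each node transmits during exactly one step —
the convention assumed by the closed-form test laws (single-edge final
size `{1: 1−α, 2: α}`, star-hub mean `1 + kα`). SI uses the same
transmission rule without recovery and stops early once no
susceptible–infected edge remains. The benchmark SI infection rate is
`(1/2)^θ` with θ = 3, i.e. 0.125.

The mean-field SIR iteration (`ΔS = −αSI`, `ΔI = αSI − βI`,
`ΔR = βI`, Δt = 1) is provided as a separate deterministic operation;
its increments sum to zero, so the population total is conserved
exactly. Note the discrete iteration is only meaningful in the stable
regime (roughly `α·N ≤ 1`); outside it the forward map diverges, which
is a property of the difference scheme, not an implementation artefact.

**Spreading power** of a node is the mean count of ever-infected nodes
(seed included) over `iterations` independent runs seeded at that node
alone — the single-seed reading of the benchmark protocol. Counting
the seed makes the isolated-node and α = 0 cases exactly 1 and is
irrelevant to rank correlation.

**Defaults** mirror the benchmark protocols: α = 0.01, β = 1,
horizon 30 steps, 1000 iterations (the top-k curve protocol); the
α-sweep grid is 0.01…0.10 in steps of 0.01. `max_steps = 30` is a
measurement horizon for SI and a safety cap for SIR, which with β = 1
terminates on its own within the graph's eccentricity bound.

**Reproducibility.** Every stochastic entry point accepts an explicit
RNG or seed. Batch helpers derive one `numpy` substream per node from
`(experiment seed, node position)` and the sweep derives per-grid-point
seeds from `(experiment seed, grid position)`, so results are
bit-reproducible, independent of evaluation order, and any sub-grid
recomputes identically.

## Kendall coefficient

Tau-a: over all `n(n−1)/2` unordered pairs, `τ = 2(nc − nd)/(n(n−1))`,
where concordant/discordant require *strict* agreement/disagreement in
both sequences; pairs tied in either sequence count in neither. This
is implemented literally (a tie-heavy constant scorer scores τ = 0,
and a sequence correlated with itself scores below 1 in the presence
of ties). Library defaults elsewhere compute tau-b, which rescales for
ties; `kendall_tau_b` exposes scipy's tau-b as an optional cross-check
only. Tau-a equals tau-b on tie-free data, which the tests exploit.

## Baseline centralities

Degree (raw edge count), closeness, betweenness, eigenvector
(tolerance 1e-8), PageRank (damping 0.85, tolerance 1e-8) and K-shell,
all under their standard definitions via networkx — support code, not
the contribution. On disconnected graphs closeness is computed within
the node's component and scaled by the component's size fraction
(the Wasserman–Faust correction), a documented choice where the
benchmark protocol is silent.

## Packaged example network

The 15-node walkthrough graph is not published as an edge list; it was
reconstructed offline by constraint search over all 15-node graphs
consistent with the published per-node values. The published degrees,
shells and similarities force: `v1`'s neighbour set; a K4 3-core on
`v1..v4`; the number of common neighbours between `v1` and each
neighbour; six pendant leaves whose hosts are uniquely determined by
their published influence values; and degree-2 `v9`, `v10` (with a
pendant `v12` on `v10`). Exactly one of the six admissible completions
also reproduces the full published influence ordering; that edge list
is frozen in `glinet/data/worked_example.edgelist`. Uniqueness of the
original drawing is not asserted — any graph satisfying all printed
constraints would be equally acceptable — and the test suite asserts
the constraints, not the search.

One published influence cell is internally inconsistent: `v6` is
printed as 5.54, but every graph consistent with the degree, shell and
similarity tables yields 5.64, 5.68 or 5.85 for `v6` (its second
neighbour can only be `v5`, `v8` or `v2` respectively). The packaged
graph yields 5.637, which preserves the published ranking
(`v9` = 5.667 just above `v6`). Two further cells (`v4` = 11.1865,
`v3` = 10.1857) match the printed 11.18/10.18 under truncation rather
than rounding. Fixture comparisons therefore use tolerance 0.011 at
two printed decimals, and exact 1e-6 tolerances everywhere full
precision is published.

## What the synthetic generators do and do not emulate

Erdős–Rényi and Barabási–Albert generators (plus exact ring / star /
complete / path topologies) provide seeded test networks. BA graphs
reproduce the heavy-tailed degree distributions under which
coreness-plus-degree methods are most discriminative; they do not
emulate the clustering, community structure or isolated nodes of real
biological networks. Passing the benchmark suite on them demonstrates
correctness of the machinery and reproducibility of the protocol, not
dataset-level performance on real networks, which depends on
externally supplied edge lists.

## Problem sizes and numerical notes

The end-to-end benchmark test runs the full α-sweep on a seeded
BA(n = 200, m = 3) graph at 200 iterations per node — a desk-scale
setting chosen so the whole suite stays interactive while still
exercising every protocol path; the CLI exposes the full-scale
defaults (1000 iterations). All arithmetic is double precision; the
identities `Local = P + N` and `I = Local + Global` are exact by
construction and asserted to machine precision. Score tables iterate
neighbours in sorted-label order so sums are independent of adjacency
iteration order up to floating-point associativity.

## Known limitations

* Only first-order neighbourhood information enters the local term;
  graphs whose influential nodes are distinguished two or more hops
  out are outside the score's resolution.
* Tau-a's tie penalty makes comparisons sensitive to heavy tying in
  either ranking (e.g. coarse K-shell baselines on regular graphs).
* The stochastic simulators are synchronous discrete-time; no
  continuous-time (Gillespie) or SEIR dynamics.
* The O(n²) scoring path (pairwise similarity along edges) is intended
  for networks up to the tens of thousands of nodes, not millions.
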