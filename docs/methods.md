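# Methods

This note documents the model implemented by `pleionet`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## Boolean network model

A signed directed graph G(V, A) is simulated synchronously: the network
state at step t is a bit vector over the node order, and all nodes update
simultaneously. Each node with at least one regulator carries a nested
canalyzing function (NCF): its inputs are examined in a fixed nesting
order, the first input whose value equals its canalyzing value I_m forces
the output O_m, and if no input canalyzes, the default output
O_def = 1 − O_k applies. NCFs are a standard rule class for gene
regulation — most experimentally compiled regulatory rules fall in it —
and make the update biologically interpretable: every regulator can
unilaterally decide the target's next state when it is in its canalyzing
configuration.

Rule randomization draws each I_m uniformly from {0, 1}. Two modes govern
the canalyzed values:

* `sign_consistent` (default): O_m = I_m on activating links and
  O_m = 1 − I_m on inhibiting links, so the link sign keeps its usual
  semantics (an activator at its canalyzing value pushes the target
  toward "on"). A single activating input therefore always yields the
  identity rule, and a single inhibiting input the negation.
* `fully_random`: O_m uniform, ignoring signs. Kept because randomizing
  both I and O is the literal reading of the rule-generation recipe; the
  sign-consistent mode is the default because it preserves the
  activation/inhibition semantics the signed network encodes.

The nesting order of a node's inputs matters for an NCF; it is a seeded
random permutation of the in-neighbors, fixed at generation time. Rule
generation is a pure function of (graph, seed, mode).

**Source nodes.** Nodes with no incoming links have no defined update; the
package adopts a "hold" policy — they keep their current value forever, so
their initial state acts as a constant boundary condition. This preserves
the initial-state diversity the dynamics are known to depend on; the main
alternative (constant reset to a fixed value) would collapse much of the
state space.

## Attractors and mutations

Every synchronous trajectory enters a cycle: the attractor is the ordered
list of p distinct states entered at the transient step τ. `find_attractor`
indexes every visited state and reports the first revisit; an exhaustive
oracle (`brute_force_attractors`, feasible to 16 nodes) builds the full
2^N-state transition map and is used in tests to certify the trajectory
search from every initial state.

A mutation clamps one node to α (0 knockout, 1 over-expression) for a
finite duration: the initial state's mutated coordinate and every computed
state at step t ≤ T are forced to α; from step T+1 the native rule applies
again. Two conventions needed fixing:

* The clamp covers t = 0, i.e. the initial state itself is modified. With
  duration 0 and an initial state that already has the clamped value, the
  mutant trajectory is identical to the wild-type one (the identity limit
  holds exactly).
* The "mutant attractor" is the cycle reached after clamp release. Repeat
  detection starts at the state of step T — the first state whose outgoing
  transition follows the restored rules — so the returned cycle is always
  a genuine attractor of the unperturbed network.

The default step budget after release is 10,000; exceeding it raises an
explicit error rather than returning silently (real trajectories at the
sizes studied converge within tens of steps).

## Alignment distance, influence, and the scores

Gene v_j's behavior in an attractor is its periodic bit trace. Wild-type
and mutant traces with periods p, p′ are overlaid over c = lcm(p, p′)
positions; offsets that differ by a multiple of e = gcd(p, p′) produce the
same overlay (shifting either trace by its own period is a no-op), so the
minimum mismatch fraction is taken over the e inequivalent offsets. This
also makes the distance invariant to where each cycle was entered, so the
transients can be discarded. Distances and their averages μ(v_i, v_j) over
the initial-state sample are kept as exact `Fraction`s: the affected-set
membership test μ > 0 is exact and needs no epsilon.

The mutated gene itself is excluded from its own affected set — a clamped
gene's trace difference reflects the clamp, not propagation.

**sPS scope.** The affected sets V_k, V_o are defined from μ, which is
already an average over initial states, so "1 − |V_k∩V_o| / |V_k∪V_o|" is a
single number (the `global` scope, default). A per-state variant is offered
that compares per-initial-state affected sets and averages the ratio; the
two genuinely differ (e.g. when knockout only acts from all-on states and
over-expression only from all-off states, global sPS is 0 but per-state sPS
is 1). When V_k ∪ V_o = ∅ the score is defined as 0: a gene that influences
nothing under either mutation is not pleiotropic.

**zPS.** The affected-gene count m_d defaults to |V_k ∪ V_o| (the
mutation-agnostic count), with |V_k| or |V_o| selectable. The annotation
background uses the arithmetic mean and the sample (n−1) standard
deviation; zPS is refused when SD = 0.

## Structural metrics

Feedback loops are simple directed cycles (self-loops count, length ≥ 1);
a node's FBL count is the number of such cycles through it, enumerated via
Johnson's algorithm with a length cap (default 8 in the pipeline) or, when
uncapped, an abort budget of 10^7 cycles — cycle counts grow exponentially
in dense graphs and a silent hang is worse than an explicit error.

Centralities use the directed, unsigned graph for path-based measures:
closeness is the number of reachable nodes over the sum of shortest-path
distances to them (0 when nothing is reached; reached-only averaging keeps
the measure finite on disconnected graphs), betweenness is the
unnormalized pair-dependency sum, and stress counts the shortest paths
through a node. Eigenvector centrality is computed on the undirected
projection so the principal eigenvector is guaranteed non-negative
(Perron–Frobenius) regardless of reducibility of the directed adjacency.
Report statistics are the Pearson correlation (two-sided t test, n−2 df)
and the Welch two-sample t test; when both groups are constant with equal
means the comparison degenerates to (t = 0, p = 1), and with differing
means it raises an error carrying the exact mean difference.

## Synthetic networks and what the benchmarks show

Real curated signaling networks are not shipped; synthetic stand-ins are:

* **Barabási–Albert topologies** with m links per new node (exactly
  m·(n−m) links), each link oriented uniformly at random and inhibitory
  with probability 0.3 — scale-free degree distributions match the heavy
  tail of signaling networks, and roughly a third inhibitory links is a
  realistic mix for such pathways. The classic growth model is undirected
  and unsigned; orientation and sign assignment are the package's own
  extension.
* **Hand-built fixtures** (a regulatory hub star, a two-node negative
  feedback loop, an identity chain) with fixed rules for exact expected
  values.

The generator reproduces topology statistics, not biological rule content:
its rules are random NCFs, its initial states uniform. Passing benchmarks
therefore certify the *machinery* (attractor detection, distances, scores,
metrics) and the *direction* of structure–score relationships, not
quantitative agreement with any real network.

Default simulation conditions are 1000 random initial states and mutation
durations T = 14..20 (appropriate to networks of order 10^3 genes). The
benchmark ensemble is scaled down to keep desk-scale runtimes — 20
networks of 60 genes, 50 initial states, T = 14 — and at that scale the
degree–sPS correlation, though positive on average (mean r ≈ 0.05–0.12
across rule/sign regimes), is individually weak: its sign per network is
noisy, and ensembles of 20 do not reliably show 16 of 20 positive. At
n = 150 genes and 100 initial states the positive trend holds in ~9 of 10
networks. The feedback-loop effect (FBL members out-scoring non-members)
is more robust and usually visible at the small scale. This is a
statistical-power limitation of the scaled-down conditions, not of the
scoring machinery, which is oracle-verified exactly.

## Numerical and engineering choices

* Exact rational arithmetic for d, μ and sPS; floats only at
  serialization.
* The rule set is compiled once per network into padded numpy arrays; one
  synchronous step is a handful of vectorized operations. Pure-dynamics
  attractor lookups are memoized per network (every visited state maps to
  its attractor), which the per-gene mutation scans share.
* One master seed; child seeds are derived with purpose-tagged
  `SeedSequence`s, so e.g. rule generation and initial-state sampling do
  not share streams and adding analyses does not reshuffle existing draws.
* Gene-level parallelism (`n_workers`) distributes independent per-gene
  computations; aggregation is order-free, so worker count never changes
  output bytes.
* Isolated nodes are not representable in the edge-list format; networks
  are assumed connected enough to carry at least one link per node of
  interest.

## Known limitations

* Synchronous update only; asynchronous schemes need an update-order model
  the data does not determine.
* Random NCFs are a null model for rule content; inferred or curated rules
  can be supplied by constructing `BooleanNetwork` objects directly.
* Attractor search is exact but per-trajectory; networks beyond ~10^4
  nodes or very long limit cycles would need sampling strategies not
  implemented here.
* FBL counts with a length cap undercount long loops; uncapped counts are
  exponential in dense graphs and guarded by a budget.
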