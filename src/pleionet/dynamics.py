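"""Synchronous Boolean dynamics: state update, attractors, mutation clamps.

The state of an N-node network at step t is a bit vector indexed by node
order.  All nodes update simultaneously; each regulated node applies its
nested canalyzing cascade to the previous state, and input-free nodes hold
their value.  A trajectory from any initial state eventually enters a fixed
point or limit cycle (the attractor).

A mutation clamps one node to a value alpha (0 = knockout, 1 =
over-expression) for a finite duration: the initial state's mutated
coordinate and every computed state at step t <= T are forced to alpha,
after which the native rule is restored.  The mutant attractor is the cycle
the trajectory settles into after release — an attractor of the unperturbed
rule set, possibly different from the wild-type one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .net_model import BooleanNetwork

__all__ = [
    "MutationSpec",
    "Attractor",
    "AttractorNotFoundError",
    "sync_step",
    "find_attractor",
    "brute_force_attractors",
    "KNOCKOUT",
    "OVEREXPRESSION",
]

KNOCKOUT = "knockout"
OVEREXPRESSION = "overexpression"

#: default simulation horizon beyond the clamp window
DEFAULT_MAX_STEPS = 10_000

#: exhaustive-oracle size limit (2**N states are enumerated)
BRUTE_FORCE_MAX_NODES = 16


class AttractorNotFoundError(RuntimeError):
    """No state repeat was observed within the step budget."""


@dataclass(frozen=True)
class MutationSpec:
    """A finite-duration clamp of one node.

    ``alpha`` is the clamp value: 0 models a knockout, 1 an
    over-expression.  The clamp covers steps 0..duration inclusive.
    """

    node: str
    alpha: int
    duration: int

    def __post_init__(self) -> None:
        if self.alpha not in (0, 1):
            raise ValueError("alpha must be 0 or 1")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")

    @classmethod
    def knockout(cls, node: str, duration: int) -> "MutationSpec":
        return cls(node=node, alpha=0, duration=duration)

    @classmethod
    def overexpression(cls, node: str, duration: int) -> "MutationSpec":
        return cls(node=node, alpha=1, duration=duration)


@dataclass(frozen=True)
class Attractor:
    """One period of a synchronous attractor.

    ``states`` lists the p distinct cycle states in trajectory order
    starting at the first repeated state; ``transient`` is the step at
    which the cycle was entered; ``period`` is p.
    """

    states: tuple[tuple[int, ...], ...]
    transient: int
    period: int

    def __post_init__(self) -> None:
        if self.period != len(self.states) or self.period < 1:
            raise ValueError("period must equal the number of cycle states")

    def canonical(self) -> tuple[tuple[int, ...], ...]:
        """Cycle states rotated so the lexicographically smallest is first.

        Two attractors describe the same cycle iff their canonical forms
        are equal, regardless of where the trajectory entered the cycle.
        """
        k = min(range(self.period), key=lambda i: self.states[i])
        return self.states[k:] + self.states[:k]

    def trace(self, index: int) -> tuple[int, ...]:
        """State sequence of the node at position ``index`` over one period."""
        return tuple(s[index] for s in self.states)

    def to_dict(self) -> dict:
        """JSON-serializable report form (states as bit strings)."""
        return {
            "states": ["".join(map(str, s)) for s in self.states],
            "transient": self.transient,
            "period": self.period,
        }


# ---------------------------------------------------------------------------
# Compiled update (array form of the rule set, built once per network)
# ---------------------------------------------------------------------------

class _CompiledNetwork:
    """Padded-array representation of all NCF cascades for vectorized steps."""

    def __init__(self, net: BooleanNetwork) -> None:
        nodes = net.graph.nodes
        n = len(nodes)
        index = {v: i for i, v in enumerate(nodes)}
        kmax = max((len(r.inputs) for r in net.rules.values()), default=1)
        self.n = n
        self.inp = np.zeros((n, kmax), dtype=np.intp)
        self.canalyzing = np.zeros((n, kmax), dtype=np.uint8)
        self.canalyzed = np.zeros((n, kmax), dtype=np.uint8)
        self.valid = np.zeros((n, kmax), dtype=bool)
        self.default = np.zeros(n, dtype=np.uint8)
        self.has_rule = np.zeros(n, dtype=bool)
        for node, rule in net.rules.items():
            i = index[node]
            k = len(rule.inputs)
            self.has_rule[i] = True
            self.inp[i, :k] = [index[s] for s in rule.inputs]
            self.canalyzing[i, :k] = rule.canalyzing_values
            self.canalyzed[i, :k] = rule.canalyzed_values
            self.valid[i, :k] = True
            self.default[i] = rule.default_output
        self._rows = np.arange(n)

    def step(self, state: np.ndarray) -> np.ndarray:
        """One synchronous update of the whole network."""
        match = (state[self.inp] == self.canalyzing) & self.valid
        hit = match.any(axis=1)
        first = match.argmax(axis=1)
        out = np.where(hit, self.canalyzed[self._rows, first], self.default)
        # input-free nodes hold their value
        return np.where(self.has_rule, out, state).astype(np.uint8)


def _compiled(net: BooleanNetwork) -> _CompiledNetwork:
    if net._compiled is None:
        net._compiled = _CompiledNetwork(net)
    return net._compiled


def _as_state(net: BooleanNetwork, values) -> np.ndarray:
    arr = np.asarray(values, dtype=np.uint8)
    if arr.shape != (net.n_nodes,):
        raise ValueError(
            f"state length {arr.shape} does not match network size {net.n_nodes}"
        )
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("state values must be 0 or 1")
    return arr


# ---------------------------------------------------------------------------
# Public stepping / attractor search
# ---------------------------------------------------------------------------

def sync_step(
    net: BooleanNetwork,
    state,
    clamp: tuple[str, int] | None = None,
) -> tuple[int, ...]:
    """Advance the network one synchronous step.

    If ``clamp`` is given as ``(node, alpha)``, the clamped node's next
    value is ``alpha`` regardless of its rule.
    """
    arr = _as_state(net, state)
    nxt = _compiled(net).step(arr)
    if clamp is not None:
        node, alpha = clamp
        nxt[net.graph.index(node)] = alpha
    return tuple(int(b) for b in nxt)


def find_attractor(
    net: BooleanNetwork,
    v0,
    mut: MutationSpec | None = None,
    max_steps: int | None = None,
) -> Attractor:
    """Simulate from ``v0`` until a state repeats; return the cycle.

    With a mutation, ``v0`` itself has the mutated coordinate forced to
    alpha and every computed state at step t <= duration is clamped; repeat
    detection starts at the first state whose outgoing transition follows
    the restored rules, so the returned cycle is always a true attractor of
    the unperturbed network.  ``transient`` is reported as an absolute step
    number of the original trajectory.
    """
    comp = _compiled(net)
    state = _as_state(net, v0).copy()
    t = 0
    if mut is not None:
        ci = net.graph.index(mut.node)
        state[ci] = mut.alpha
        for _ in range(mut.duration):
            state = comp.step(state)
            state[ci] = mut.alpha
            t += 1
    budget = DEFAULT_MAX_STEPS if max_steps is None else int(max_steps)
    if budget < 1:
        raise ValueError("max_steps must be >= 1")
    seen: dict[bytes, int] = {state.tobytes(): t}
    trajectory = [state]
    t0 = t
    for _ in range(budget):
        state = comp.step(state)
        t += 1
        key = state.tobytes()
        if key in seen:
            tau = seen[key]
            period = t - tau
            cycle = trajectory[tau - t0 : tau - t0 + period]
            return Attractor(
                states=tuple(tuple(int(b) for b in s) for s in cycle),
                transient=tau,
                period=period,
            )
        seen[key] = t
        trajectory.append(state)
    raise AttractorNotFoundError(
        f"no attractor within {budget} steps from the clamp release"
    )


def brute_force_attractors(
    net: BooleanNetwork,
) -> tuple[list[Attractor], dict[tuple[int, ...], int]]:
    """Exhaustively enumerate attractors of a small network.

    Builds the full synchronous transition map over all 2**N states and
    extracts the cycles of the resulting functional graph.  Returns the
    attractor list and a basin map from every state to the index of its
    attractor.  Intended as an independent oracle; limited to N <= 16.
    """
    n = net.n_nodes
    if n > BRUTE_FORCE_MAX_NODES:
        raise ValueError(
            f"brute-force enumeration limited to {BRUTE_FORCE_MAX_NODES} nodes"
        )
    comp = _compiled(net)
    n_states = 1 << n
    # all states as one (2**N, N) array, stepped column-wise
    bits = (
        (np.arange(n_states)[:, None] >> np.arange(n - 1, -1, -1)) & 1
    ).astype(np.uint8)
    match = (bits[:, comp.inp] == comp.canalyzing) & comp.valid
    hit = match.any(axis=2)
    first = match.argmax(axis=2)
    out = np.where(hit, comp.canalyzed[comp._rows, first], comp.default)
    nxt_bits = np.where(comp.has_rule, out, bits).astype(np.uint8)
    weights = 1 << np.arange(n - 1, -1, -1)
    succ = nxt_bits @ weights

    attractors: list[Attractor] = []
    attractor_of = np.full(n_states, -1, dtype=np.int64)
    for start in range(n_states):
        if attractor_of[start] >= 0:
            continue
        path = []
        pos: dict[int, int] = {}
        s = start
        while attractor_of[s] < 0 and s not in pos:
            pos[s] = len(path)
            path.append(s)
            s = int(succ[s])
        if attractor_of[s] >= 0:
            aid = int(attractor_of[s])
        else:  # new cycle discovered within this path
            cycle = path[pos[s] :]
            aid = len(attractors)
            states = tuple(tuple(int(b) for b in bits[c]) for c in cycle)
            attractors.append(
                Attractor(states=states, transient=pos[s], period=len(cycle))
            )
        for visited in path:
            attractor_of[visited] = aid
    basin = {
        tuple(int(b) for b in bits[s]): int(attractor_of[s])
        for s in range(n_states)
    }
    return attractors, basin
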