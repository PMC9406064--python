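"""Signed network and Boolean-rule data structures.

A signaling network is a directed graph whose links carry an activation
(+1) or inhibition (-1) sign.  Each node with at least one regulator is
assigned a nested canalyzing function (NCF): an ordered cascade over its
inputs where the first input matching its canalyzing value I_m forces the
output O_m, and a default output O_def = 1 - O_k applies when no input
canalyzes.  Nodes without regulators hold their current value ("hold"
source policy), so their initial state acts as a constant input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "SignedDiGraph",
    "NCFRule",
    "BooleanNetwork",
    "EdgeListError",
    "parse_signed_edge_list",
    "write_signed_edge_list",
    "generate_ncf_rules",
    "generate_ba_network",
    "fixture_networks",
]

#: sign tokens accepted on input (SIF-style relation words included)
_SIGN_TOKENS = {
    "+": 1,
    "-": -1,
    "1": 1,
    "-1": -1,
    "activates": 1,
    "inhibits": -1,
}


class EdgeListError(ValueError):
    """Raised on malformed or inconsistent signed edge-list input."""


@dataclass(frozen=True)
class SignedDiGraph:
    """Directed graph with per-link activation/inhibition signs.

    Parameters
    ----------
    nodes
        Unique node identifiers in a deterministic order (first-appearance
        order when parsed from an edge list).
    links
        ``(source, target, sign)`` triples with ``sign`` in ``{+1, -1}``.
        Self-loops are permitted; duplicate ``(source, target)`` pairs are
        not.
    """

    nodes: tuple[str, ...]
    links: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise EdgeListError("duplicate node identifiers")
        seen: set[tuple[str, str]] = set()
        for src, tgt, sign in self.links:
            if sign not in (1, -1):
                raise EdgeListError(f"invalid sign {sign!r} on link {src}->{tgt}")
            if src not in node_set or tgt not in node_set:
                raise EdgeListError(f"link endpoint not declared: {src}->{tgt}")
            if (src, tgt) in seen:
                raise EdgeListError(f"duplicate link ({src}, {tgt})")
            seen.add((src, tgt))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def in_links(self, node: str) -> list[tuple[str, int]]:
        """Regulators of ``node`` as ``(source, sign)`` in link order."""
        return [(s, sign) for s, t, sign in self.links if t == node]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, t, sign in self.links:
            g.add_edge(s, t, sign=sign)
        return g


@dataclass(frozen=True)
class NCFRule:
    """Nested canalyzing update rule for one node.

    The rule is evaluated as a cascade over ``inputs`` in order: the first
    input whose current value equals its canalyzing value yields the
    corresponding canalyzed output; if no input canalyzes, ``default_output``
    applies.  By convention ``default_output == 1 - canalyzed_values[-1]``.
    """

    target: str
    inputs: tuple[str, ...]
    canalyzing_values: tuple[int, ...]
    canalyzed_values: tuple[int, ...]
    default_output: int

    def __post_init__(self) -> None:
        k = len(self.inputs)
        if k < 1:
            raise ValueError("NCF rule requires at least one input")
        if not (len(self.canalyzing_values) == len(self.canalyzed_values) == k):
            raise ValueError("canalyzing/canalyzed value lists must match input count")
        for v in (*self.canalyzing_values, *self.canalyzed_values, self.default_output):
            if v not in (0, 1):
                raise ValueError("rule values must be Boolean")
        if self.default_output != 1 - self.canalyzed_values[-1]:
            raise ValueError("default output must equal 1 - last canalyzed value")

    def evaluate(self, input_values: dict[str, int]) -> int:
        """Apply the cascade to the given regulator values."""
        for name, i_m, o_m in zip(
            self.inputs, self.canalyzing_values, self.canalyzed_values
        ):
            if input_values[name] == i_m:
                return o_m
        return self.default_output


@dataclass
class BooleanNetwork:
    """A signed graph plus one NCF rule per regulated node.

    Nodes with no incoming links have no rule; under the "hold" source
    policy they keep their current value forever.
    """

    graph: SignedDiGraph
    rules: dict[str, NCFRule]
    source_policy: str = "hold"
    # lazy caches, rebuilt on demand; excluded from equality/pickling
    _compiled: object = field(default=None, repr=False, compare=False)
    _attractor_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.source_policy != "hold":
            raise ValueError(f"unknown source policy {self.source_policy!r}")
        for node in self.graph.nodes:
            regulators = {s for s, _ in self.graph.in_links(node)}
            if regulators:
                if node not in self.rules:
                    raise ValueError(f"missing rule for regulated node {node}")
                if set(self.rules[node].inputs) != regulators:
                    raise ValueError(
                        f"rule inputs for {node} do not match its in-neighbors"
                    )
            elif node in self.rules:
                raise ValueError(f"rule given for input-free node {node}")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.graph.nodes

    @property
    def n_nodes(self) -> int:
        return self.graph.n_nodes

    def __getstate__(self):
        state = self.__dict__.copy()
        state["_compiled"] = None
        state["_attractor_cache"] = {}
        return state


# ---------------------------------------------------------------------------
# Signed edge-list I/O
# ---------------------------------------------------------------------------

def parse_signed_edge_list(text: str) -> SignedDiGraph:
    """Parse a signed edge list: one ``source sign target`` triple per line.

    Accepted sign tokens: ``+ - 1 -1 activates inhibits``.  Lines starting
    with ``#`` and blank lines are ignored.  Nodes are ordered by first
    appearance.
    """
    nodes: list[str] = []
    seen_nodes: set[str] = set()
    links: list[tuple[str, str, int]] = []
    seen_links: set[tuple[str, str]] = set()

    def add_node(name: str) -> None:
        if name not in seen_nodes:
            seen_nodes.add(name)
            nodes.append(name)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise EdgeListError(
                f"line {lineno}: expected 'source sign target', got {raw!r}"
            )
        src, sign_tok, tgt = fields
        if sign_tok not in _SIGN_TOKENS:
            raise EdgeListError(f"line {lineno}: unknown sign token {sign_tok!r}")
        if (src, tgt) in seen_links:
            raise EdgeListError(f"line {lineno}: duplicate link ({src}, {tgt})")
        seen_links.add((src, tgt))
        add_node(src)
        add_node(tgt)
        links.append((src, tgt, _SIGN_TOKENS[sign_tok]))
    return SignedDiGraph(nodes=tuple(nodes), links=tuple(links))


def write_signed_edge_list(g: SignedDiGraph) -> str:
    """Serialize a graph with canonical ``+``/``-`` sign tokens.

    ``parse_signed_edge_list(write_signed_edge_list(g))`` round-trips for
    any graph without isolated nodes; isolated nodes carry no link and are
    not representable in the edge-list format.
    """
    lines = [
        f"{src}\t{'+' if sign == 1 else '-'}\t{tgt}" for src, tgt, sign in g.links
    ]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Random rule generation
# ---------------------------------------------------------------------------

def generate_ncf_rules(
    g: SignedDiGraph, seed: int, sign_mode: str = "sign_consistent"
) -> BooleanNetwork:
    """Assign a random NCF rule to every regulated node.

    The input nesting order is a seeded random permutation of the node's
    in-neighbors.  Canalyzing values I_m are drawn uniformly from {0, 1}.
    In ``fully_random`` mode the canalyzed values O_m are drawn uniformly
    too; in ``sign_consistent`` mode O_m = I_m for activating links and
    O_m = 1 - I_m for inhibiting links, so an active activator pushes its
    target on and an active inhibitor pushes it off.  The default output is
    always 1 - O_k.  Bit-reproducible for a fixed ``(g, seed, sign_mode)``.
    """
    if sign_mode not in ("sign_consistent", "fully_random"):
        raise ValueError(f"unknown sign_mode {sign_mode!r}")
    if g.n_nodes == 0:
        raise ValueError("cannot generate rules for an empty graph")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4E43]))
    rules: dict[str, NCFRule] = {}
    for node in g.nodes:
        in_links = g.in_links(node)
        if not in_links:
            continue
        order = rng.permutation(len(in_links))
        inputs = tuple(in_links[i][0] for i in order)
        signs = tuple(in_links[i][1] for i in order)
        canalyzing = tuple(int(b) for b in rng.integers(0, 2, size=len(inputs)))
        if sign_mode == "fully_random":
            canalyzed = tuple(int(b) for b in rng.integers(0, 2, size=len(inputs)))
        else:
            canalyzed = tuple(
                i_m if s == 1 else 1 - i_m for i_m, s in zip(canalyzing, signs)
            )
        rules[node] = NCFRule(
            target=node,
            inputs=inputs,
            canalyzing_values=canalyzing,
            canalyzed_values=canalyzed,
            default_output=1 - canalyzed[-1],
        )
    return BooleanNetwork(graph=g, rules=rules)


# ---------------------------------------------------------------------------
# Synthetic networks
# ---------------------------------------------------------------------------

def generate_ba_network(
    n: int, m: int, seed: int, inhibition_prob: float = 0.3
) -> SignedDiGraph:
    """Barabási–Albert scale-free topology with random directions and signs.

    Growth with preferential attachment by total degree produces exactly
    ``m * (n - m)`` links.  Each undirected attachment is oriented uniformly
    at random and carries an inhibitory sign with probability
    ``inhibition_prob``.
    """
    if not (n > m >= 1):
        raise ValueError(f"require n > m >= 1, got n={n}, m={m}")
    if not (0.0 <= inhibition_prob <= 1.0):
        raise ValueError("inhibition_prob must lie in [0, 1]")
    base = nx.barabasi_albert_graph(n, m, seed=int(seed))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBA]))
    names = [f"v{i + 1}" for i in range(n)]
    links: list[tuple[str, str, int]] = []
    for u, v in sorted(base.edges()):
        if rng.integers(0, 2):
            u, v = v, u
        sign = -1 if rng.random() < inhibition_prob else 1
        links.append((names[u], names[v], sign))
    return SignedDiGraph(nodes=tuple(names), links=tuple(links))


def _identity_rule(target: str, source: str) -> NCFRule:
    return NCFRule(
        target=target,
        inputs=(source,),
        canalyzing_values=(1,),
        canalyzed_values=(1,),
        default_output=0,
    )


def fixture_networks() -> dict[str, BooleanNetwork]:
    """Small hand-built networks with fixed, fully explicit rules.

    ``fig1_star``
        A hub ``v1`` activating ``v2``..``v4`` (copy rules), the classic
        one-regulator star used to illustrate pleiotropy scoring.
    ``neg_loop_2``
        The two-node negative feedback loop: ``v1 -> v2`` activating and
        ``v2 -| v1`` inhibiting, i.e. ``v1(t+1) = NOT v2(t)`` and
        ``v2(t+1) = v1(t)``; its synchronous dynamics is one period-4
        oscillation covering the whole state space.
    ``const_chain``
        The identity chain ``v1 -> v2 -> v3``; ``v1`` is input-free and
        holds its value, so the chain copies it downstream.
    """
    star_graph = SignedDiGraph(
        nodes=("v1", "v2", "v3", "v4"),
        links=(("v1", "v2", 1), ("v1", "v3", 1), ("v1", "v4", 1)),
    )
    fig1_star = BooleanNetwork(
        graph=star_graph,
        rules={
            "v2": _identity_rule("v2", "v1"),
            "v3": NCFRule(  # v3 = NOT v1
                target="v3",
                inputs=("v1",),
                canalyzing_values=(1,),
                canalyzed_values=(0,),
                default_output=1,
            ),
            "v4": _identity_rule("v4", "v1"),
        },
    )

    loop_graph = SignedDiGraph(
        nodes=("v1", "v2"),
        links=(("v2", "v1", -1), ("v1", "v2", 1)),
    )
    neg_loop_2 = BooleanNetwork(
        graph=loop_graph,
        rules={
            "v1": NCFRule(  # v1 = NOT v2
                target="v1",
                inputs=("v2",),
                canalyzing_values=(1,),
                canalyzed_values=(0,),
                default_output=1,
            ),
            "v2": _identity_rule("v2", "v1"),
        },
    )

    chain_graph = SignedDiGraph(
        nodes=("v1", "v2", "v3"),
        links=(("v1", "v2", 1), ("v2", "v3", 1)),
    )
    const_chain = BooleanNetwork(
        graph=chain_graph,
        rules={
            "v2": _identity_rule("v2", "v1"),
            "v3": _identity_rule("v3", "v2"),
        },
    )

    return {
        "fig1_star": fig1_star,
        "neg_loop_2": neg_loop_2,
        "const_chain": const_chain,
    }
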