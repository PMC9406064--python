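"""Attractor-alignment distance and gene-gene dynamics influence.

How much does mutating gene v_i disturb gene v_j?  For each random initial
state the wild-type and mutant trajectories settle into (possibly
different) attractors; gene v_j's periodic state sequence is read off each
and the two cyclic sequences are compared over their least common period,
minimizing the mismatch fraction over the gcd many inequivalent relative
offsets.  Averaging this distance over the initial-state sample gives the
dynamics influence mu(v_i, v_j) in [0, 1].  All distances are exact
rationals so the "mu > 0" membership test needs no epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd, lcm

import numpy as np

from .dynamics import (
    KNOCKOUT,
    OVEREXPRESSION,
    Attractor,
    MutationSpec,
    _as_state,
    _compiled,
    find_attractor,
)
from .net_model import BooleanNetwork

__all__ = [
    "InfluenceMatrix",
    "alignment_distance",
    "dynamics_influence",
    "affected_set",
]


@dataclass(frozen=True)
class InfluenceMatrix:
    """Dynamics influence of one source gene under one mutation type.

    ``mu`` maps every other gene to an exact rational in [0, 1]; the
    average over ``n_initial_states`` initial states of the per-state
    alignment distances.
    """

    source: str
    mutation: str
    mu: dict[str, Fraction]
    n_initial_states: int
    duration: int

    def to_records(self) -> list[dict]:
        """Flat rows for TSV serialization (exact numerator/denominator)."""
        return [
            {
                "source": self.source,
                "mutation": self.mutation,
                "target": target,
                "mu_numerator": value.numerator,
                "mu_denominator": value.denominator,
                "mu_float": float(value),
            }
            for target, value in self.mu.items()
        ]


def alignment_distance(wild, mutant) -> Fraction:
    """Minimal cyclic mismatch fraction between two periodic gene traces.

    With periods p and p', the traces are overlaid for c = lcm(p, p')
    positions; offsets differing by a multiple of e = gcd(p, p') produce
    the same overlay, so the minimum runs over the e inequivalent offsets.
    Returns an exact ``Fraction`` (mismatch count over c).
    """
    w = tuple(wild)
    m = tuple(mutant)
    p, q = len(w), len(m)
    if p == 0 or q == 0:
        raise ValueError("traces must be non-empty")
    if p == 1 and q == 1:  # fixed points: distance is 0 or 1
        return Fraction(0 if w[0] == m[0] else 1)
    c = lcm(p, q)
    e = gcd(p, q)
    best = c + 1
    for offset in range(e):
        mismatches = sum(
            1 for l in range(c) if w[(l + offset) % p] != m[l % q]
        )
        if mismatches < best:
            best = mismatches
            if best == 0:
                break
    return Fraction(best, c)


def _mutation_spec(node: str, mutation: str, duration: int) -> MutationSpec:
    if mutation == KNOCKOUT:
        return MutationSpec.knockout(node, duration)
    if mutation == OVEREXPRESSION:
        return MutationSpec.overexpression(node, duration)
    raise ValueError(f"unknown mutation type {mutation!r}")


def _pure_attractor(net: BooleanNetwork, state: np.ndarray) -> Attractor:
    """Attractor of the unperturbed dynamics, memoized per network.

    Every state visited on the way is cached, so repeated queries across
    genes, mutation types and initial states share work.  The cache maps
    state bytes to the Attractor whose basin contains the state.
    """
    cache = net._attractor_cache
    comp = _compiled(net)
    s = state
    path: list[bytes] = []
    pos: dict[bytes, int] = {}
    trajectory: list[np.ndarray] = []
    while True:
        key = s.tobytes()
        hit = cache.get(key)
        if hit is not None:
            att = hit
            break
        if key in pos:
            start = pos[key]
            cycle = trajectory[start:]
            att = Attractor(
                states=tuple(tuple(int(b) for b in c) for c in cycle),
                transient=start,
                period=len(cycle),
            )
            break
        pos[key] = len(path)
        path.append(key)
        trajectory.append(s)
        s = comp.step(s)
    for key in path:
        cache[key] = att
    return att


def _mutant_attractor(
    net: BooleanNetwork, v0: np.ndarray, mut: MutationSpec
) -> Attractor:
    """Run the clamped phase, then resolve the released state via the cache."""
    comp = _compiled(net)
    ci = net.graph.index(mut.node)
    s = v0.copy()
    s[ci] = mut.alpha
    for _ in range(mut.duration):
        s = comp.step(s)
        s[ci] = mut.alpha
    return _pure_attractor(net, s)


def _per_state_distances(
    net: BooleanNetwork,
    vi: str,
    mutation: str,
    S,
    T: int,
) -> list[dict[str, Fraction]]:
    """Alignment distance d(v0, vi, vj) for every v0 in S and vj != vi."""
    nodes = net.graph.nodes
    i_src = net.graph.index(vi)
    mut = _mutation_spec(vi, mutation, T)
    results: list[dict[str, Fraction]] = []
    for v0 in S:
        arr = _as_state(net, v0)
        wild = _pure_attractor(net, arr)
        mutant = _mutant_attractor(net, arr, mut)
        row: dict[str, Fraction] = {}
        if wild.canonical() == mutant.canonical():
            zero = Fraction(0)
            for j, vj in enumerate(nodes):
                if j != i_src:
                    row[vj] = zero
        else:
            for j, vj in enumerate(nodes):
                if j != i_src:
                    row[vj] = alignment_distance(wild.trace(j), mutant.trace(j))
        results.append(row)
    return results


def dynamics_influence(
    net: BooleanNetwork,
    vi: str,
    mutation: str,
    S,
    T: int,
) -> InfluenceMatrix:
    """Average alignment distance of every gene to a mutation of ``vi``.

    ``mutation`` is ``"knockout"`` (clamp to 0) or ``"overexpression"``
    (clamp to 1); ``S`` is the initial-state sample and ``T`` the mutation
    duration.  The result is independent of the order of ``S``.
    """
    S = list(S)
    if not S:
        raise ValueError("at least one initial state is required")
    if vi not in net.graph.nodes:
        raise ValueError(f"unknown node {vi!r}")
    rows = _per_state_distances(net, vi, mutation, S, T)
    n = len(S)
    totals: dict[str, Fraction] = {
        vj: Fraction(0) for vj in net.graph.nodes if vj != vi
    }
    for row in rows:
        for vj, d in row.items():
            totals[vj] += d
    mu = {vj: total / n for vj, total in totals.items()}
    return InfluenceMatrix(
        source=vi, mutation=mutation, mu=mu, n_initial_states=n, duration=T
    )


def affected_set(infl: InfluenceMatrix) -> frozenset[str]:
    """Genes with strictly positive influence; never includes the source."""
    return frozenset(vj for vj, value in infl.mu.items() if value > 0)
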