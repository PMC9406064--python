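"""Structural network metrics related to pleiotropy.

Degrees, feedback-loop (simple directed cycle) involvement, and four
centrality measures computed on the unsigned topology: closeness and
betweenness/stress from directed shortest paths, eigenvector centrality
from the undirected projection's adjacency matrix (whose principal
eigenvector is non-negative by Perron-Frobenius).  Also the two report
statistics used to relate these metrics to pleiotropy scores: Pearson
correlation and a Welch two-sample comparison.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .net_model import SignedDiGraph

__all__ = [
    "StructuralProfile",
    "count_fbls",
    "fbl_counts",
    "degrees",
    "centralities",
    "structural_profiles",
    "pearson",
    "group_compare",
]

#: abort threshold for uncapped cycle enumeration
DEFAULT_CYCLE_BUDGET = 10_000_000

#: default cycle-length cap used by the profile pipeline
DEFAULT_MAX_FBL_LEN = 8


@dataclass(frozen=True)
class StructuralProfile:
    gene: str
    degree: int
    in_degree: int
    out_degree: int
    n_fbl: int
    in_fbl: bool
    closeness: float
    betweenness: float
    stress: float
    eigenvector: float


def _iter_cycles(g: SignedDiGraph, max_len: int | None, budget: int):
    """Yield simple directed cycles (as node lists), guarding the budget."""
    dg = g.to_networkx()
    gen = nx.simple_cycles(dg, length_bound=max_len)
    count = 0
    for cycle in gen:
        count += 1
        if count > budget:
            raise RuntimeError(
                f"cycle enumeration exceeded the budget of {budget}; "
                "pass a max_len cap"
            )
        yield cycle


def fbl_counts(
    g: SignedDiGraph,
    max_len: int | None = None,
    budget: int = DEFAULT_CYCLE_BUDGET,
) -> dict[str, int]:
    """Number of feedback loops through every node.

    A feedback loop is a simple directed cycle (self-loops are length-1
    loops); each cycle is counted once for every node it contains.  With
    ``max_len`` only cycles of at most that length are enumerated; without
    a cap the enumeration aborts if it exceeds ``budget`` cycles.
    """
    counts = {v: 0 for v in g.nodes}
    for cycle in _iter_cycles(g, max_len, budget):
        for node in cycle:
            counts[node] += 1
    return counts


def count_fbls(
    g: SignedDiGraph,
    node: str,
    max_len: int | None = None,
    budget: int = DEFAULT_CYCLE_BUDGET,
) -> int:
    """Feedback loops through one node; see :func:`fbl_counts`."""
    if node not in g.nodes:
        raise ValueError(f"unknown node {node!r}")
    return fbl_counts(g, max_len=max_len, budget=budget)[node]


def degrees(g: SignedDiGraph) -> dict[str, tuple[int, int, int]]:
    """Per-node (total, in, out) link counts; a self-loop adds 1 to each."""
    ins = {v: 0 for v in g.nodes}
    outs = {v: 0 for v in g.nodes}
    for src, tgt, _ in g.links:
        outs[src] += 1
        ins[tgt] += 1
    return {v: (ins[v] + outs[v], ins[v], outs[v]) for v in g.nodes}


def _bfs_counts(adj: list[list[int]], source: int, n: int):
    """Distances and shortest-path counts from one source (unit weights)."""
    dist = np.full(n, -1, dtype=np.int64)
    sigma = np.zeros(n, dtype=np.float64)
    dist[source] = 0
    sigma[source] = 1.0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if dist[w] < 0:
                dist[w] = dist[u] + 1
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def centralities(
    g: SignedDiGraph,
) -> dict[str, tuple[float, float, float, float]]:
    """(closeness, betweenness, stress, eigenvector) per node.

    Closeness: number of reachable nodes over the sum of directed
    shortest-path distances to them (0 for a node reaching nothing).
    Betweenness: unnormalized directed pair-dependency sum.  Stress: number
    of shortest paths over all ordered pairs passing through the node as an
    intermediate.  Eigenvector: principal eigenvector of the undirected
    projection's adjacency matrix, L2-normalized and non-negative.
    """
    n = g.n_nodes
    if n == 0:
        raise ValueError("centralities undefined on the empty graph")
    index = {v: i for i, v in enumerate(g.nodes)}
    adj: list[list[int]] = [[] for _ in range(n)]
    for src, tgt, _ in g.links:
        if src != tgt:  # self-loops do not enter shortest paths
            adj[index[src]].append(index[tgt])

    dist = np.empty((n, n), dtype=np.int64)
    sigma = np.empty((n, n), dtype=np.float64)
    for s in range(n):
        dist[s], sigma[s] = _bfs_counts(adj, s, n)

    closeness = np.zeros(n)
    for u in range(n):
        reachable = (dist[u] > 0)
        r = int(reachable.sum())
        if r:
            closeness[u] = r / float(dist[u][reachable].sum())

    betweenness = np.zeros(n)
    stress = np.zeros(n)
    for v in range(n):
        for s in range(n):
            if s == v or dist[s, v] < 0:
                continue
            through = (
                (dist[s] == dist[s, v] + dist[v])
                & (dist[v] >= 0)
                & (dist[s] >= 0)
            )
            through[s] = False
            through[v] = False
            if not through.any():
                continue
            paths_through = sigma[s, v] * sigma[v][through]
            stress[v] += paths_through.sum()
            betweenness[v] += (paths_through / sigma[s][through]).sum()

    und = np.zeros((n, n))
    for src, tgt, _ in g.links:
        und[index[src], index[tgt]] = 1.0
        und[index[tgt], index[src]] = 1.0
    eigenvalues, eigenvectors = np.linalg.eigh(und)
    principal = eigenvectors[:, -1]
    if principal.sum() < 0:
        principal = -principal
    principal = np.clip(principal, 0.0, None)
    norm = np.linalg.norm(principal)
    if norm > 0:
        principal = principal / norm

    return {
        v: (
            float(closeness[i]),
            float(betweenness[i]),
            float(stress[i]),
            float(principal[i]),
        )
        for v, i in index.items()
    }


def structural_profiles(
    g: SignedDiGraph,
    max_fbl_len: int | None = DEFAULT_MAX_FBL_LEN,
    budget: int = DEFAULT_CYCLE_BUDGET,
) -> list[StructuralProfile]:
    """Full structural profile for every node, in node order."""
    deg = degrees(g)
    fbl = fbl_counts(g, max_len=max_fbl_len, budget=budget)
    cent = centralities(g)
    profiles = []
    for v in g.nodes:
        d, di, do = deg[v]
        cl, bw, st, ev = cent[v]
        profiles.append(
            StructuralProfile(
                gene=v,
                degree=d,
                in_degree=di,
                out_degree=do,
                n_fbl=fbl[v],
                in_fbl=fbl[v] > 0,
                closeness=cl,
                betweenness=bw,
                stress=st,
                eigenvector=ev,
            )
        )
    return profiles


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def group_compare(values_a, values_b) -> tuple[float, float, float, float]:
    """Welch two-sample comparison: (mean_a, mean_b, t, two-sided p).

    When both groups are constant the t statistic is degenerate: identical
    means yield (t=0, p=1); differing means raise an error that reports the
    exact mean difference.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    mean_a = float(a.mean())
    mean_b = float(b.mean())
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if mean_a == mean_b:
            return mean_a, mean_b, 0.0, 1.0
        raise ValueError(
            "t statistic undefined for two constant groups; "
            f"exact mean difference = {mean_a - mean_b}"
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return mean_a, mean_b, float(t), float(p)
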