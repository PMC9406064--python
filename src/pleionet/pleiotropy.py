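"""Pleiotropy scores: sPS from affected-set divergence, zPS from counts.

A gene is pleiotropic in the dynamical sense when its knockout and its
over-expression disturb *different* downstream genes.  With V_k and V_o the
affected sets under the two mutation types, the in-silico pleiotropic
score is

    sPS = 1 - |V_k ∩ V_o| / |V_k ∪ V_o|

i.e. the symmetric difference over the union (0 when the two mutations hit
the same genes, 1 when they hit disjoint ones).  The z-standardized score
zPS = (md - m_wt) / SD instead measures the sheer number of affected genes
md against a phenotype-annotation background with mean m_wt and standard
deviation SD.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .dynamics import KNOCKOUT, OVEREXPRESSION
from .influence import _per_state_distances
from .net_model import BooleanNetwork

__all__ = [
    "PleiotropyResult",
    "PhenotypeAnnotation",
    "sps_from_sets",
    "compute_sps",
    "compute_zps",
    "load_phenotype_annotation",
]

GLOBAL = "global"
PER_STATE = "per_state"


@dataclass(frozen=True)
class PleiotropyResult:
    """Per-gene pleiotropy scoring outcome.

    ``vk`` / ``vo`` are the affected sets under knockout / over-expression
    built from the influence averages; ``sps`` is exact.  ``scope`` records
    whether the score compares the globally aggregated sets ("global") or
    averages per-initial-state set comparisons ("per_state").
    """

    gene: str
    sps: Fraction
    vk: frozenset[str]
    vo: frozenset[str]
    scope: str
    duration: int
    n_states: int


@dataclass(frozen=True)
class PhenotypeAnnotation:
    """Gene -> number of associated phenotypes, with background stats.

    ``m_wt`` is the arithmetic mean of the counts and ``sd`` the sample
    standard deviation (n-1 denominator), recomputed from the counts.
    """

    counts: dict[str, int]
    m_wt: float
    sd: float

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "PhenotypeAnnotation":
        if not counts:
            raise ValueError("annotation must contain at least one gene")
        series = pd.Series(list(counts.values()), dtype=float)
        sd = float(series.std(ddof=1)) if len(series) > 1 else float("nan")
        return cls(counts=dict(counts), m_wt=float(series.mean()), sd=sd)


def sps_from_sets(vk, vo) -> Fraction:
    """Symmetric difference of the two affected sets over their union.

    Equivalently ``1 - Jaccard(vk, vo)``.  Both sets empty (a gene that
    influences nothing under either mutation) scores 0.
    """
    vk = frozenset(vk)
    vo = frozenset(vo)
    union = vk | vo
    if not union:
        return Fraction(0)
    return Fraction(len(vk ^ vo), len(union))


def compute_sps(
    net: BooleanNetwork,
    vi: str,
    S,
    T: int,
    scope: str = GLOBAL,
) -> PleiotropyResult:
    """Score gene ``vi`` by simulating both mutation types over ``S``.

    Global scope (default) compares the affected sets V_k, V_o aggregated
    over all initial states; per-state scope averages the set comparison
    per initial state, so a gene whose two mutations disturb the same genes
    but under different initial conditions can still score positive.
    """
    if scope not in (GLOBAL, PER_STATE):
        raise ValueError(f"unknown scope {scope!r}")
    S = list(S)
    if not S:
        raise ValueError("at least one initial state is required")
    ko_rows = _per_state_distances(net, vi, KNOCKOUT, S, T)
    oe_rows = _per_state_distances(net, vi, OVEREXPRESSION, S, T)
    n = len(S)

    def aggregate(rows):
        totals: dict[str, Fraction] = {}
        for row in rows:
            for vj, d in row.items():
                if d:
                    totals[vj] = totals.get(vj, Fraction(0)) + d
        return frozenset(totals)

    vk = aggregate(ko_rows)
    vo = aggregate(oe_rows)
    if scope == GLOBAL:
        sps = sps_from_sets(vk, vo)
    else:
        total = sum(
            (
                sps_from_sets(
                    {vj for vj, d in ko.items() if d},
                    {vj for vj, d in oe.items() if d},
                )
                for ko, oe in zip(ko_rows, oe_rows)
            ),
            Fraction(0),
        )
        sps = total / n
    return PleiotropyResult(
        gene=vi, sps=sps, vk=vk, vo=vo, scope=scope, duration=T, n_states=n
    )


def compute_zps(md: int, annot: PhenotypeAnnotation) -> float:
    """z-standardize an affected-gene count against the annotation background."""
    if not annot.sd > 0:
        raise ValueError("zPS undefined: annotation standard deviation is not > 0")
    return (md - annot.m_wt) / annot.sd


def load_phenotype_annotation(path_or_buffer) -> PhenotypeAnnotation:
    """Read a two-column TSV ``gene<TAB>phenotype_count`` (header required)."""
    if isinstance(path_or_buffer, str) and "\t" in path_or_buffer:
        path_or_buffer = io.StringIO(path_or_buffer)
    df = pd.read_csv(path_or_buffer, sep="\t")
    if df.shape[1] != 2:
        raise ValueError(f"expected 2 columns, found {df.shape[1]}")
    if df.empty:
        raise ValueError("annotation file has no data rows")
    counts: dict[str, int] = {}
    for row_number, (gene, count) in enumerate(
        zip(df.iloc[:, 0], df.iloc[:, 1]), start=2
    ):
        value = float(count)
        if value != int(value) or value < 0:
            raise ValueError(
                f"row {row_number}: phenotype count must be a non-negative "
                f"integer, got {count!r}"
            )
        counts[str(gene)] = int(value)
    return PhenotypeAnnotation.from_counts(counts)
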