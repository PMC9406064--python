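"""End-to-end scoring pipeline: config, seeded runs, TSV/JSON reports.

Joins the simulator, the influence/pleiotropy scoring and the structural
metrics into reproducible command-level operations.  One master seed
drives every random draw (rule generation, initial states, synthetic
topologies) through purpose-tagged child seeds, so a fixed configuration
yields byte-identical outputs regardless of worker count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .net_model import (
    BooleanNetwork,
    generate_ba_network,
    generate_ncf_rules,
    parse_signed_edge_list,
    write_signed_edge_list,
)
from .pleiotropy import (
    GLOBAL,
    PhenotypeAnnotation,
    compute_sps,
    compute_zps,
    load_phenotype_annotation,
)
from .structure import (
    DEFAULT_MAX_FBL_LEN,
    degrees,
    fbl_counts,
    group_compare,
    pearson,
    structural_profiles,
)

__all__ = [
    "RunConfig",
    "random_initial_states",
    "score_table",
    "cmd_score",
    "cmd_structure",
    "cmd_randnet",
    "cmd_report",
    "ba_ensemble_trend",
]

logger = logging.getLogger("pleionet")

# purpose tags for child-seed derivation
_SEED_STATES = 0x5354
_SEED_RULES = 0x4E43
_SEED_ENSEMBLE = 0xEB5

#: structural metrics correlated against sPS in reports
REPORT_METRICS = (
    "degree",
    "in_degree",
    "out_degree",
    "n_fbl",
    "closeness",
    "betweenness",
    "stress",
    "eigenvector",
)


@dataclass
class RunConfig:
    """Configuration of one scoring run.

    Defaults follow the study conditions: 1000 random initial states and
    mutation durations 14..20 (chosen for networks of around 10^3 genes).
    """

    network_path: str
    annotation_path: str | None = None
    n_initial_states: int = 1000
    durations: tuple[int, ...] = (14, 15, 16, 17, 18, 19, 20)
    seed: int = 0
    scope: str = GLOBAL
    sign_mode: str = "sign_consistent"
    md_variant: str = "union"
    output_dir: str = "pleionet_out"
    n_workers: int = 1

    def __post_init__(self) -> None:
        self.durations = tuple(int(t) for t in self.durations)
        if self.n_initial_states < 1:
            raise ValueError("n_initial_states must be >= 1")
        if not self.durations or any(t < 0 for t in self.durations):
            raise ValueError("durations must be non-empty and non-negative")
        if self.md_variant not in ("union", "knockout", "overexpression"):
            raise ValueError(f"unknown md_variant {self.md_variant!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["durations"] = list(self.durations)
        return d


def random_initial_states(n_nodes: int, n_states: int, seed: int) -> np.ndarray:
    """Seeded uniform random initial states as an (n_states, n_nodes) array."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _SEED_STATES]))
    return rng.integers(0, 2, size=(n_states, n_nodes), dtype=np.uint8)


def _score_one_gene(net: BooleanNetwork, vi: str, S, T: int, scope: str):
    return compute_sps(net, vi, S, T, scope=scope)


def score_table(
    net: BooleanNetwork,
    S,
    T: int,
    scope: str = GLOBAL,
    annotation: PhenotypeAnnotation | None = None,
    md_variant: str = "union",
    seed: int | None = None,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Per-gene pleiotropy scores for one mutation duration.

    Genes are processed independently (optionally in parallel); the
    aggregation is order-free, so the table is identical for any worker
    count.
    """
    genes = list(net.graph.nodes)
    if n_workers > 1:
        results = Parallel(n_jobs=n_workers)(
            delayed(_score_one_gene)(net, vi, S, T, scope) for vi in genes
        )
    else:
        results = [_score_one_gene(net, vi, S, T, scope) for vi in genes]
    rows = []
    for res in results:
        row = {
            "gene": res.gene,
            "sps": float(res.sps),
            "n_knockout_affected": len(res.vk),
            "n_overexpression_affected": len(res.vo),
            "n_intersection": len(res.vk & res.vo),
            "n_union": len(res.vk | res.vo),
        }
        if annotation is not None:
            md = {
                "union": len(res.vk | res.vo),
                "knockout": len(res.vk),
                "overexpression": len(res.vo),
            }[md_variant]
            row["zps"] = compute_zps(md, annotation)
        row.update(
            scope=res.scope,
            duration=T,
            n_states=res.n_states,
            seed=seed if seed is not None else "",
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _load_network(config: RunConfig) -> BooleanNetwork:
    text = Path(config.network_path).read_text()
    graph = parse_signed_edge_list(text)
    return generate_ncf_rules(graph, seed=config.seed, sign_mode=config.sign_mode)


def cmd_score(config: RunConfig) -> dict:
    """Score every gene for every configured duration; write TSVs + manifest.

    Returns the manifest dictionary.  Outputs: ``scores_T<T>.tsv`` per
    duration and ``manifest.json`` in the output directory.
    """
    net = _load_network(config)
    annotation = (
        load_phenotype_annotation(config.annotation_path)
        if config.annotation_path
        else None
    )
    S = random_initial_states(net.n_nodes, config.n_initial_states, config.seed)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for T in config.durations:
        logger.info("scoring %d genes at duration T=%d", net.n_nodes, T)
        table = score_table(
            net,
            S,
            T,
            scope=config.scope,
            annotation=annotation,
            md_variant=config.md_variant,
            seed=config.seed,
            n_workers=config.n_workers,
        )
        path = out_dir / f"scores_T{T}.tsv"
        table.to_csv(path, sep="\t", index=False)
        outputs.append(path.name)
    config_dict = config.to_dict()
    manifest = {
        "tool": "pleionet",
        "version": __version__,
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": outputs,
        "notes": {
            "closeness": "reached-only averaging on the directed graph",
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def cmd_structure(
    network_path: str,
    out_path: str | None = None,
    max_len: int | None = DEFAULT_MAX_FBL_LEN,
) -> pd.DataFrame:
    """Structural profile table for every gene of a network file."""
    graph = parse_signed_edge_list(Path(network_path).read_text())
    if graph.n_nodes == 0:
        raise ValueError("network is empty")
    profiles = structural_profiles(graph, max_fbl_len=max_len)
    df = pd.DataFrame([dataclasses.asdict(p) for p in profiles])
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def cmd_randnet(
    n: int,
    m: int,
    seed: int,
    inhibition_prob: float,
    out_path: str,
) -> None:
    """Generate a signed scale-free network and write it as an edge list."""
    graph = generate_ba_network(n, m, seed=seed, inhibition_prob=inhibition_prob)
    Path(out_path).write_text(write_signed_edge_list(graph) + "\n")


def cmd_report(
    score_tsv: str,
    structure_tsv: str,
    out_path: str | None = None,
) -> tuple[pd.DataFrame, str]:
    """Relate pleiotropy scores to structural metrics.

    Per duration: Pearson r of sPS against each structural metric, a
    comparison of sPS between FBL-member and non-member genes, and a
    comparison of degree between zero- and non-zero-sPS genes.  Metrics
    whose correlation is undefined (constant columns) are reported with an
    error note; the rest still appear.
    """
    scores = pd.read_csv(score_tsv, sep="\t")
    struct = pd.read_csv(structure_tsv, sep="\t")
    joined = scores.merge(struct, on="gene", how="inner")
    if joined.empty:
        raise ValueError("no shared genes between the score and structure tables")
    rows = []
    lines = []
    for T, sub in joined.groupby("duration"):
        for metric in REPORT_METRICS:
            record = {"duration": T, "analysis": "pearson", "metric": metric}
            try:
                r, p = pearson(sub["sps"], sub[metric])
                record.update(r=r, p_value=p, note="")
            except ValueError as exc:
                record.update(r=float("nan"), p_value=float("nan"), note=str(exc))
            rows.append(record)
        if "in_fbl" in sub:
            fbl_mask = sub["in_fbl"].astype(bool)
            record = {"duration": T, "analysis": "sps_fbl_vs_nofbl",
                      "metric": "sps"}
            try:
                ma, mb, t, p = group_compare(
                    sub.loc[fbl_mask, "sps"], sub.loc[~fbl_mask, "sps"]
                )
                record.update(
                    mean_group=ma, mean_rest=mb, t=t, p_value=p, note=""
                )
            except ValueError as exc:
                record.update(note=str(exc))
            rows.append(record)
        record = {"duration": T, "analysis": "degree_nonzero_vs_zero_sps",
                  "metric": "degree"}
        nonzero = sub["sps"] > 0
        try:
            ma, mb, t, p = group_compare(
                sub.loc[nonzero, "degree"], sub.loc[~nonzero, "degree"]
            )
            record.update(mean_group=ma, mean_rest=mb, t=t, p_value=p, note="")
        except ValueError as exc:
            record.update(note=str(exc))
        rows.append(record)
        lines.append(f"T={T}: n={len(sub)} genes")
    report = pd.DataFrame(rows)
    text = "\n".join(lines)
    if out_path is not None:
        report.to_csv(out_path, sep="\t", index=False)
    return report, text


def ba_ensemble_trend(
    n_networks: int = 20,
    n: int = 60,
    m: int = 2,
    n_states: int = 50,
    T: int = 14,
    seed: int = 0,
    inhibition_prob: float = 0.3,
    sign_mode: str = "sign_consistent",
    max_fbl_len: int | None = DEFAULT_MAX_FBL_LEN,
) -> pd.DataFrame:
    """Degree/FBL vs pleiotropy trends on an ensemble of scale-free networks.

    For each seeded network: generate topology and rules, score every gene,
    and record the Pearson correlation of total degree with sPS plus the
    mean sPS of feedback-loop members vs non-members.  Returns one row per
    network.
    """
    children = np.random.SeedSequence([int(seed), _SEED_ENSEMBLE]).generate_state(
        n_networks
    )
    rows = []
    for i in range(n_networks):
        net_seed = int(children[i]) % (2**31)
        graph = generate_ba_network(n, m, seed=net_seed,
                                    inhibition_prob=inhibition_prob)
        net = generate_ncf_rules(graph, seed=net_seed, sign_mode=sign_mode)
        S = random_initial_states(n, n_states, net_seed)
        sps = np.array(
            [float(compute_sps(net, vi, S, T).sps) for vi in graph.nodes]
        )
        deg_map = degrees(graph)
        deg = np.array([deg_map[v][0] for v in graph.nodes], dtype=float)
        fbl = fbl_counts(graph, max_len=max_fbl_len)
        in_fbl = np.array([fbl[v] > 0 for v in graph.nodes])
        try:
            r, p = pearson(deg, sps)
        except ValueError:
            r, p = float("nan"), float("nan")
        mean_fbl = float(sps[in_fbl].mean()) if in_fbl.any() else float("nan")
        mean_nofbl = float(sps[~in_fbl].mean()) if (~in_fbl).any() else float("nan")
        rows.append(
            {
                "network_seed": net_seed,
                "degree_sps_r": r,
                "degree_sps_p": p,
                "mean_sps_fbl": mean_fbl,
                "mean_sps_nofbl": mean_nofbl,
                "fbl_ge_nofbl": bool(mean_fbl >= mean_nofbl)
                if not (np.isnan(mean_fbl) or np.isnan(mean_nofbl))
                else False,
            }
        )
    return pd.DataFrame(rows)
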