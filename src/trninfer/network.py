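"""Assembly of the final regulatory network: the comparative-genomics core
(rank-1 TF per cluster, operon-extended), augmented with expression-only
consensus edges for TFs the core does not cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SIGNS = {"activation", "repression", "undetermined"}


@dataclass(frozen=True)
class Edge:
    tf_id: str
    target_id: str
    provenance: str  # comparative | expression
    score: float
    cluster_id: str | None = None
    sign: str = "undetermined"

    def __post_init__(self) -> None:
        if self.provenance == "comparative" and self.cluster_id is None:
            raise ValueError("comparative edges must carry a cluster id")
        if self.sign not in SIGNS:
            raise ValueError(f"unknown sign {self.sign!r}")


@dataclass
class RegulatoryNetwork:
    edges: list[Edge] = field(default_factory=list)

    @property
    def tfs(self) -> set[str]:
        return {e.tf_id for e in self.edges}

    @property
    def targets(self) -> set[str]:
        return {e.target_id for e in self.edges}

    def interaction_set(self) -> set[tuple[str, str]]:
        return {(e.tf_id, e.target_id) for e in self.edges}


def _edge_sign(tf_id: str, target: str, conditions: list[str], matrix: pd.DataFrame) -> str:
    if tf_id not in matrix.index or target not in matrix.index or len(conditions) < 2:
        return "undetermined"
    a = matrix.loc[tf_id, conditions].to_numpy(dtype=float)
    b = matrix.loc[target, conditions].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        return "undetermined"
    r = float(np.corrcoef(a, b)[0, 1])
    if r > 0:
        return "activation"
    if r < 0:
        return "repression"
    return "undetermined"


def build_core_network(
    clusters: list,
    rankings: dict[str, list],
    extended_targets: dict[str, set[str]] | None = None,
    matrix: pd.DataFrame | None = None,
) -> RegulatoryNetwork:
    """One edge from each cluster's rank-1 TF to every cluster member and
    operon-extended gene.  Sign annotation comes from the signed TF-target
    correlation over the bicluster's conditions (metadata only).  A gene
    shared by two clusters with different rank-1 TFs keeps both edges
    (combinatorial regulation); duplicate (tf, target) pairs keep the
    higher-scoring edge."""
    best: dict[tuple[str, str], Edge] = {}
    for cl in clusters:
        ranked = rankings.get(cl.cluster_id)
        if not ranked:
            continue
        top = ranked[0]
        targets = set(cl.genes)
        if extended_targets:
            targets |= extended_targets.get(cl.cluster_id, set())
        targets.discard(top.tf_id)
        conds = sorted(cl.conditions)
        for t in sorted(targets):
            sign = _edge_sign(top.tf_id, t, conds, matrix) if matrix is not None else "undetermined"
            e = Edge(
                tf_id=top.tf_id,
                target_id=t,
                provenance="comparative",
                score=top.r_score,
                cluster_id=cl.cluster_id,
                sign=sign,
            )
            key = (e.tf_id, e.target_id)
            if key not in best or e.score > best[key].score:
                best[key] = e
    return RegulatoryNetwork(edges=sorted(best.values(), key=lambda e: (e.tf_id, e.target_id)))


def merge_networks(
    core: RegulatoryNetwork,
    expression_edges: list,
    cutoff: float | None = None,
) -> RegulatoryNetwork:
    """Merge with TF-level precedence for the comparative core: expression
    edges are added only for TFs that do not regulate anything in the core.
    ``expression_edges`` are consensus edges (already operon-extended and
    thresholded); ``cutoff`` re-filters by score if given."""
    core_tfs = core.tfs
    merged = dict.fromkeys(core.interaction_set())
    out = list(core.edges)
    for e in expression_edges:
        tf, tgt, score = e.tf_id, e.target_id, e.r_exp
        if tf in core_tfs:
            continue
        if cutoff is not None and score < cutoff:
            continue
        if (tf, tgt) in merged:
            continue
        merged[(tf, tgt)] = None
        out.append(Edge(tf_id=tf, target_id=tgt, provenance="expression", score=score))
    return RegulatoryNetwork(edges=out)


def summarize(net: RegulatoryNetwork) -> dict[str, int]:
    clusters = {e.cluster_id for e in net.edges if e.cluster_id is not None}
    return {
        "n_edges": len(net.edges),
        "n_tfs": len(net.tfs),
        "n_targets": len(net.targets),
        "n_genes": len(net.tfs | net.targets),
        "n_clusters": len(clusters),
    }


def export_network(net: RegulatoryNetwork, path: str | Path) -> None:
    """Write a TSV edge list preceded by a '#'-commented summary block."""
    s = summarize(net)
    with open(path, "w") as fh:
        for k, v in s.items():
            fh.write(f"# {k}\t{v}\n")
        fh.write("tf\ttarget\tcluster\tprovenance\tscore\tsign\n")
        for e in net.edges:
            fh.write(
                f"{e.tf_id}\t{e.target_id}\t{e.cluster_id or ''}\t"
                f"{e.provenance}\t{e.score:.6g}\t{e.sign}\n"
            )


def read_network(path: str | Path) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"tf": str, "target": str})
    edges = [
        Edge(
            tf_id=row.tf,
            target_id=row.target,
            provenance=row.provenance,
            score=float(row.score),
            cluster_id=None if pd.isna(row.cluster) or row.cluster == "" else str(row.cluster),
            sign=row.sign,
        )
        for row in df.itertuples(index=False)
    ]
    return RegulatoryNetwork(edges=edges)
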