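"""Condition overlay of a signalling pathway for one cell type.

Each pathway node is classed by where its gene is expressed — "both",
"healthy-only", "disease-only" or "absent" — and, for "both" nodes, scored
with delta = log2(disease) - log2(healthy) mean expression (disease minus
healthy, so positive delta means higher in disease). Nodes expressed in a
single condition keep a categorical class rather than an imputed delta.
An edge is present in a condition iff both endpoints are expressed there.
BEV-target flags come from the context-restricted interactomes, so a protein
can be a target in one context and not in another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vesiclink.errors import VesiclinkError
from vesiclink.expression import ExpressionContext
from vesiclink.io import FLOAT_FORMAT, PathwayDefinition, write_network

logger = logging.getLogger(__name__)

LAYER_ORDER = ["receptor", "adaptor", "kinase", "tf", "other"]


@dataclass
class ContextualPathway:
    """Pathway graph with per-node condition presence, delta and target flag."""

    cell_type: str
    nodes: pd.DataFrame  # index symbol: layer, expressed_healthy, expressed_disease,
    #                      klass, delta, bev_target
    edges: pd.DataFrame  # source, target, present_healthy, present_disease
    meta: dict = field(default_factory=dict)


def overlay(pathway: PathwayDefinition,
            ctx_healthy: ExpressionContext,
            ctx_disease: ExpressionContext,
            bev_targets: set) -> ContextualPathway:
    """Combine pathway topology with two same-cell-type expression contexts."""
    if ctx_healthy.cell_type != ctx_disease.cell_type:
        raise VesiclinkError(
            f"contexts are from different cell types: "
            f"{ctx_healthy.cell_type!r} vs {ctx_disease.cell_type!r}")

    eh, ed = ctx_healthy.expressed_genes, ctx_disease.expressed_genes
    known = set(ctx_healthy.expressed.index) | set(ctx_disease.expressed.index)
    unknown = sorted(pathway.members - known)
    if unknown:
        logger.warning("cell type %s: %d pathway members absent from both "
                       "expression tables: %s", ctx_healthy.cell_type,
                       len(unknown), ", ".join(unknown))

    rows = []
    for sym in sorted(pathway.members):
        in_h, in_d = sym in eh, sym in ed
        if in_h and in_d:
            klass = "both"
            delta = float(ctx_disease.mean_log2[sym] - ctx_healthy.mean_log2[sym])
        elif in_h:
            klass, delta = "healthy-only", np.nan
        elif in_d:
            klass, delta = "disease-only", np.nan
        else:
            klass, delta = "absent", np.nan
        rows.append({
            "symbol": sym,
            "layer": pathway.layer.get(sym, "other"),
            "expressed_healthy": in_h,
            "expressed_disease": in_d,
            "klass": klass,
            "delta": delta,
            "bev_target": sym in bev_targets,
        })
    nodes = pd.DataFrame(
        rows, columns=["symbol", "layer", "expressed_healthy",
                       "expressed_disease", "klass", "delta", "bev_target"],
    ).set_index("symbol")

    erows = [{
        "source": s, "target": t,
        "present_healthy": (s in eh) and (t in eh),
        "present_disease": (s in ed) and (t in ed),
    } for s, t, _ in pathway.edges]
    edges = (pd.DataFrame(erows,
                          columns=["source", "target", "present_healthy",
                                   "present_disease"])
               .sort_values(["source", "target"]).reset_index(drop=True))

    return ContextualPathway(
        cell_type=ctx_healthy.cell_type, nodes=nodes, edges=edges,
        meta={
            "condition_healthy": ctx_healthy.condition,
            "condition_disease": ctx_disease.condition,
            "edge_rule": "present iff both endpoints expressed in condition",
            "n_members_absent_everywhere": len(unknown),
        },
    )


def condition_specific_report(cp: ContextualPathway) -> pd.DataFrame:
    """Per-layer counts and member lists of condition-specific nodes."""
    rows = []
    for layer in LAYER_ORDER:
        sub = cp.nodes[cp.nodes["layer"] == layer]
        if sub.empty:
            continue
        h_only = sorted(sub.index[sub["klass"] == "healthy-only"])
        d_only = sorted(sub.index[sub["klass"] == "disease-only"])
        both = sorted(sub.index[sub["klass"] == "both"])
        rows.append({
            "layer": layer,
            "healthy_only_count": len(h_only),
            "disease_only_count": len(d_only),
            "both_count": len(both),
            "healthy_only": ",".join(h_only),
            "disease_only": ",".join(d_only),
        })
    return pd.DataFrame(rows, columns=["layer", "healthy_only_count",
                                       "disease_only_count", "both_count",
                                       "healthy_only", "disease_only"])


def targeted_receptors(cp: ContextualPathway) -> pd.DataFrame:
    """Receptor-layer nodes flagged as BEV targets, with per-condition presence.

    A receptor counts as a target of a condition only where it is expressed;
    non-receptor targets are excluded here (they stay in the full node table).
    """
    sub = cp.nodes[(cp.nodes["layer"] == "receptor") & cp.nodes["bev_target"]]
    rows = [{
        "receptor": sym,
        "expressed_healthy": bool(row["expressed_healthy"]),
        "expressed_disease": bool(row["expressed_disease"]),
        "target_in_healthy": bool(row["expressed_healthy"]),
        "target_in_disease": bool(row["expressed_disease"]),
    } for sym, row in sub.sort_index().iterrows()]
    return pd.DataFrame(rows, columns=["receptor", "expressed_healthy",
                                       "expressed_disease", "target_in_healthy",
                                       "target_in_disease"])


def write_overlay(cp: ContextualPathway, out_prefix) -> None:
    """Node/edge attribute TSVs + SIF, loadable by a graph viewer."""
    sif_edges = [(r.source, "ppi", r.target) for r in cp.edges.itertuples()]
    write_network(sif_edges, out_prefix, node_attrs=cp.nodes,
                  edge_attrs=cp.edges, allow_empty=True)
    condition_specific_report(cp).to_csv(
        f"{out_prefix}.condition_specific.tsv", sep="\t", index=False,
        float_format=FLOAT_FORMAT)
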