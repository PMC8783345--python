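"""Per-(cell type, condition) bipartite BEV–host interactomes and reports.

Contextualization restricts the predicted edge set to host genes expressed in
a given cell type / condition; reports cover per-bacterial-protein degrees
(with hub flags) and convergent targets (host proteins hit by several
bacterial proteins, e.g. a set of helicases all targeting one polymerase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from vesiclink.expression import ExpressionContext
from vesiclink.predict import PredictedInteraction

logger = logging.getLogger(__name__)

DEFAULT_HUB_QUANTILE = 0.9
DEFAULT_HUB_FLOOR = 100


@dataclass
class ContextInteractome:
    """Predicted edges restricted to one expression context."""

    cell_type: str
    condition: str
    edges: list  # of PredictedInteraction
    n_expressed_genes: int
    n_unmapped_hosts: int = 0
    summary_extra: dict = field(default_factory=dict)

    @property
    def n_target_proteins(self) -> int:
        return len({e.host_protein_id for e in self.edges})

    @property
    def n_bev_proteins_interacting(self) -> int:
        return len({e.bacterial_protein_id for e in self.edges})

    @property
    def target_symbols(self) -> set:
        return {e.host_protein_id for e in self.edges}


def contextualize(edges: Sequence[PredictedInteraction],
                  context: ExpressionContext,
                  id_to_symbol: Mapping[str, str] | None = None) -> ContextInteractome:
    """Keep only edges whose host gene is expressed in *context*.

    Host protein ids are mapped to gene symbols via *id_to_symbol* (identity
    by default); unmappable hosts are excluded and counted.
    """
    expressed = context.expressed_genes
    kept, unmapped = [], 0
    for edge in edges:
        if id_to_symbol is None:
            symbol = edge.host_protein_id
        else:
            symbol = id_to_symbol.get(edge.host_protein_id)
            if symbol is None:
                unmapped += 1
                continue
        if symbol in expressed:
            kept.append(edge)
    if unmapped:
        logger.warning("context (%s, %s): %d host ids had no symbol mapping",
                       context.cell_type, context.condition, unmapped)
    return ContextInteractome(
        cell_type=context.cell_type,
        condition=context.condition,
        edges=kept,
        n_expressed_genes=len(expressed),
        n_unmapped_hosts=unmapped,
    )


def degree_report(interactome: ContextInteractome,
                  hub_quantile: float = DEFAULT_HUB_QUANTILE,
                  hub_floor: int = DEFAULT_HUB_FLOOR) -> pd.DataFrame:
    """Host-degree per bacterial protein with hub flags.

    A protein is a hub when its degree reaches the *hub_quantile*-th
    percentile of bacterial degrees OR the absolute floor. Sorted by degree
    descending, ties by id.
    """
    degrees: dict[str, set] = {}
    for e in interactome.edges:
        degrees.setdefault(e.bacterial_protein_id, set()).add(e.host_protein_id)
    if not degrees:
        return pd.DataFrame(columns=["bact_id", "degree", "hub"])
    df = pd.DataFrame(
        {"bact_id": list(degrees), "degree": [len(v) for v in degrees.values()]}
    )
    threshold = float(np.quantile(df["degree"], hub_quantile))
    df["hub"] = (df["degree"] >= threshold) | (df["degree"] >= hub_floor)
    return (df.sort_values(["degree", "bact_id"], ascending=[False, True])
              .reset_index(drop=True))


def convergent_targets(interactome: ContextInteractome, min_bact: int = 2,
                       bact_class: Mapping[str, str] | None = None,
                       same_label: bool = False) -> pd.DataFrame:
    """Host proteins targeted by ≥ *min_bact* bacterial proteins.

    With *bact_class* labels and ``same_label=True``, only sets of bacterial
    proteins sharing one functional label are reported (the shared label in
    column ``shared_label``; otherwise NA).
    """
    by_host: dict[str, set] = {}
    for e in interactome.edges:
        by_host.setdefault(e.host_protein_id, set()).add(e.bacterial_protein_id)
    rows = []
    for host, bacts in by_host.items():
        shared = "NA"
        if bact_class is not None:
            labels = {bact_class.get(b) for b in bacts}
            if len(labels) == 1 and None not in labels:
                shared = labels.pop()
            elif same_label:
                continue
        if len(bacts) >= min_bact:
            rows.append({
                "host_id": host,
                "n_bact": len(bacts),
                "bact_ids": ",".join(sorted(bacts)),
                "shared_label": shared,
            })
    df = pd.DataFrame(rows, columns=["host_id", "n_bact", "bact_ids",
                                     "shared_label"])
    return (df.sort_values(["n_bact", "host_id"], ascending=[False, True])
              .reset_index(drop=True))


def summary_frame(interactomes: Iterable[ContextInteractome]) -> pd.DataFrame:
    """Per-context counts: expressed genes, target proteins, interacting BEVs."""
    rows = [{
        "cell_type": it.cell_type,
        "condition": it.condition,
        "n_expressed_genes": it.n_expressed_genes,
        "n_target_proteins": it.n_target_proteins,
        "n_bev_proteins_interacting": it.n_bev_proteins_interacting,
        "n_edges": len(it.edges),
    } for it in interactomes]
    return (pd.DataFrame(rows)
              .sort_values(["cell_type", "condition"])
              .reset_index(drop=True))


def to_sif_edges(interactome: ContextInteractome) -> list:
    """(source, relation, target) triples for io.write_network."""
    return sorted({(e.bacterial_protein_id, "dmi", e.host_protein_id)
                   for e in interactome.edges})
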