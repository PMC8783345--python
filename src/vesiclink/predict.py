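"""Domain→linear-motif interaction prediction with intrinsic-disorder gating.

A bacterial protein carrying a domain is predicted to bind a host protein
that carries a cognate linear motif — but only when the motif instance lies
in an intrinsically disordered, binding-competent region: the mean IUPred
score over the motif span must exceed 0.5 and the mean ANCHOR2 score must
exceed 0.4 (both strictly).

Motif scanning attempts the class regex at every start position, so
overlapping occurrences are all reported; ``$`` anchors to the sequence end.
Domain coordinates on the bacterial protein are metadata only — matching is
by domain presence, not geometry — and host proteins are never filtered by
cellular location.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from vesiclink.errors import VesiclinkError
from vesiclink.io import (DisorderProfile, DomainAnnotation, MotifClass,
                          ProteinRecord, FLOAT_FORMAT)

DEFAULT_IUPRED_CUTOFF = 0.5
DEFAULT_ANCHOR_CUTOFF = 0.4


@dataclass(frozen=True)
class MotifMatch:
    """One motif-class occurrence on a host protein (1-based inclusive span)."""

    host_protein_id: str
    motif_class_id: str
    start: int
    end: int
    matched_subsequence: str
    iupred_mean: float | None = None
    anchor_mean: float | None = None
    passed_disorder: bool | None = None


@dataclass(frozen=True)
class Evidence:
    domain_acc: str
    motif_class_id: str
    start: int
    end: int


@dataclass(frozen=True)
class PredictedInteraction:
    """A bacterial→host edge with its (domain, motif class, span) evidence."""

    bacterial_protein_id: str
    host_protein_id: str
    evidence: tuple  # of Evidence, sorted


def scan_motifs(host: ProteinRecord, cls: MotifClass) -> list:
    """All occurrences of *cls* on *host*, overlapping matches included.

    The pattern is attempted anchored at every start position 1..L; at each
    position the regex engine's match (greedy, leftmost alternative) is
    reported. Zero-length matches are discarded.
    """
    seq = host.sequence
    matches = []
    for pos in range(len(seq)):
        m = cls.pattern.match(seq, pos)
        if m is not None and m.end() > m.start():
            matches.append(MotifMatch(
                host_protein_id=host.id,
                motif_class_id=cls.identifier,
                start=pos + 1,
                end=m.end(),
                matched_subsequence=seq[pos:m.end()],
            ))
    return matches


_AGGREGATORS = {
    "mean": lambda v: float(np.mean(v)),
    "min": lambda v: float(np.min(v)),
}


def disorder_filter(match: MotifMatch, profile: DisorderProfile,
                    iupred_cutoff: float = DEFAULT_IUPRED_CUTOFF,
                    anchor_cutoff: float = DEFAULT_ANCHOR_CUTOFF,
                    aggregator: str = "mean") -> MotifMatch:
    """Aggregate disorder scores over the match span and set ``passed_disorder``.

    ``passed_disorder`` requires the aggregated IUPred score strictly above
    *iupred_cutoff* AND the aggregated ANCHOR2 score strictly above
    *anchor_cutoff*. Aggregator "all" demands every residue above both cutoffs.
    """
    if match.end > len(profile):
        raise VesiclinkError(
            f"match span {match.start}..{match.end} exceeds disorder profile "
            f"length {len(profile)} for {match.host_protein_id}"
        )
    iu = profile.iupred[match.start - 1:match.end]
    an = profile.anchor[match.start - 1:match.end]
    if aggregator == "all":
        iu_agg, an_agg = float(np.min(iu)), float(np.min(an))
    else:
        try:
            agg = _AGGREGATORS[aggregator]
        except KeyError:
            raise VesiclinkError(f"unknown aggregator {aggregator!r}") from None
        iu_agg, an_agg = agg(iu), agg(an)
    passed = (iu_agg > iupred_cutoff) and (an_agg > anchor_cutoff)
    return replace(match, iupred_mean=iu_agg, anchor_mean=an_agg,
                   passed_disorder=passed)


def predict_interactions(
    bact_proteins: Sequence[ProteinRecord],
    domain_annotations: Iterable[DomainAnnotation],
    host_proteins: Sequence[ProteinRecord],
    disorder_profiles: Mapping[str, DisorderProfile],
    motif_classes: Sequence[MotifClass],
    expressed_host_set: set | None = None,
    iupred_cutoff: float = DEFAULT_IUPRED_CUTOFF,
    anchor_cutoff: float = DEFAULT_ANCHOR_CUTOFF,
    aggregator: str = "mean",
    on_missing_profile: str = "error",
) -> list:
    """Predict bacterial→host edges from domain/motif complementarity.

    An edge (B, H) is emitted iff some domain D annotated on B appears in the
    interacting-domain set of a motif class E for which H carries at least one
    disorder-passing match; the evidence lists every such (D, E, span) triple.
    Host proteins are restricted to *expressed_host_set* when given.
    """
    if expressed_host_set is not None:
        host_proteins = [h for h in host_proteins if h.id in expressed_host_set]

    usable = [c for c in motif_classes if c.usable]

    missing = [h.id for h in host_proteins if h.id not in disorder_profiles]
    if missing:
        if on_missing_profile == "error":
            raise VesiclinkError(
                "missing disorder profiles for host proteins: "
                + ", ".join(sorted(missing))
            )
        host_proteins = [h for h in host_proteins if h.id in disorder_profiles]

    domains_by_protein: dict[str, set] = {}
    for ann in domain_annotations:
        domains_by_protein.setdefault(ann.protein_id, set()).add(ann.domain_acc)

    # host -> motif class -> disorder-passing spans
    passing: dict[str, dict[str, list]] = {}
    for host in host_proteins:
        profile = disorder_profiles[host.id]
        for cls in usable:
            spans = [
                (m.start, m.end)
                for m in scan_motifs(host, cls)
                if disorder_filter(m, profile, iupred_cutoff, anchor_cutoff,
                                   aggregator).passed_disorder
            ]
            if spans:
                passing.setdefault(host.id, {})[cls.identifier] = spans

    class_by_id = {c.identifier: c for c in usable}
    interactions = []
    for bact in bact_proteins:
        bdoms = domains_by_protein.get(bact.id, set())
        if not bdoms:
            continue
        for host in host_proteins:
            evidence = []
            for cls_id, spans in passing.get(host.id, {}).items():
                shared = bdoms & class_by_id[cls_id].interacting_domains
                for dom in sorted(shared):
                    evidence.extend(
                        Evidence(dom, cls_id, s, e) for s, e in spans
                    )
            if evidence:
                evidence.sort(key=lambda ev: (ev.domain_acc, ev.motif_class_id,
                                              ev.start, ev.end))
                interactions.append(PredictedInteraction(
                    bacterial_protein_id=bact.id,
                    host_protein_id=host.id,
                    evidence=tuple(evidence),
                ))
    interactions.sort(key=lambda i: (i.bacterial_protein_id, i.host_protein_id))
    return interactions


def interactions_to_frame(interactions: Iterable[PredictedInteraction],
                          disorder_profiles: Mapping[str, DisorderProfile] | None = None,
                          aggregator: str = "mean") -> pd.DataFrame:
    """Flatten predictions to one row per evidence triple (the edges TSV)."""
    rows = []
    for it in interactions:
        for ev in it.evidence:
            row = {
                "bact_id": it.bacterial_protein_id,
                "host_id": it.host_protein_id,
                "domain": ev.domain_acc,
                "motif_class": ev.motif_class_id,
                "start": ev.start,
                "end": ev.end,
            }
            if disorder_profiles is not None:
                prof = disorder_profiles[it.host_protein_id]
                agg = _AGGREGATORS["min" if aggregator == "all" else aggregator]
                row["iupred_mean"] = agg(prof.iupred[ev.start - 1:ev.end])
                row["anchor_mean"] = agg(prof.anchor[ev.start - 1:ev.end])
            rows.append(row)
    cols = ["bact_id", "host_id", "domain", "motif_class", "start", "end"]
    if disorder_profiles is not None:
        cols += ["iupred_mean", "anchor_mean"]
    return pd.DataFrame(rows, columns=cols)


def write_edges_tsv(interactions, path, disorder_profiles=None,
                    aggregator: str = "mean") -> None:
    df = interactions_to_frame(interactions, disorder_profiles, aggregator)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_edges_tsv(path) -> list:
    """Inverse of :func:`write_edges_tsv` (score columns are ignored)."""
    df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int})
    interactions = []
    if df.empty:
        return interactions
    for (bact, host), sub in df.groupby(["bact_id", "host_id"], sort=True):
        evidence = tuple(sorted(
            (Evidence(r.domain, r.motif_class, int(r.start), int(r.end))
             for r in sub.itertuples()),
            key=lambda ev: (ev.domain_acc, ev.motif_class_id, ev.start, ev.end),
        ))
        interactions.append(PredictedInteraction(bact, host, evidence))
    return interactions
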