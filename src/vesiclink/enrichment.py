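"""GO over-representation of BEV-target genes against an expressed background.

Per term with at least one annotated target, the upper-tail hypergeometric
probability P(X >= k) is computed with universe N = |background|, K background
genes annotated to the term, draw size n = |targets|, and k annotated targets.
Annotations are first propagated up the is_a hierarchy, so a gene annotated to
a term counts for every ancestor. Multiple testing is controlled per GO
namespace with Benjamini-Hochberg; a term is called enriched when p < 1e-3
AND q < 0.05 (both configurable).

Redundancy among enriched terms is reduced with Schlicker's relevance
similarity (simRel):

    sim(t1, t2) = max over common ancestors a of
                  [2 * IC(a) / (IC(t1) + IC(t2))] * (1 - p(a))

with IC(t) = -ln p(t) and p(t) the fraction of background genes annotated
(after propagation) to t. Identical terms score 1 - p(t); terms whose only
common ancestor is the root score 0. A greedy pass over terms sorted by
p-value assigns each term to the most similar existing representative
(similarity >= threshold) or opens a new cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from vesiclink.errors import VesiclinkError
from vesiclink.io import FLOAT_FORMAT, GoAnnotation, GoDag

DEFAULT_P_CUTOFF = 1e-3
DEFAULT_Q_CUTOFF = 0.05
DEFAULT_SIMREL_THRESHOLD = 0.7


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float
    enriched: bool


@dataclass(frozen=True)
class TermCluster:
    representative: str
    members: tuple  # term ids, sorted
    similarities: tuple  # simRel(member, representative) per member


def propagate_annotations(annotations: Iterable[GoAnnotation],
                          dag: GoDag) -> dict:
    """gene -> set of term ids closed under is_a ancestry (idempotent)."""
    out: dict[str, set] = {}
    skipped = 0
    for gene, term in annotations:
        if term not in dag:
            skipped += 1
            continue
        out.setdefault(gene, set()).update(dag.ancestors(term))
    if skipped:
        import logging
        logging.getLogger(__name__).warning(
            "skipped %d annotations to terms outside the DAG", skipped)
    return out


def hypergeometric_enrich(target_genes: set, background_genes: set,
                          gene_to_terms: Mapping[str, set],
                          dag: GoDag | None = None,
                          namespace: str | None = None,
                          p_cutoff: float = DEFAULT_P_CUTOFF,
                          q_cutoff: float = DEFAULT_Q_CUTOFF) -> list:
    """Hypergeometric ORA per term with k >= 1; BH per namespace.

    *target_genes* must be a subset of *background_genes* (the expressed genes
    of the context). Genes without annotations contribute to N only.
    """
    offenders = sorted(target_genes - background_genes)
    if offenders:
        raise VesiclinkError(
            "target genes missing from background: " + ", ".join(offenders))

    N, n = len(background_genes), len(target_genes)
    term_bg: dict[str, int] = {}
    term_tg: dict[str, int] = {}
    for gene in background_genes:
        for t in gene_to_terms.get(gene, ()):
            term_bg[t] = term_bg.get(t, 0) + 1
            if gene in target_genes:
                term_tg[t] = term_tg.get(t, 0) + 1

    tested = sorted(t for t in term_tg if term_tg[t] >= 1)
    if namespace is not None and dag is not None:
        tested = [t for t in tested if dag.namespace(t) == namespace]

    rows = []
    for t in tested:
        k, K = term_tg[t], term_bg[t]
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term_id": t,
            "term_name": dag.terms[t].name if dag and t in dag else "",
            "namespace": dag.namespace(t) if dag and t in dag else "",
            "k": k, "n": n, "K": K, "N": N, "p_value": min(p, 1.0),
        })
    if not rows:
        return []

    df = pd.DataFrame(rows)
    df["q_value"] = 1.0
    for _, idx in df.groupby("namespace").groups.items():
        df.loc[idx, "q_value"] = bh_adjust(df.loc[idx, "p_value"].tolist())
    df["enriched"] = (df["p_value"] < p_cutoff) & (df["q_value"] < q_cutoff)
    df = df.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    return [EnrichmentResult(**row) for row in df.to_dict("records")]


def bh_adjust(p_values: Sequence[float]) -> list:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    if len(p_values) == 0:
        return []
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise VesiclinkError(f"p-value {p} outside [0,1]")
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return list(q)


def term_probabilities(background_genes: set,
                       gene_to_terms: Mapping[str, set]) -> dict:
    """term -> fraction of background genes annotated (propagated) to it."""
    N = len(background_genes)
    if N == 0:
        raise VesiclinkError("empty background")
    counts: dict[str, int] = {}
    for gene in background_genes:
        for t in gene_to_terms.get(gene, ()):
            counts[t] = counts.get(t, 0) + 1
    return {t: c / N for t, c in counts.items()}


def simrel(t1: str, t2: str, dag: GoDag,
           term_prob: Mapping[str, float]) -> float:
    """Schlicker relevance similarity between two terms of one namespace."""
    p1, p2 = term_prob.get(t1, 0.0), term_prob.get(t2, 0.0)
    if p1 <= 0 or p2 <= 0:
        raise VesiclinkError(f"simrel needs positive probabilities for {t1}, {t2}")
    if dag.namespace(t1) != dag.namespace(t2):
        raise VesiclinkError(f"{t1} and {t2} are in different namespaces")
    ic1, ic2 = -math.log(p1), -math.log(p2)
    common = dag.ancestors(t1) & dag.ancestors(t2)
    best = 0.0
    for a in common:
        pa = term_prob.get(a, 0.0)
        if pa <= 0:
            continue
        ica = -math.log(pa)
        denom = ic1 + ic2
        score = 0.0 if denom == 0 else (2.0 * ica / denom) * (1.0 - pa)
        best = max(best, score)
    return min(best, 1.0)


def reduce_terms(results: Sequence[EnrichmentResult], dag: GoDag,
                 term_prob: Mapping[str, float],
                 threshold: float = DEFAULT_SIMREL_THRESHOLD) -> list:
    """Greedy simRel clustering of enriched terms.

    Terms are visited by ascending p (ties by term id). A term opens a new
    cluster iff its simRel to every existing representative is < threshold;
    otherwise it joins the representative with maximal simRel (ties to the
    lexicographically smallest representative id). Clusters partition the set.
    """
    enriched = sorted((r for r in results if r.enriched),
                      key=lambda r: (r.p_value, r.term_id))
    reps: list[str] = []
    members: dict[str, list] = {}
    sims: dict[str, list] = {}
    for r in enriched:
        scored = [(simrel(r.term_id, rep, dag, term_prob), rep) for rep in reps]
        eligible = [(s, rep) for s, rep in scored if s >= threshold]
        if not eligible:
            reps.append(r.term_id)
            members[r.term_id] = [r.term_id]
            sims[r.term_id] = [simrel(r.term_id, r.term_id, dag, term_prob)]
        else:
            # max similarity; ties -> lexicographically smallest rep id
            top = max(s for s, _ in eligible)
            rep = min(rep for s, rep in eligible if s == top)
            members[rep].append(r.term_id)
            sims[rep].append(top)
    return [TermCluster(representative=rep,
                        members=tuple(sorted(members[rep])),
                        similarities=tuple(sims[rep]))
            for rep in reps]


def venn_partition(named_sets: Mapping[str, set]) -> dict:
    """Partition the union of 2-6 named sets by exact membership signature.

    Returns {signature: (count, sorted members)} where the signature is the
    '&'-joined names (input order) of the sets containing the element.
    """
    names = list(named_sets)
    if not (2 <= len(names) <= 6):
        raise VesiclinkError("venn_partition needs between 2 and 6 sets")
    union = set().union(*named_sets.values())
    parts: dict[str, list] = {}
    for el in union:
        sig = "&".join(nm for nm in names if el in named_sets[nm])
        parts.setdefault(sig, []).append(el)
    return {sig: (len(v), sorted(v)) for sig, v in sorted(parts.items())}


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    cols = ["term_id", "term_name", "namespace", "k", "n", "K", "N",
            "p_value", "q_value", "enriched"]
    return pd.DataFrame([r.__dict__ for r in results], columns=cols)


def write_enrichment_tsv(results, path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False,
                                     float_format=FLOAT_FORMAT)


def write_clusters_tsv(clusters: Sequence[TermCluster], path) -> None:
    rows = [{"representative": c.representative,
             "n_members": len(c.members),
             "members": ",".join(c.members)} for c in clusters]
    pd.DataFrame(rows, columns=["representative", "n_members", "members"]) \
        .to_csv(path, sep="\t", index=False)


def write_venn_tsv(partition: Mapping, path) -> None:
    rows = [{"signature": sig, "count": count, "members": ",".join(members)}
            for sig, (count, members) in partition.items()]
    pd.DataFrame(rows, columns=["signature", "count", "members"]) \
        .to_csv(path, sep="\t", index=False)
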