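"""Synthetic pipeline inputs with planted ground truth.

Every external input the pipeline consumes can be generated here with a known
answer key: motif instances planted inside disordered spans (scores a margin
above the cutoffs) and decoys inside ordered spans (a margin below), negative
binomial single-cell counts with planted off / barely-expressed / condition-
specific genes, a random GO DAG with one term wired to be enriched, and a
layered receptor→adaptor→kinase→TF pathway.

Two deliberate choices:

* The interaction truth table is *finalized by a brute-force oracle* run on
  the generated sequences, not by the planting intent — random background
  residues can form incidental motif matches, and those belong in the truth.
* Disorder scores are drawn directly (uniform above/below the cutoffs by a
  margin) rather than produced by a disorder predictor; the pipeline consumes
  scores, so predictor fidelity is irrelevant.

Everything is deterministic under a seed; regenerated fixture trees are
byte-identical.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vesiclink.errors import VesiclinkError
from vesiclink.io import (DisorderProfile, DomainAnnotation, GoAnnotation,
                          GoDag, GoTerm, MotifClass, PathwayDefinition,
                          ProteinRecord, write_disorder_profile,
                          write_expression, write_fasta, write_gaf, write_obo)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_MOTIF_CLASSES = (
    MotifClass("LIG_PDZ_1", "[ST].[ACVILF]$", frozenset({"PF00595"}),
               "C-terminal PDZ-binding motif"),
    MotifClass("LIG_SH3_lite", "P..P[AL]", frozenset({"PF00018"}),
               "proline-rich SH3-binding motif"),
    MotifClass("DOC_KIN_1", "K[RK].LL", frozenset({"PF00069"}),
               "kinase docking motif"),
    MotifClass("LIG_WW_1", "PP.Y", frozenset({"PF00397"}),
               "WW-domain binding motif"),
    MotifClass("UNPAIRED_W", "W..W", frozenset(),
               "class with no interacting domain (unusable)"),
)


# ---------------------------------------------------------------------------
# regex witnesses
# ---------------------------------------------------------------------------

class UnrealizableRegexError(VesiclinkError):
    pass


def witness(regex: str, class_name: str = "?") -> tuple:
    """A concrete string matching *regex*, plus whether it is end-anchored.

    Supports the ELM-like subset: literal residues, ``.``, ``[...]`` (with
    ``^`` negation), fixed ``{m}`` / ``{m,n}`` repeats, and a trailing ``$``.
    Anything else raises :class:`UnrealizableRegexError` naming the class.
    """
    out: list[str] = []
    i, n = 0, len(regex)
    end_anchored = False
    while i < n:
        c = regex[i]
        if c == "$":
            if i != n - 1:
                raise UnrealizableRegexError(
                    f"class {class_name}: '$' not at pattern end")
            end_anchored = True
            i += 1
        elif c == ".":
            out.append("A")
            i += 1
        elif c == "[":
            j = regex.find("]", i)
            if j < 0:
                raise UnrealizableRegexError(
                    f"class {class_name}: unterminated character class")
            inner = regex[i + 1:j]
            if inner.startswith("^"):
                banned = set(inner[1:])
                pick = next((a for a in ALPHABET if a not in banned), None)
            else:
                pick = next((a for a in ALPHABET if a in set(inner)), None)
            if pick is None:
                raise UnrealizableRegexError(
                    f"class {class_name}: empty character class {inner!r}")
            out.append(pick)
            i = j + 1
        elif c == "{":
            j = regex.find("}", i)
            if j < 0 or not out:
                raise UnrealizableRegexError(
                    f"class {class_name}: bad repeat in {regex!r}")
            m = regex[i + 1:j].split(",")[0]
            if not m.isdigit():
                raise UnrealizableRegexError(
                    f"class {class_name}: unsupported repeat {regex[i:j+1]!r}")
            out.append(out[-1] * (int(m) - 1))
            i = j + 1
        elif c in ALPHABET or c == "X":
            out.append(c)
            i += 1
        else:
            raise UnrealizableRegexError(
                f"class {class_name}: unsupported regex construct {c!r}")
    w = "".join(out)
    if not w or not re.compile(regex).match(w) or (
            end_anchored and re.compile(regex).match(w).end() != len(w)):
        raise UnrealizableRegexError(
            f"class {class_name}: could not realize {regex!r}")
    return w, end_anchored


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def oracle_predict(bact_proteins, domain_annotations, host_proteins,
                   profiles, motif_classes, iupred_cutoff=0.5,
                   anchor_cutoff=0.4) -> set:
    """Naive triple loop over (bacterial protein x motif class x host).

    Deliberately written without any helper from :mod:`vesiclink.predict`:
    per-position regex attempts, plain-Python mean aggregation, strict
    cutoffs. Returns (bact, host, class, domain, start, end) tuples.
    """
    found = set()
    for b in bact_proteins:
        for cls in motif_classes:
            if not cls.interacting_domains:
                continue
            pat = re.compile(cls.regex)
            for d in domain_annotations:
                if d.protein_id != b.id or d.domain_acc not in cls.interacting_domains:
                    continue
                for h in host_proteins:
                    prof = profiles[h.id]
                    for pos in range(len(h.sequence)):
                        m = pat.match(h.sequence, pos)
                        if m is None or m.end() == pos:
                            continue
                        span_iu = prof.iupred[pos:m.end()]
                        span_an = prof.anchor[pos:m.end()]
                        iu = sum(span_iu) / len(span_iu)
                        an = sum(span_an) / len(span_an)
                        if iu > iupred_cutoff and an > anchor_cutoff:
                            found.add((b.id, h.id, cls.identifier,
                                       d.domain_acc, pos + 1, m.end()))
    return found


# ---------------------------------------------------------------------------
# proteomes + disorder
# ---------------------------------------------------------------------------

@dataclass
class SimProteomes:
    bact: list
    domains: list
    hosts: list
    profiles: dict
    motif_classes: list
    planted_sites: list      # (host_id, class_id, start, end)
    decoy_sites: list
    truth_matches: set       # oracle-finalized (b, h, cls, dom, start, end)

    @property
    def truth_edges(self) -> set:
        return {(b, h) for b, h, *_ in self.truth_matches}


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def gen_proteomes(n_bact: int = 6, n_host: int = 12,
                  motif_classes=DEFAULT_MOTIF_CLASSES,
                  n_planted: int = 5, n_decoys: int = 3,
                  margin: float = 0.1,
                  iupred_cutoff: float = 0.5, anchor_cutoff: float = 0.4,
                  seed: int = 0, host_ids=None,
                  priority_hosts=()) -> SimProteomes:
    """Generate both proteomes, domain annotations and disorder profiles.

    Planted sites get span scores ~ U(cutoff+margin, 1); decoy sites (motif
    present, disorder absent) stay on the ordered background
    ~ U(0, cutoff-margin). *priority_hosts* are planted first, so a named
    host (e.g. a TLR4-like receptor) is guaranteed a disorder-passing motif.
    """
    if margin <= 0:
        raise VesiclinkError("margin must be positive")
    rng = np.random.default_rng(seed)
    usable = [c for c in motif_classes if c.interacting_domains]
    witnesses = {c.identifier: witness(c.regex, c.identifier) for c in usable}

    if host_ids is None:
        host_ids = [f"HGENE{i:03d}" for i in range(1, n_host + 1)]
    if len(host_ids) != n_host:
        raise VesiclinkError("host_ids length must equal n_host")

    lengths = rng.integers(80, 161, size=n_host)
    seqs = {hid: list(_random_seq(rng, L)) for hid, L in zip(host_ids, lengths)}
    iu = {hid: rng.uniform(0.0, iupred_cutoff - margin, size=len(seqs[hid]))
          for hid in host_ids}
    an = {hid: rng.uniform(0.0, anchor_cutoff - margin, size=len(seqs[hid]))
          for hid in host_ids}

    host_order = list(priority_hosts) + [h for h in host_ids
                                         if h not in priority_hosts]
    cursor = {hid: 5 for hid in host_ids}
    end_used = {hid: False for hid in host_ids}
    class_cycle = itertools.cycle(usable)

    def _place(site_idx: int, disordered: bool):
        cls = next(class_cycle)
        w, end_anchored = witnesses[cls.identifier]
        for attempt in range(len(host_order)):
            hid = host_order[(site_idx + attempt) % len(host_order)]
            L = len(seqs[hid])
            if end_anchored:
                if end_used[hid]:
                    continue
                start0 = L - len(w)
                end_used[hid] = True
            else:
                start0 = cursor[hid]
                if start0 + len(w) > L - len(w) - 5:  # keep the tail free
                    continue
                cursor[hid] = start0 + len(w) + 8
            seqs[hid][start0:start0 + len(w)] = list(w)
            span = slice(start0, start0 + len(w))
            if disordered:
                iu[hid][span] = rng.uniform(iupred_cutoff + margin, 1.0,
                                            size=len(w))
                an[hid][span] = rng.uniform(anchor_cutoff + margin, 1.0,
                                            size=len(w))
            return (hid, cls.identifier, start0 + 1, start0 + len(w))
        raise VesiclinkError("could not place a motif site; enlarge hosts")

    planted = [_place(i, disordered=True) for i in range(n_planted)]
    decoys = [_place(n_planted + i, disordered=False) for i in range(n_decoys)]

    hosts = [ProteinRecord(hid, "".join(seqs[hid])) for hid in host_ids]
    profiles = {
        hid: DisorderProfile(hid, tuple(np.round(iu[hid], 4)),
                             tuple(np.round(an[hid], 4)))
        for hid in host_ids
    }

    bact, domains = [], []
    domain_pool = sorted({d for c in usable for d in c.interacting_domains})
    for i in range(n_bact):
        bid = f"BEV{i + 1:03d}"
        L = int(rng.integers(150, 301))
        bact.append(ProteinRecord(bid, _random_seq(rng, L)))
        if i == n_bact - 1:
            accs = ["PF99999"]  # no motif class references it: zero edges
        else:
            k = int(rng.integers(1, 3))
            accs = [domain_pool[(i + j) % len(domain_pool)] for j in range(k)]
        for acc in accs:
            start = int(rng.integers(1, max(2, L - 60)))
            domains.append(DomainAnnotation(bid, acc, start,
                                            min(L, start + 50), "synthetic"))

    truth = oracle_predict(bact, domains, hosts, profiles, list(motif_classes),
                           iupred_cutoff, anchor_cutoff)
    return SimProteomes(bact=bact, domains=domains, hosts=hosts,
                        profiles=profiles, motif_classes=list(motif_classes),
                        planted_sites=planted, decoy_sites=decoys,
                        truth_matches=truth)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class SimExpression:
    values: pd.DataFrame   # counts, genes x cells
    labels: pd.DataFrame   # index cell_id: cell_type, condition
    truth_expressed: dict  # (cell_type, condition) -> set of genes
    truth_off: dict
    truth_low: dict


def gen_expression(cell_types, conditions, n_genes: int = 120,
                   n_cells_per_group: int = 30, off_fraction: float = 0.1,
                   low_fraction: float = 0.05, lowexpr_log2_gap: float = 14.0,
                   nb_dispersion: float = 0.1, seed: int = 0,
                   gene_names=None, condition_specific=None,
                   constant_across_conditions=(),
                   protected_genes=()) -> SimExpression:
    """Negative-binomial counts with planted expressed/off/low structure.

    Per (cell type, condition) group: an *off* set has mean exactly 0, a *low*
    set has a true mean ``lowexpr_log2_gap`` log2 units below the expressed
    genes (far outside 3 population SDs, so the z rule must reject it), and
    genes listed in *condition_specific* (gene -> set of groups where ON) are
    off elsewhere. *constant_across_conditions* genes (e.g. transcription
    factors) reuse one draw per cell type in every condition, making their
    disease-healthy delta exactly zero. *protected_genes* are never chosen
    for the off/low sets.
    """
    if n_genes < 50:
        raise VesiclinkError("n_genes must be >= 50")
    rng = np.random.default_rng(seed)
    if gene_names is None:
        gene_names = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    if len(gene_names) != n_genes:
        raise VesiclinkError("gene_names length must equal n_genes")
    condition_specific = condition_specific or {}
    constant = set(constant_across_conditions)
    protected = (set(protected_genes) | set(condition_specific) | constant)

    base_log2_mean = pd.Series(rng.uniform(6.0, 9.0, size=n_genes),
                               index=gene_names)
    r = 1.0 / nb_dispersion  # NB size parameter

    def _draw(mean_vec: np.ndarray, size: int) -> np.ndarray:
        out = np.zeros((len(mean_vec), size), dtype=int)
        pos = mean_vec > 0
        if pos.any():
            m = mean_vec[pos][:, None]
            p = r / (r + m)
            out[pos] = rng.negative_binomial(r, p, size=(int(pos.sum()), size))
        return out

    eligible = [g for g in gene_names if g not in protected]
    n_off = int(round(off_fraction * n_genes))
    n_low = int(round(low_fraction * n_genes))

    blocks, label_rows = [], []
    truth_expressed, truth_off, truth_low = {}, {}, {}
    constant_draws: dict[tuple, np.ndarray] = {}

    groups = [(ct, cond) for ct in cell_types for cond in conditions]
    for ct, cond in groups:
        off = set(rng.choice(eligible, size=n_off, replace=False))
        low_pool = [g for g in eligible if g not in off]
        low = set(rng.choice(low_pool, size=n_low, replace=False))
        for g, on_groups in condition_specific.items():
            if (ct, cond) not in on_groups:
                off.add(g)

        mean_vec = np.power(2.0, base_log2_mean.to_numpy()).copy()
        gidx = {g: i for i, g in enumerate(gene_names)}
        for g in off:
            mean_vec[gidx[g]] = 0.0
        low_mean = 2.0 ** (float(base_log2_mean.mean()) - lowexpr_log2_gap)
        for g in low:
            mean_vec[gidx[g]] = low_mean

        counts = _draw(mean_vec, n_cells_per_group)
        for g in sorted(constant):
            key = (ct, g)
            if key not in constant_draws:
                constant_draws[key] = counts[gidx[g]].copy()
            counts[gidx[g]] = constant_draws[key]

        cells = [f"{ct}.{cond}.c{i:03d}" for i in range(n_cells_per_group)]
        blocks.append(pd.DataFrame(counts, index=gene_names, columns=cells))
        label_rows.extend({"cell_id": c, "cell_type": ct, "condition": cond}
                          for c in cells)
        truth_expressed[(ct, cond)] = {g for g in gene_names
                                       if g not in off and g not in low}
        truth_off[(ct, cond)] = off
        truth_low[(ct, cond)] = low

    values = pd.concat(blocks, axis=1)
    labels = pd.DataFrame(label_rows).set_index("cell_id")
    return SimExpression(values=values, labels=labels,
                         truth_expressed=truth_expressed,
                         truth_off=truth_off, truth_low=truth_low)


# ---------------------------------------------------------------------------
# GO
# ---------------------------------------------------------------------------

@dataclass
class SimGo:
    dag: GoDag
    annotations: list
    planted_term: str
    planted_genes: set


def gen_go(genes, n_terms: int = 40, depth: int = 3,
           planted_block: int = 25, seed: int = 0,
           namespace: str = "biological_process") -> SimGo:
    """Random is_a tree of bounded depth with one deliberately enriched term.

    The planted term (a deepest term) annotates a random block of
    *planted_block* genes; drawing a target set preferentially from that
    block makes the term recoverable by over-representation analysis.
    """
    rng = np.random.default_rng(seed)
    ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    root = ids[0]
    depths = {root: 0}
    terms = {root: GoTerm(root, "synthetic root", namespace, frozenset())}
    for tid in ids[1:]:
        candidates = [t for t in terms if depths[t] < depth]
        parent = str(rng.choice(sorted(candidates)))
        depths[tid] = depths[parent] + 1
        terms[tid] = GoTerm(tid, f"synthetic process {tid[-4:]}", namespace,
                            frozenset({parent}))
    dag = GoDag(terms)

    genes = list(genes)
    deepest = max(depths.values())
    planted_term = sorted(t for t, d in depths.items() if d == deepest)[0]
    planted_genes = set(rng.choice(genes, size=min(planted_block, len(genes)),
                                   replace=False))

    non_root = ids[1:]
    annotations = []
    for g in genes:
        k = int(rng.integers(1, 4))
        for t in rng.choice(non_root, size=k, replace=False):
            annotations.append(GoAnnotation(g, str(t)))
    for g in sorted(planted_genes):
        annotations.append(GoAnnotation(g, planted_term))
    annotations = sorted(set(annotations))
    return SimGo(dag=dag, annotations=annotations,
                 planted_term=planted_term, planted_genes=planted_genes)


def sample_targets(planted_genes, background, n_targets: int,
                   strength: float = 0.7, seed: int = 0) -> set:
    """Draw a target set preferentially from the planted gene block."""
    rng = np.random.default_rng(seed)
    background = sorted(background)
    inside = sorted(set(planted_genes) & set(background))
    outside = sorted(set(background) - set(inside))
    k_in = min(len(inside), int(round(strength * n_targets)))
    k_out = min(len(outside), n_targets - k_in)
    chosen = set(rng.choice(inside, size=k_in, replace=False)) | \
        set(rng.choice(outside, size=k_out, replace=False))
    return chosen


# ---------------------------------------------------------------------------
# pathway
# ---------------------------------------------------------------------------

_LAYER_NAMES = {
    "receptor": ["TLR4", "TLR2", "TLR5", "TLR7", "TLR1", "TLR10"],
    "adaptor": ["MYD88", "TIRAP", "TICAM1"],
    "kinase": ["IRAK1", "IRAK4", "TBK1", "MAP3K7"],
    "tf": ["NFKB1", "RELA", "JUN"],
}


def gen_pathway(n_receptors: int = 4, n_adaptors: int = 2, n_kinases: int = 3,
                n_tfs: int = 2, seed: int = 0) -> PathwayDefinition:
    """A layered receptor→adaptor→kinase→TF pathway; edges only go forward."""
    rng = np.random.default_rng(seed)
    counts = {"receptor": n_receptors, "adaptor": n_adaptors,
              "kinase": n_kinases, "tf": n_tfs}
    layers: dict[str, list] = {}
    for layer, n in counts.items():
        pool = _LAYER_NAMES[layer]
        names = pool[:n] + [f"{layer.upper()}{i}" for i in
                            range(len(pool) + 1, n + 1)]
        layers[layer] = names[:n]

    members = {m for ms in layers.values() for m in ms}
    layer_map = {m: layer for layer, ms in layers.items() for m in ms}
    order = ["receptor", "adaptor", "kinase", "tf"]
    edges = []
    for up, down in zip(order, order[1:]):
        for src in layers[up]:
            k = int(rng.integers(1, len(layers[down]) + 1))
            for tgt in rng.choice(layers[down], size=k, replace=False):
                edges.append((src, str(tgt), None))
    edges = sorted(set(edges))
    return PathwayDefinition(members=members, edges=edges, layer=layer_map)


# ---------------------------------------------------------------------------
# full fixture on disk
# ---------------------------------------------------------------------------

@dataclass
class SimFixture:
    root: Path
    proteomes: SimProteomes
    expr: SimExpression
    go: SimGo
    pathway: PathwayDefinition
    config_path: Path
    truth: dict = field(default_factory=dict)


def generate_fixture(outdir, seed: int = 0,
                     cell_types=("cycling_monocytes", "DC2"),
                     conditions=("healthy", "uc_noninflamed"),
                     n_bact: int = 6, n_host: int = 12, n_genes: int = 120,
                     n_cells_per_group: int = 30, n_planted: int = 5,
                     n_decoys: int = 3, margin: float = 0.1) -> SimFixture:
    """Write the complete input tree + truth tables + a pipeline config.

    Host protein ids double as gene symbols (identity id→symbol mapping);
    pathway members are part of the gene universe, the disease-associated
    receptor TLR4 carries a planted disorder-passing motif (so it is a BEV
    target) and is expressed only in the disease condition, while one kinase
    (IRAK4) is healthy-only and TF expression is identical across conditions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]

    healthy, disease = conditions
    pathway = gen_pathway(seed=sub[0])
    pathway_members = sorted(pathway.members)

    # host proteome: pathway members first, padded with generic host genes
    n_extra = max(0, n_host - len(pathway_members))
    host_ids = pathway_members + [f"HGENE{i:03d}" for i in range(1, n_extra + 1)]
    prot = gen_proteomes(n_bact=n_bact, n_host=len(host_ids),
                         n_planted=n_planted, n_decoys=n_decoys,
                         margin=margin, seed=sub[1], host_ids=host_ids,
                         priority_hosts=("TLR4",))

    tf_genes = [m for m in pathway_members if pathway.layer[m] == "tf"]
    cs = {"TLR4": {(ct, disease) for ct in cell_types},
          "IRAK4": {(ct, healthy) for ct in cell_types}}
    cs = {g: grp for g, grp in cs.items() if g in pathway.members}
    gene_names = host_ids + [f"FILL{i:04d}" for i in
                             range(1, n_genes - len(host_ids) + 1)]
    expr = gen_expression(cell_types, conditions, n_genes=len(gene_names),
                          n_cells_per_group=n_cells_per_group, seed=sub[2],
                          gene_names=gene_names, condition_specific=cs,
                          constant_across_conditions=tf_genes,
                          protected_genes=pathway_members)

    go = gen_go(gene_names, seed=sub[3])

    # ---- write inputs -----------------------------------------------------
    write_fasta(prot.bact, outdir / "bact.fasta")
    write_fasta(prot.hosts, outdir / "host.fasta")
    with open(outdir / "bact_domains.tsv", "w") as fh:
        for d in sorted(prot.domains, key=lambda d: (d.protein_id, d.domain_acc,
                                                     d.start)):
            md5 = "-"
            fh.write(f"{d.protein_id}\t{md5}\t0\tPfam\t{d.domain_acc}\t"
                     f"synthetic domain\t{d.start}\t{d.end}\t0.0\tT\t"
                     f"2020-01-01\n")
    ddir = outdir / "disorder"
    ddir.mkdir(exist_ok=True)
    seq_by_id = {h.id: h.sequence for h in prot.hosts}
    for hid, profile in sorted(prot.profiles.items()):
        write_disorder_profile(profile, ddir / f"{hid}.tsv",
                               sequence=seq_by_id[hid])
    with open(outdir / "motif_classes.tsv", "w") as fh:
        fh.write("identifier\tregex\tdescription\n")
        for c in prot.motif_classes:
            fh.write(f"{c.identifier}\t{c.regex}\t{c.description}\n")
    with open(outdir / "motif_interactions.tsv", "w") as fh:
        fh.write("identifier\tdomain\n")
        for c in prot.motif_classes:
            for dom in sorted(c.interacting_domains):
                fh.write(f"{c.identifier}\t{dom}\n")
    write_expression(expr.values, expr.labels, outdir / "expression", fmt="mtx")
    write_obo(go.dag, outdir / "go.obo")
    write_gaf(go.annotations, outdir / "annotations.gaf")
    with open(outdir / "pathway_members.tsv", "w") as fh:
        fh.write("symbol\tlayer\n")
        for m in pathway_members:
            fh.write(f"{m}\t{pathway.layer[m]}\n")
    with open(outdir / "pathway_edges.tsv", "w") as fh:
        fh.write("source\ttarget\n")
        for s, t, _ in pathway.edges:
            fh.write(f"{s}\t{t}\n")

    # ---- truth tables -----------------------------------------------------
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    with open(tdir / "planted_interactions.tsv", "w") as fh:
        fh.write("bact_id\thost_id\tmotif_class\tdomain\tstart\tend\n")
        for row in sorted(prot.truth_matches):
            fh.write("\t".join(map(str, row)) + "\n")
    with open(tdir / "expressed.tsv", "w") as fh:
        fh.write("cell_type\tcondition\tgene\texpressed\n")
        for (ct, cond) in sorted(expr.truth_expressed):
            on = expr.truth_expressed[(ct, cond)]
            for g in sorted(gene_names):
                fh.write(f"{ct}\t{cond}\t{g}\t{g in on}\n")
    (tdir / "enriched_term.txt").write_text(go.planted_term + "\n")
    with open(tdir / "condition_specific_nodes.tsv", "w") as fh:
        fh.write("cell_type\tsymbol\tklass\n")
        for ct in sorted(cell_types):
            for g, on_groups in sorted(cs.items()):
                klass = ("disease-only" if (ct, disease) in on_groups
                         else "healthy-only")
                fh.write(f"{ct}\t{g}\t{klass}\n")

    # ---- pipeline config --------------------------------------------------
    config = {
        "inputs": {
            "bact_fasta": "bact.fasta",
            "bact_domains": "bact_domains.tsv",
            "host_fasta": "host.fasta",
            "disorder_dir": "disorder",
            "motif_classes": "motif_classes.tsv",
            "motif_interactions": "motif_interactions.tsv",
            "expression_mtx": "expression.mtx",
            "expression_genes": "expression.genes.tsv",
            "expression_cells": "expression.cells.tsv",
            "expression_labels": "expression.labels.tsv",
            "go_obo": "go.obo",
            "gaf": "annotations.gaf",
            "pathway_members": "pathway_members.tsv",
            "pathway_edges": "pathway_edges.tsv",
        },
        "thresholds": {
            "iupred_cutoff": 0.5, "anchor_cutoff": 0.4, "z_cutoff": -3.0,
            "p_cutoff": 1.0e-3, "q_cutoff": 0.05, "simrel_threshold": 0.7,
        },
        "contexts": {"healthy_condition": healthy,
                     "disease_condition": disease},
        "seed": int(seed),
    }
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))

    truth = {
        "interactions": prot.truth_matches,
        "edges": prot.truth_edges,
        "expressed": expr.truth_expressed,
        "enriched_term": go.planted_term,
        "condition_specific": cs,
    }
    return SimFixture(root=outdir, proteomes=prot, expr=expr, go=go,
                      pathway=pathway, config_path=config_path, truth=truth)
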