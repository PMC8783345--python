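"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA (protein sequences), InterProScan-style domain TSV, IUPred2A
long-format per-residue disorder scores, ELM-style motif class/interaction
TSVs, expression matrices (MTX triplet or dense TSV) with cell labels,
GO DAG (OBO subset: id / name / namespace / is_a), GAF 2.2 annotations,
pathway member + edge tables, and SIF / attribute-TSV network exports.

Coordinates are 1-based inclusive everywhere; conversion to Python slices
happens exactly once, at the point of use. All readers validate rather than
coerce, and all writers are byte-deterministic (sorted rows, fixed float
formatting).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from vesiclink.errors import FormatError

logger = logging.getLogger(__name__)

_PFAM_RE = re.compile(r"^PF\d{5}$")
_SEQ_RE = re.compile(r"^[A-Z]+$")

# float format shared by every TSV writer so reruns are byte-identical
FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence: 20 canonical amino acids plus 'X' (unknown)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise FormatError("protein record with empty id")
        if len(self.sequence) < 1:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        if not _SEQ_RE.match(self.sequence):
            raise FormatError(
                f"protein {self.id!r}: sequence contains characters outside A-Z"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """A domain (e.g. Pfam) annotated on a bacterial protein, 1-based span."""

    protein_id: str
    domain_acc: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"domain {self.domain_acc} on {self.protein_id}: "
                f"invalid span {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class MotifClass:
    """A linear-motif class: regex plus the domain accessions known to bind it."""

    identifier: str
    regex: str
    interacting_domains: frozenset = frozenset()
    description: str = ""

    def __post_init__(self):
        try:
            object.__setattr__(self, "_pattern", re.compile(self.regex))
        except re.error as exc:
            raise FormatError(
                f"motif class {self.identifier!r}: regex does not compile: {exc}"
            ) from exc

    @property
    def pattern(self) -> re.Pattern:
        return self._pattern

    @property
    def usable(self) -> bool:
        """Classes without any interacting domain cannot support a prediction."""
        return len(self.interacting_domains) > 0


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue IUPred (disorder) and ANCHOR2 (binding) scores, both in [0,1]."""

    protein_id: str
    iupred: tuple
    anchor: tuple

    def __post_init__(self):
        if len(self.iupred) != len(self.anchor):
            raise FormatError(
                f"disorder profile {self.protein_id}: score vectors differ in length"
            )
        for name, vec in (("iupred", self.iupred), ("anchor", self.anchor)):
            for v in vec:
                if not (0.0 <= v <= 1.0):
                    raise FormatError(
                        f"disorder profile {self.protein_id}: {name} score {v} "
                        "outside [0,1]"
                    )

    def __len__(self) -> int:
        return len(self.iupred)


@dataclass(frozen=True)
class GoTerm:
    id: str
    name: str
    namespace: str
    parents: frozenset = frozenset()  # is_a targets


class GoDag:
    """A GO DAG restricted to is_a edges.

    Supports ancestor closure (memoised) and is the semantic backbone for
    annotation propagation and simRel similarity.
    """

    def __init__(self, terms: Mapping[str, GoTerm]):
        self.terms = dict(terms)
        for t in self.terms.values():
            for p in t.parents:
                if p not in self.terms:
                    raise FormatError(f"term {t.id}: parent {p} not in DAG")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            g.add_edges_from((t.id, p) for p in t.parents)
        if not nx.is_directed_acyclic_graph(g):
            raise FormatError("GO graph contains a cycle")
        self._graph = g
        self._anc_cache: dict[str, frozenset] = {}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def roots(self) -> set:
        return {t.id for t in self.terms.values() if not t.parents}

    def ancestors(self, term_id: str, include_self: bool = True) -> frozenset:
        """All terms reachable from *term_id* via is_a, optionally with itself."""
        if term_id not in self.terms:
            raise KeyError(term_id)
        if term_id not in self._anc_cache:
            self._anc_cache[term_id] = frozenset(
                nx.descendants(self._graph, term_id)
            )
        anc = self._anc_cache[term_id]
        return anc | {term_id} if include_self else anc

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id].namespace

    def depth(self, term_id: str) -> int:
        """Shortest is_a distance to a root."""
        roots = self.roots()
        if term_id in roots:
            return 0
        lengths = nx.single_source_shortest_path_length(self._graph, term_id)
        return min(l for t, l in lengths.items() if t in roots)


class GoAnnotation(NamedTuple):
    gene: str
    term: str


@dataclass
class PathwayDefinition:
    """A signalling pathway: member gene symbols, directed edges, layer labels."""

    members: set
    edges: list  # (source, target, sign-or-None)
    layer: dict = field(default_factory=dict)  # symbol -> receptor|adaptor|kinase|tf|other

    def __post_init__(self):
        for s, t, _ in self.edges:
            if s not in self.members or t not in self.members:
                raise FormatError(f"pathway edge ({s},{t}) has a non-member endpoint")
            if s == t:
                raise FormatError(f"pathway self-loop on {s}")


class ExpressionMatrix(NamedTuple):
    """Raw expression tensor (genes x cells) with per-cell labels."""

    values: pd.DataFrame  # index: gene symbols, columns: cell ids
    labels: pd.DataFrame  # index: cell ids; columns: cell_type, condition


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _fasta_id(header_token: str) -> str:
    parts = header_token.split("|")
    if len(parts) == 3:  # UniProt-style db|ACC|name
        return parts[1]
    return header_token


def read_fasta(path) -> list:
    """Read protein records; UniProt ``db|ACC|name`` headers yield ACC as id."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = _fasta_id(rec.id)
        if pid in seen:
            raise FormatError(f"duplicate id {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"record {pid!r} in {path}: empty sequence")
        records.append(ProteinRecord(id=pid, sequence=seq))
    if not records:
        raise FormatError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


# ---------------------------------------------------------------------------
# InterProScan-style domain table
# ---------------------------------------------------------------------------

#: named dialects: 1-based column indices (protein id, signature acc, start, stop)
DOMAIN_DIALECTS = {
    "interproscan-tsv": (1, 5, 7, 8),
    "simple": (1, 2, 3, 4),
}


def read_domain_table(path, dialect: str = "interproscan-tsv",
                      skip_policy: str = "pfam-only") -> list:
    """Parse a domain-annotation TSV.

    skip_policy:
      * ``pfam-only`` — keep rows whose signature matches ``PFxxxxx``; count the
        rest and log the count.
      * ``keep-all`` — keep every row; non-Pfam accessions are accepted verbatim
        with a warning.
    """
    if dialect not in DOMAIN_DIALECTS:
        raise FormatError(f"unknown domain-table dialect {dialect!r}")
    id_c, acc_c, start_c, stop_c = (c - 1 for c in DOMAIN_DIALECTS[dialect])
    need = max(id_c, acc_c, start_c, stop_c) + 1

    annotations, skipped = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < need:
                raise FormatError(f"{path}:{lineno}: expected ≥{need} columns")
            acc = cols[acc_c]
            if not _PFAM_RE.match(acc):
                if skip_policy == "pfam-only":
                    skipped += 1
                    continue
                logger.warning("%s:%d: non-Pfam accession %r kept verbatim",
                               path, lineno, acc)
            try:
                start, stop = int(cols[start_c]), int(cols[stop_c])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start > stop:
                raise FormatError(f"{path}:{lineno}: start {start} > stop {stop}")
            annotations.append(
                DomainAnnotation(cols[id_c], acc, start, stop, source=dialect)
            )
    if skipped:
        logger.info("%s: skipped %d non-domain rows (policy %s)",
                    path, skipped, skip_policy)
    return annotations


# ---------------------------------------------------------------------------
# IUPred2A long-format disorder profile
# ---------------------------------------------------------------------------

def read_disorder_profile(path, protein_id: str | None = None,
                          sequence: str | None = None) -> DisorderProfile:
    """Parse ``POS<TAB>RES<TAB>IUPRED<TAB>ANCHOR`` lines ('#' = comment).

    Positions must be 1..L contiguous. If *sequence* is given, the residue
    column is cross-checked against it.
    """
    pid = protein_id or Path(path).stem
    iupred, anchor, residues = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            pos = int(cols[0])
            expected = len(iupred) + 1
            if pos != expected:
                if pos <= len(iupred):
                    raise FormatError(f"{path}:{lineno}: duplicate position {pos}")
                raise FormatError(f"{path}: position gap at {expected}")
            s1, s2 = float(cols[2]), float(cols[3])
            for v in (s1, s2):
                if not (0.0 <= v <= 1.0):
                    raise FormatError(
                        f"{path}:{lineno}: score {v} outside [0,1]"
                    )
            residues.append(cols[1])
            iupred.append(s1)
            anchor.append(s2)
    if not iupred:
        raise FormatError(f"{path}: no data lines")
    if sequence is not None:
        if "".join(residues) != sequence:
            raise FormatError(
                f"{path}: residue column disagrees with FASTA sequence for {pid}"
            )
    return DisorderProfile(pid, tuple(iupred), tuple(anchor))


def write_disorder_profile(profile: DisorderProfile, path,
                           sequence: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# POS\tRES\tIUPRED2\tANCHOR2\n")
        for i, (s1, s2) in enumerate(zip(profile.iupred, profile.anchor)):
            res = sequence[i] if sequence else "X"
            fh.write(f"{i + 1}\t{res}\t{s1:.4f}\t{s2:.4f}\n")


# ---------------------------------------------------------------------------
# ELM-style motif classes + interactions
# ---------------------------------------------------------------------------

def read_motif_classes(classes_path, interactions_path) -> list:
    """Join the class table (identifier, regex[, description]) with the
    interaction table (identifier, domain accession) on identifier.

    Classes with zero interacting domains are retained but ``usable`` is False.
    """
    classes = pd.read_csv(classes_path, sep="\t", comment="#", dtype=str)
    inter = pd.read_csv(interactions_path, sep="\t", comment="#", dtype=str)
    for col in ("identifier", "regex"):
        if col not in classes.columns:
            raise FormatError(f"{classes_path}: missing column {col!r}")
    if not {"identifier", "domain"}.issubset(inter.columns):
        raise FormatError(f"{interactions_path}: need columns identifier, domain")

    known = set(classes["identifier"])
    dangling = sorted(set(inter["identifier"]) - known)
    if dangling:
        raise FormatError(
            f"{interactions_path}: interaction rows reference unknown classes: "
            + ", ".join(dangling)
        )
    domains_by_class = inter.groupby("identifier")["domain"].agg(frozenset)

    out = []
    for row in classes.itertuples(index=False):
        out.append(
            MotifClass(
                identifier=row.identifier,
                regex=row.regex,
                interacting_domains=frozenset(
                    domains_by_class.get(row.identifier, frozenset())
                ),
                description=getattr(row, "description", "") or "",
            )
        )
    return out


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _read_labels(labels_path) -> pd.DataFrame:
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    need = {"cell_id", "cell_type", "condition"}
    if not need.issubset(labels.columns):
        raise FormatError(f"{labels_path}: need columns {sorted(need)}")
    if labels["cell_id"].duplicated().any():
        raise FormatError(f"{labels_path}: duplicate cell ids")
    return labels.set_index("cell_id")


def read_expression(path, labels_path, genes_path=None, cells_path=None) -> ExpressionMatrix:
    """Load a genes x cells matrix plus per-cell (cell type, condition) labels.

    ``path`` ending in ``.mtx`` selects the MTX triplet route, which requires
    *genes_path* and *cells_path* (one label per line, matrix row/column order).
    Anything else is read as a dense TSV (gene rows, cell-id header).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise FormatError("MTX input needs genes_path and cells_path")
        mat = scipy.io.mmread(str(path))
        genes = [l.strip() for l in open(genes_path) if l.strip()]
        cells = [l.strip() for l in open(cells_path) if l.strip()]
        mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                         dtype=float)
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"{path}: matrix shape {mat.shape} != labels "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        values = pd.DataFrame(mat, index=genes, columns=cells)
    else:
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)

    if values.index.duplicated().any():
        raise FormatError(f"{path}: duplicate gene symbols")
    if (values.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression values")

    labels = _read_labels(labels_path)
    if set(labels.index) != set(values.columns) or len(labels) != values.shape[1]:
        raise FormatError(
            f"{labels_path}: label rows do not match the {values.shape[1]} "
            "matrix columns"
        )
    return ExpressionMatrix(values=values, labels=labels.loc[values.columns])


def write_expression(values: pd.DataFrame, labels: pd.DataFrame, out_prefix,
                     fmt: str = "mtx") -> None:
    """Write a matrix + labels; the inverse of :func:`read_expression`."""
    out_prefix = Path(out_prefix)
    labels_out = labels.reset_index().rename(columns={"index": "cell_id"})
    if "cell_id" not in labels_out.columns:
        labels_out = labels_out.rename(columns={labels_out.columns[0]: "cell_id"})
    labels_out.to_csv(out_prefix.with_suffix(".labels.tsv"), sep="\t", index=False)
    if fmt == "mtx":
        sp = scipy.sparse.coo_matrix(values.to_numpy())
        scipy.io.mmwrite(str(out_prefix.with_suffix(".mtx")), sp)
        out_prefix.with_suffix(".genes.tsv").write_text(
            "".join(f"{g}\n" for g in values.index))
        out_prefix.with_suffix(".cells.tsv").write_text(
            "".join(f"{c}\n" for c in values.columns))
    elif fmt == "tsv":
        values.to_csv(out_prefix.with_suffix(".tsv"), sep="\t",
                      float_format=FLOAT_FORMAT)
    else:
        raise FormatError(f"unknown expression format {fmt!r}")


# ---------------------------------------------------------------------------
# GO: OBO subset + GAF 2.2
# ---------------------------------------------------------------------------

def read_obo(path) -> GoDag:
    """Parse the OBO subset: [Term] stanzas with id, name, namespace, is_a."""
    terms: dict[str, GoTerm] = {}
    cur: dict | None = None

    def _flush():
        nonlocal cur
        if cur is not None and "id" in cur:
            terms[cur["id"]] = GoTerm(
                id=cur["id"],
                name=cur.get("name", ""),
                namespace=cur.get("namespace", ""),
                parents=frozenset(cur.get("is_a", [])),
            )
        cur = None

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                _flush()
                cur = {}
            elif line.startswith("[") and line.endswith("]"):
                _flush()  # e.g. [Typedef] — ignored
            elif cur is not None and ":" in line:
                key, _, val = line.partition(":")
                key, val = key.strip(), val.strip()
                if key == "is_a":
                    cur.setdefault("is_a", []).append(val.split("!")[0].strip())
                elif key in ("id", "name", "namespace"):
                    cur[key] = val
    _flush()
    if not terms:
        raise FormatError(f"{path}: no [Term] stanzas")
    return GoDag(terms)


def write_obo(dag: GoDag, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for tid in sorted(dag.terms):
            t = dag.terms[tid]
            fh.write(f"\n[Term]\nid: {t.id}\nname: {t.name}\n"
                     f"namespace: {t.namespace}\n")
            for p in sorted(t.parents):
                fh.write(f"is_a: {p}\n")


def read_gaf(path, dag: GoDag | None = None) -> list:
    """Parse GAF 2.2; returns (gene symbol, term id) annotations.

    Annotations to terms outside *dag* (when given) are skipped with a warning.
    """
    annotations, skipped = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: expected ≥5 GAF columns")
            symbol, term = cols[2], cols[4]
            if not symbol:
                raise FormatError(f"{path}:{lineno}: empty gene symbol")
            if dag is not None and term not in dag:
                skipped += 1
                continue
            annotations.append(GoAnnotation(symbol, term))
    if skipped:
        logger.warning("%s: skipped %d annotations to unknown terms", path, skipped)
    return annotations


def write_gaf(annotations: Iterable[GoAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for ann in sorted(annotations):
            fh.write(f"DB\t{ann.gene}\t{ann.gene}\tenables\t{ann.term}\t"
                     f"REF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20200101\tDB\t\t\n")


# ---------------------------------------------------------------------------
# pathway tables
# ---------------------------------------------------------------------------

def read_pathway(members_path, edges_path) -> PathwayDefinition:
    """Members TSV: ``symbol[<TAB>layer]``; edges TSV ``source<TAB>target[<TAB>sign]``
    or SIF ``source<TAB>relation<TAB>target`` (by ``.sif`` extension)."""
    members_df = pd.read_csv(members_path, sep="\t", dtype=str)
    if "symbol" not in members_df.columns:
        raise FormatError(f"{members_path}: missing column 'symbol'")
    members = set(members_df["symbol"])
    layer = {}
    if "layer" in members_df.columns:
        layer = dict(zip(members_df["symbol"], members_df["layer"]))

    edges = []
    is_sif = str(edges_path).endswith(".sif")
    with open(edges_path) as fh:
        header_skipped = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if not is_sif and not header_skipped:
                header_skipped = True
                if cols[0] in ("source", "src"):
                    continue
            if is_sif:
                if len(cols) != 3:
                    raise FormatError(f"{edges_path}: SIF lines need 3 columns")
                src, _, tgt = cols
                sign = None
            else:
                src, tgt = cols[0], cols[1]
                sign = cols[2] if len(cols) > 2 and cols[2] else None
            edges.append((src, tgt, sign))
    return PathwayDefinition(members=members, edges=edges, layer=layer)


# ---------------------------------------------------------------------------
# network export (SIF + attribute TSVs)
# ---------------------------------------------------------------------------

def write_network(edges: Sequence[tuple], out_prefix,
                  node_attrs: pd.DataFrame | None = None,
                  edge_attrs: pd.DataFrame | None = None,
                  allow_empty: bool = False) -> None:
    """Write a network as ``<prefix>.sif`` plus attribute TSVs.

    *edges* are (source, relation, target) triples. Rows are sorted
    lexicographically, so identical inputs give byte-identical files.
    """
    if not edges and not allow_empty:
        raise FormatError("refusing to write an empty network (allow_empty=False)")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{out_prefix}.sif", "w") as fh:
        for src, rel, tgt in sorted(edges):
            fh.write(f"{src}\t{rel}\t{tgt}\n")
    if node_attrs is not None:
        node_attrs.sort_index().to_csv(
            f"{out_prefix}.nodes.tsv", sep="\t", float_format=FLOAT_FORMAT)
    if edge_attrs is not None:
        sort_cols = [c for c in ("source", "target") if c in edge_attrs.columns]
        out = edge_attrs.sort_values(sort_cols) if sort_cols else edge_attrs
        out.to_csv(f"{out_prefix}.edges.tsv", sep="\t", index=False,
                   float_format=FLOAT_FORMAT)
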