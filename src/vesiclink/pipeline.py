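"""Single-command pipeline runner: config validation, staged execution,
per-stage caching and a reproducibility manifest.

Stage order mirrors the analysis workflow: (1) proteome + motif loading,
(2) expression contexts, (3) interaction prediction + per-context
contextualization, (4) pathway loading, (5) condition overlay per cell type,
(6) GO enrichment per context. All outputs are byte-deterministic; a cached
rerun reloads stage outputs instead of recomputing and produces identical
files. The manifest records thresholds, the seed and a checksum per input
and output — and nothing run-dependent, so it too is byte-stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from vesiclink import enrichment as enr
from vesiclink import expression as expr
from vesiclink import interactome as inter
from vesiclink import overlay as ovl
from vesiclink import predict as pred
from vesiclink.errors import ConfigError, PipelineError
from vesiclink import io as vio

logger = logging.getLogger(__name__)

_REQUIRED_INPUTS = (
    "bact_fasta", "bact_domains", "host_fasta", "disorder_dir",
    "motif_classes", "motif_interactions", "expression_mtx",
    "expression_genes", "expression_cells", "expression_labels",
    "go_obo", "gaf", "pathway_members", "pathway_edges",
)

_THRESHOLD_RANGES = {
    "iupred_cutoff": (0.0, 1.0),
    "anchor_cutoff": (0.0, 1.0),
    "z_cutoff": (-10.0, 0.0),
    "p_cutoff": (0.0, 1.0),
    "q_cutoff": (0.0, 1.0),
    "simrel_threshold": (0.0, 1.0),
}


@dataclass
class RunConfig:
    inputs: dict
    thresholds: dict = field(default_factory=dict)
    contexts: dict = field(default_factory=dict)
    seed: int = 0
    base_dir: Path = Path(".")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            inputs=raw.get("inputs", {}),
            thresholds=raw.get("thresholds", {}),
            contexts=raw.get("contexts", {}),
            seed=int(raw.get("seed", 0)),
            base_dir=path.parent,
        )

    def path(self, key: str) -> Path:
        return self.base_dir / self.inputs[key]

    def threshold(self, key: str) -> float:
        defaults = {"iupred_cutoff": 0.5, "anchor_cutoff": 0.4,
                    "z_cutoff": -3.0, "p_cutoff": 1e-3, "q_cutoff": 0.05,
                    "simrel_threshold": 0.7}
        return float(self.thresholds.get(key, defaults[key]))

    def validate(self) -> None:
        missing = [k for k in _REQUIRED_INPUTS if k not in self.inputs]
        if missing:
            raise ConfigError(f"config missing input keys: {missing}")
        absent = [k for k in _REQUIRED_INPUTS if not self.path(k).exists()]
        if absent:
            raise ConfigError(
                "config references missing paths: "
                + ", ".join(f"{k}={self.path(k)}" for k in absent))
        for key, (lo, hi) in _THRESHOLD_RANGES.items():
            v = self.threshold(key)
            if not (lo <= v <= hi):
                raise ConfigError(f"threshold {key}={v} outside [{lo},{hi}]")
        for key in ("healthy_condition", "disease_condition"):
            if key not in self.contexts:
                raise ConfigError(f"config missing contexts.{key}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record):
        self.count += 1


def _context_key(ct: str, cond: str) -> str:
    return f"{ct}__{cond}"


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, outdir, cache: bool = True) -> Path:
    """Execute all stages; returns the output directory.

    Stage caching: a stage whose input checksums and parameters match the
    previous run (recorded in ``.cache.json``) reloads its own output files
    instead of recomputing. Cached and fresh runs write byte-identical trees.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache_path = outdir / ".cache.json"
    old_cache = {}
    if cache and cache_path.exists():
        old_cache = json.loads(cache_path.read_text())
    new_cache: dict = {}

    counter = _WarningCounter()
    logging.getLogger("vesiclink").addHandler(counter)
    manifest: dict = {
        "thresholds": {k: config.threshold(k) for k in _THRESHOLD_RANGES},
        "contexts": dict(config.contexts),
        "seed": config.seed,
        "stages": [],
    }

    def _stage_key(name: str, input_keys, params: dict) -> str:
        h = hashlib.sha256()
        for k in input_keys:
            p = config.path(k)
            if p.is_dir():
                for f in sorted(p.iterdir()):
                    h.update(_sha256(f).encode())
            else:
                h.update(_sha256(p).encode())
        h.update(json.dumps(params, sort_keys=True).encode())
        return f"{name}:{h.hexdigest()}"

    def _record(name: str, input_keys, outputs):
        def _input_sum(k):
            p = config.path(k)
            if p.is_dir():
                h = hashlib.sha256()
                for f in sorted(p.iterdir()):
                    h.update(_sha256(f).encode())
                return h.hexdigest()
            return _sha256(p)

        manifest["stages"].append({
            "name": name,
            "inputs": {k: {"path": str(config.inputs[k]),
                           "sha256": _input_sum(k)} for k in input_keys},
            "outputs": {str(p.relative_to(outdir)): _sha256(p)
                        for p in sorted(outputs)},
        })

    try:
        # ---- stage 1: proteomes, domains, motif classes, disorder --------
        stage = "1-proteomes"
        try:
            bact = vio.read_fasta(config.path("bact_fasta"))
            hosts = vio.read_fasta(config.path("host_fasta"))
            domains = vio.read_domain_table(config.path("bact_domains"))
            classes = vio.read_motif_classes(config.path("motif_classes"),
                                             config.path("motif_interactions"))
            seq_by_id = {h.id: h.sequence for h in hosts}
            profiles = {}
            for h in hosts:
                ppath = config.path("disorder_dir") / f"{h.id}.tsv"
                if not ppath.exists():
                    raise vio.FormatError(f"no disorder profile for {h.id}")
                profiles[h.id] = vio.read_disorder_profile(
                    ppath, protein_id=h.id, sequence=seq_by_id[h.id])
            _record(stage, ["bact_fasta", "host_fasta", "bact_domains",
                            "motif_classes", "motif_interactions"], [])
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- stage 2: expression contexts --------------------------------
        stage = "2-contexts"
        ctx_dir = outdir / "contexts"
        ctx_dir.mkdir(exist_ok=True)
        input_keys = ["expression_mtx", "expression_genes",
                      "expression_cells", "expression_labels"]
        params = {"z_cutoff": config.threshold("z_cutoff")}
        key = _stage_key(stage, input_keys, params)
        try:
            matrix = vio.read_expression(
                config.path("expression_mtx"),
                config.path("expression_labels"),
                genes_path=config.path("expression_genes"),
                cells_path=config.path("expression_cells"))
            groups = sorted(set(map(tuple,
                                    matrix.labels[["cell_type", "condition"]]
                                    .itertuples(index=False))))
            expected = {g: ctx_dir / f"{_context_key(*g)}.tsv" for g in groups}
            if cache and old_cache.get(stage) == key and \
                    all(p.exists() for p in expected.values()):
                contexts = {g: expr.read_context_tsv(p, *g)
                            for g, p in expected.items()}
            else:
                contexts = expr.contexts_from_matrix(
                    matrix, z_cutoff=config.threshold("z_cutoff"))
                for g, ctx in contexts.items():
                    ctx.write_tsv(expected[g])
            new_cache[stage] = key
            _record(stage, input_keys, expected.values())
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- stage 3: prediction + contextualization ----------------------
        stage = "3-predict"
        input_keys = ["bact_fasta", "host_fasta", "bact_domains",
                      "motif_classes", "motif_interactions", "disorder_dir"]
        params = {"iupred_cutoff": config.threshold("iupred_cutoff"),
                  "anchor_cutoff": config.threshold("anchor_cutoff")}
        key = _stage_key(stage, input_keys, params)
        edges_path = outdir / "edges.tsv"
        try:
            if cache and old_cache.get(stage) == key and edges_path.exists():
                interactions = pred.read_edges_tsv(edges_path)
            else:
                interactions = pred.predict_interactions(
                    bact, domains, hosts, profiles, classes,
                    iupred_cutoff=config.threshold("iupred_cutoff"),
                    anchor_cutoff=config.threshold("anchor_cutoff"))
                pred.write_edges_tsv(interactions, edges_path,
                                     disorder_profiles=profiles)
            new_cache[stage] = key

            inter_dir = outdir / "interactomes"
            inter_dir.mkdir(exist_ok=True)
            interactomes = {}
            outputs = [edges_path]
            for g, ctx in sorted(contexts.items()):
                it = inter.contextualize(interactions, ctx)
                interactomes[g] = it
                prefix = inter_dir / _context_key(*g)
                pred.write_edges_tsv(it.edges, f"{prefix}.edges.tsv")
                inter.degree_report(it).to_csv(
                    f"{prefix}.hubs.tsv", sep="\t", index=False)
                inter.convergent_targets(it).to_csv(
                    f"{prefix}.convergent.tsv", sep="\t", index=False)
                vio.write_network(inter.to_sif_edges(it), prefix,
                                  allow_empty=True)
                outputs += [Path(f"{prefix}.edges.tsv"),
                            Path(f"{prefix}.hubs.tsv"),
                            Path(f"{prefix}.convergent.tsv"),
                            Path(f"{prefix}.sif")]
            summary_path = outdir / "summary.tsv"
            inter.summary_frame(interactomes.values()).to_csv(
                summary_path, sep="\t", index=False)
            outputs.append(summary_path)
            _record(stage, input_keys, outputs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- stage 4: pathway ---------------------------------------------
        stage = "4-pathway"
        try:
            pathway = vio.read_pathway(config.path("pathway_members"),
                                       config.path("pathway_edges"))
            _record(stage, ["pathway_members", "pathway_edges"], [])
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- stage 5: overlay per cell type -------------------------------
        stage = "5-overlay"
        healthy = config.contexts["healthy_condition"]
        disease = config.contexts["disease_condition"]
        ovl_dir = outdir / "overlays"
        ovl_dir.mkdir(exist_ok=True)
        try:
            outputs = []
            cell_types = sorted({ct for ct, _ in contexts})
            for ct in cell_types:
                if (ct, healthy) not in contexts or (ct, disease) not in contexts:
                    continue
                bev_targets = (interactomes[(ct, healthy)].target_symbols |
                               interactomes[(ct, disease)].target_symbols)
                cp = ovl.overlay(pathway, contexts[(ct, healthy)],
                                 contexts[(ct, disease)], bev_targets)
                prefix = ovl_dir / ct
                ovl.write_overlay(cp, prefix)
                ovl.targeted_receptors(cp).to_csv(
                    f"{prefix}.receptors.tsv", sep="\t", index=False)
                outputs += [Path(f"{prefix}{s}") for s in
                            (".sif", ".nodes.tsv", ".edges.tsv",
                             ".condition_specific.tsv", ".receptors.tsv")]
            _record(stage, ["pathway_members", "pathway_edges"], outputs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- stage 6: enrichment ------------------------------------------
        stage = "6-enrichment"
        enr_dir = outdir / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        try:
            dag = vio.read_obo(config.path("go_obo"))
            annotations = vio.read_gaf(config.path("gaf"), dag=dag)
            gene2terms = enr.propagate_annotations(annotations, dag)
            outputs = []
            enriched_terms: dict[tuple, set] = {}
            for g, ctx in sorted(contexts.items()):
                background = ctx.expressed_genes
                targets = interactomes[g].target_symbols & background
                results = []
                if targets:
                    results = enr.hypergeometric_enrich(
                        targets, background, gene2terms, dag=dag,
                        p_cutoff=config.threshold("p_cutoff"),
                        q_cutoff=config.threshold("q_cutoff"))
                prefix = enr_dir / _context_key(*g)
                enr.write_enrichment_tsv(results, f"{prefix}.tsv")
                term_prob = enr.term_probabilities(background, gene2terms)
                clusters = enr.reduce_terms(
                    results, dag, term_prob,
                    threshold=config.threshold("simrel_threshold"))
                enr.write_clusters_tsv(clusters, f"{prefix}.clusters.tsv")
                enriched_terms[g] = {r.term_id for r in results if r.enriched}
                outputs += [Path(f"{prefix}.tsv"),
                            Path(f"{prefix}.clusters.tsv")]
            for cond in (healthy, disease):
                sets = {ct: enriched_terms.get((ct, cond), set())
                        for ct in sorted({c for c, _ in contexts})}
                if 2 <= len(sets) <= 6:
                    part = enr.venn_partition(sets)
                    vpath = enr_dir / f"venn_{cond}.tsv"
                    enr.write_venn_tsv(part, vpath)
                    outputs.append(vpath)
            _record(stage, ["go_obo", "gaf"], outputs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        manifest["n_warnings"] = counter.count
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        if cache:
            cache_path.write_text(json.dumps(new_cache, indent=2,
                                             sort_keys=True) + "\n")
        return outdir
    finally:
        logging.getLogger("vesiclink").removeHandler(counter)
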