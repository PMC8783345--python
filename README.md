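# vesiclink

Gut bacteria shed membrane vesicles (bacterial extracellular vesicles, BEVs)
whose protein cargo can reach and signal to host immune cells. `vesiclink`
predicts which host proteins those BEV proteins can bind, in which immune
cell type, and under which condition (healthy mucosa vs non-inflamed
ulcerative colitis), and overlays the result on a signalling pathway such as
the Toll-like receptor (TLR) cascade. It is aimed at computational biologists
studying host–microbe crosstalk who have a vesicle proteome, transcriptomic
data for the host cells of interest, and standard annotation resources.

## What it computes

**Domain→motif interaction prediction.** A bacterial protein carrying a
domain *D* (Pfam accession, e.g. from an InterProScan run) is predicted to
bind a host protein carrying a cognate short linear motif: an occurrence of
an ELM-style class regex whose interacting-domain set contains *D*. Because
linear motifs are only accessible in unstructured regions, a motif instance
on span *[s, e]* counts only when the mean per-residue disorder scores over
the span satisfy

```
mean(IUPred[s..e]) > 0.5   and   mean(ANCHOR2[s..e]) > 0.4
```

(both strict). Overlapping regex matches are all enumerated; `$` anchors a
motif to the protein's C-terminus.

**Expressed-gene calling.** For each (cell type, condition) group a gene is
called *not expressed* when its log2 mean expression lies more than three
population standard deviations below the mean of the group's nonzero-mean
genes:

```
expressed(g)  ⇔  log2 x̄_g ≥ μ − 3σ        (zeros excluded from μ, σ)
```

Bulk counts are first normalized with median-of-ratios size factors. The
predicted interactome is then restricted per context to edges whose host
gene is expressed, yielding cell-type- and condition-specific networks,
degree/hub reports and convergent-target tables.

**Function and pathway context.** BEV-target genes are tested for GO
over-representation against the expressed background with the upper-tail
hypergeometric P(X ≥ k), Benjamini–Hochberg correction per namespace
(enriched ⇔ p < 10⁻³ and q < 0.05), and redundancy-reduced with Schlicker's
simRel semantic similarity (greedy clustering at 0.7). A pathway definition
(members, layers, directed edges) is overlaid with both conditions: nodes
are classed both / healthy-only / disease-only / absent, scored with
Δ = log2(disease) − log2(healthy) where present in both, and flagged as BEV
targets per context.

Everything can also be run on synthetic data with planted ground truth
(motifs in disordered spans, decoys in ordered spans, off/low/condition-
specific genes, one enriched GO term, a layered TLR-like pathway), which is
how the test suite validates the pipeline end to end.

## Worked example

```
vesiclink simulate --out fx --seed 7
vesiclink run-all --config fx/config.yaml --out out
cat out/summary.tsv
```

```
cell_type	condition	n_expressed_genes	n_target_proteins	n_bev_proteins_interacting	n_edges
DC2	healthy	101	4	5	8
DC2	uc_noninflamed	101	4	4	9
cycling_monocytes	healthy	101	4	5	8
cycling_monocytes	uc_noninflamed	101	4	4	9
```

Each row is one context: of the 120 simulated genes, 101 pass the z-score
expression call; 4 host proteins are predicted BEV targets there, reached by
8–9 domain–motif edges from 4–5 vesicle proteins. The per-edge evidence is
in `out/edges.tsv`:

```
bact_id	host_id	domain	motif_class	start	end	iupred_mean	anchor_mean
BEV001	IRAK1	PF00018	LIG_SH3_lite	6	10	0.79394	0.87106
BEV002	IRAK4	PF00069	DOC_KIN_1	6	10	0.83894	0.85318
```

i.e. BEV001 carries an SH3 domain and IRAK1 carries a proline-rich SH3
motif at residues 6–10 whose mean disorder scores (0.79, 0.87) clear the
cutoffs. The pathway overlay (`out/overlays/DC2.receptors.tsv`) shows the
planted disease-specific receptor:

```
receptor	expressed_healthy	expressed_disease	target_in_healthy	target_in_disease
TLR4	False	True	False	True
```

TLR4 is expressed only in the disease condition, so it is a reachable BEV
target only there — the cell-type- and condition-specific conclusion the
pipeline is built to surface. `out/overlays/DC2.nodes.tsv` carries the
per-node class and Δ (transcription-factor rows have Δ = 0 by construction
in the simulation).

## Acceptance script

`scripts/acceptance.py` regenerates the seeded synthetic fixture, runs the
complete pipeline on it (all six stages, fresh, no cached state) and writes
its result summary as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| module | role |
| --- | --- |
| `vesiclink.io` | FASTA, InterProScan TSV, IUPred2A profiles, ELM-style class tables, MTX/TSV expression, OBO/GAF, pathway tables, SIF export |
| `vesiclink.expression` | group means, z-score expressed calls, median-of-ratios normalization |
| `vesiclink.predict` | motif scanning, disorder gating, interaction prediction |
| `vesiclink.interactome` | context restriction, hubs, convergent targets |
| `vesiclink.enrichment` | annotation propagation, hypergeometric ORA, BH, simRel, Venn partitions |
| `vesiclink.overlay` | condition overlay of a layered pathway |
| `vesiclink.simulate` | synthetic inputs with planted truth + brute-force oracle |
| `vesiclink.pipeline` / `vesiclink.cli` | staged runner with caching + `vesiclink` CLI |

See `docs/methods.md` for the modelling choices, defaults and limitations.
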