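# Methods

## Interaction model

The core prediction is a domain–motif interaction (DMI) model: a bacterial
vesicle protein presenting a domain can bind a host protein that carries a
cognate short linear motif in an accessible region. Three inputs define the
model: domain annotations on the bacterial proteome (Pfam accessions with
coordinates, InterProScan-style TSV), a motif-class table (identifier,
regex, set of interacting domain accessions — the ELM classes/interactions
shape), and per-residue disorder profiles for the host proteome (IUPred2A
long format, one disorder and one binding-propensity score per residue).

Matching is by **domain presence, not geometry**: domain coordinates on the
bacterial protein are retained as metadata but no positional relationship
between domain and motif is required — the two sit on different proteins.
Host proteins are never filtered by subcellular location, because vesicles
can engage both surface receptors and, after internalisation, cytoplasmic
proteins.

Motif scanning attempts the class regex at every start position, so
overlapping occurrences are all reported, and `$` anchors to the sequence
C-terminus (PDZ-binding motifs are the canonical end-anchored case). The
scanner uses Python `re`, which is leftmost-first rather than
POSIX-longest at a given start; for the character-class/fixed-repeat
patterns typical of motif classes the two semantics coincide.

A motif instance supports an interaction only if the span is disordered and
binding-competent:

* aggregated IUPred score over the span **> 0.5**, and
* aggregated ANCHOR2 score over the span **> 0.4**,

both strict. The aggregator is the arithmetic mean by default (robust to a
single noisy residue); `min` and `all` (every residue above both cutoffs)
are available for stricter analyses. Tightening either cutoff can only
remove edges — a property the test suite checks.

Unknown residues `X` are allowed in sequences and match only `.` or a
literal `X` in a pattern, never a character class such as `[ST]`.

## Expressed-gene calling

A gene is declared unexpressed in a cell population when its log2 mean
expression falls more than 3 standard deviations below the mean — the
Hart-style one-shot z-test. Implementation decisions:

* **Single pass.** "Mean of the expressed genes" is circular; statistics
  are computed once over all genes with nonzero mean raw expression. No
  iteration to convergence, so the call is deterministic.
* **Zeros.** Genes with zero mean are always unexpressed and are excluded
  from the mean/SD; an optional pseudocount (default 0) can re-include them.
* **Population SD** (divide by n). SD = 0 (all nonzero genes equal) means
  every nonzero gene is expressed rather than an error.
* **Boundary.** The two source rules ("less than μ−3σ fails" vs "above −3
  passes") disagree exactly at the boundary; equality counts as expressed
  on both the single-cell and the bulk route, and the policy is recorded in
  the context parameters.

A consequence of the population-SD choice worth knowing: a single outlier
among n genes can sit at most √(n−1) SDs from the mean, so with fewer than
11 genes no lone low gene can ever fail a z = −3 test. The synthetic
generator therefore plants a low-expression *fraction* below 10% of genes,
which makes the planted rejection mathematically reachable.

Single-cell matrices are assumed library-normalized upstream; the group
statistic is the raw per-group mean followed by log2. Bulk counts are first
normalized with median-of-ratios size factors (reference genes = nonzero in
every sample; factor = per-sample median of count / per-gene geometric
mean); when two bulk datasets are combined, analysis is restricted to genes
detected in both. The size-factor implementation is cross-checked against
pydeseq2 in the test suite.

## Context-specific interactomes

Predicted edges are restricted per (cell type, condition) to hosts whose
gene symbol is expressed there (host id → symbol mapping is identity unless
a mapping table is supplied; unmappable hosts are counted and excluded).
"Hub" has no standard quantitative definition, so the degree report flags a
bacterial protein as a hub when its host-degree reaches the 0.9 quantile of
bacterial degrees **or** an absolute floor of 100 targets, both
configurable, and always reports the raw degrees alongside. Convergent
targets (one host protein reached by ≥ 2 bacterial proteins, optionally all
sharing one functional label, e.g. helicases) get their own table.

## Enrichment

Annotations are propagated up the is_a hierarchy before testing, so a gene
annotated to a term counts for every ancestor. Per term with at least one
annotated target, p = P(X ≥ k) from the hypergeometric with N = expressed
background, K annotated background genes, n targets, k annotated targets.
This is a deliberate substitution: the original workflow used a ranked-list
tool, but with a fixed target set and a fixed background the fixed-set
hypergeometric is the faithful statistic. Multiple testing is
Benjamini–Hochberg per namespace over the terms actually tested (k ≥ 1);
enriched ⇔ p < 10⁻³ and q < 0.05. The background defaults to all expressed
genes of the context (annotated or not) — switching to annotated-only genes
is a config choice.

simRel between two terms of one namespace:

    sim(t1,t2) = max over common ancestors a of [2·IC(a)/(IC(t1)+IC(t2))]·(1−p(a))

with p(t) the propagated annotation frequency over the background and
IC = −ln p. Identical terms score 1−p(t); a root-only relationship scores 0
(IC(root) = 0). Redundancy reduction is a greedy pass over enriched terms by
ascending p: join the most similar existing representative if sim ≥ 0.7
(the conventional "medium" threshold), else open a new cluster; ties go to
the lexicographically smallest representative. Cross-context overlap is
reported as an exact Venn partition (2–6 sets) of enriched term ids.

## Pathway overlay

A pathway is supplied as member symbols (with optional layer labels:
receptor / adaptor / kinase / tf / other) and directed edges. Per cell
type, the two condition contexts classify each node as both / healthy-only
/ disease-only / absent; Δ = log2(disease) − log2(healthy) is reported only
for "both" nodes — single-condition nodes keep a categorical class rather
than an infinite or imputed Δ. An edge is present in a condition iff both
endpoints are expressed there (the stricter of the possible rules; recorded
in the output metadata). BEV-target flags come from the context-filtered
interactomes, so the same protein can be a target in one context and not
another; the receptor report additionally counts a receptor as a target of
a condition only where it is expressed.

## Synthetic data

The generator emulates each input at a deliberately small, desk-scale size
(defaults: 6 bacterial proteins, 12 hosts, 120 genes × 30 cells per group,
2 cell types × 2 conditions, 40 GO terms, a 10-member pathway):

* **Proteomes.** Host sequences are uniform over the 20 canonical residues
  with a background drawn ordered (scores U(0, cutoff−0.1)); planted motif
  witnesses are embedded with span scores U(cutoff+0.1, 1), decoys with
  ordered-span scores. The truth table is **finalized by the brute-force
  oracle** on the generated sequences, so incidental background matches are
  truth, not noise — planting intent never disagrees with the answer key.
* **Expression.** Negative binomial counts (dispersion 0.1) around per-gene
  log2 means U(6, 9); 10% of genes off (mean 0) and 5% planted ~14 log2
  units low per group; a TLR4-like receptor is on only in disease, one
  kinase only in health, and transcription-factor genes reuse the same
  draw in both conditions so their overlay Δ is exactly 0.
* **GO.** A random is_a tree of depth ≤ 3; one deepest term annotates a
  30-gene block from which target sets can be sampled preferentially.
* **Pathway.** Edges strictly layer-forward receptor→adaptor→kinase→TF.

What a green test on this world does *not* establish: realistic amino-acid
composition or motif base rates, scRNA-seq dropout/batch structure beyond
NB sampling, fidelity of any particular disorder predictor, or the edge
counts of any real proteome/transcriptome pairing.

## Numerics and determinism

All coordinates are 1-based inclusive and converted exactly once at reader
boundaries. Every writer sorts rows and uses fixed float formatting
(`%.6g` for reports; `%.17g` for intermediate context tables that are
reloaded by the cache, which must round-trip doubles exactly). The pipeline
manifest records thresholds, seed and input/output checksums but nothing
run-dependent, so reruns — fresh, cached, or regenerated from the same
seed — are byte-identical. All randomness flows through one integer seed;
stage caching reloads a stage's own outputs only when its input checksums
and parameters match.

## Known limitations

* Activation vs inhibition of a predicted interaction is not modelled; the
  pipeline says *that* a protein is reachable, not what the binding does.
* Only class regexes are scanned; curated motif instances are not used.
* The disorder gate is the only accessibility test — no additional check
  that a motif falls outside annotated globular domains.
* GO relationships other than is_a are ignored; the OBO reader accepts only
  the subset it documents.
* Expression is taken as a proxy for protein presence; post-transcriptional
  regulation is invisible to the model.
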