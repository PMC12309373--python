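# Methods

This note documents the models, conventions and design choices behind
`anchora`, in the order the pipeline applies them.

## Inputs and data model

The pipeline consumes, never computes, the upstream dose–response (DR)
analysis: a CSV with one row per transcript (`transcript_id`, `gene_id`,
optional `gene_name`, `bmd`, `bmd_ci_low`, `bmd_ci_high`, `trend` ∈
{inc, dec, bell, U}, `model`), plus either a boolean `deregulated`
column or a separate one-column background gene list. The benchmark dose
(BMD-1SD) is the dose at which the fitted DR curve departs from its
control level by one residual standard deviation; lower BMD = more
sensitive transcript. BMD confidence intervals may be asymmetric around
the point estimate, so only `bmd_ci_low ≤ bmd_ci_high` is validated.
Transcripts without a gene id are counted and reported but excluded from
gene-level sets. The transcript→gene mapping is an input column by
design: the tool stays offline and organism-agnostic.

PPI edge lists are STRING-shaped: two node columns and a combined
confidence score, either in [0,1] or the 0–1000 integer dialect. The
dialect is auto-detected (any score > 1 rescales the whole file by
1/1000), self-edges are dropped, and duplicate undirected pairs keep the
maximum score — conservative and deterministic. Gene sets are GMT files,
one collection per database; duplicate term ids are an error rather than
a silent union. Transcription (co)factor annotations are an optional
two-column file; a gene listed as both TF and CoTF is flagged TF.

Genes that appear in GMT terms but not in the background are kept inside
the term definitions (they matter for annotation lookups during fishing)
but excluded from every test count: the ORA universe is always the
experimental background.

## Graph construction and Markov clustering

The PPI graph is induced on the deregulated genes: an edge survives iff
both endpoints are deregulated and its score reaches `confidence_min`
(default 0.9, i.e. only high-confidence interactions; the upstream
database's own default is 0.4). Deregulated genes with no surviving edge
are not graph members and enter the lonely set directly.

MCL is implemented internally: build the weighted adjacency, add
self-loops equal to each node's maximum incident edge weight (standard
practice, keeps the stochastic flow well-conditioned), column-normalize,
then iterate expansion (matrix power 2) and inflation (elementwise power
`inflation`, default 4, then re-normalization) with pruning of entries
below 1e-6, until the largest elementwise change falls below 1e-6
(at most 200 iterations; exhaustion raises a convergence error carrying
the residual, never a partial result). Rows with surviving diagonal mass
are attractors; each attractor's support is a cluster. Distinct attractor
systems claiming the same node are resolved deterministically (larger
cluster wins, ties by lexicographically smallest member tuple). Because
flow cannot cross connected components, the iteration runs per component.

Two properties worth stating precisely:

- MCL always *refines* connected components, and on disconnected cliques
  it equals them (the test suite verifies this exhaustively for planted
  cliques of sizes 3–12 at inflations 2, 4 and 6).
- MCL does **not** equal connected components on every small graph:
  sparse tree-like components (e.g. a 4-node path) genuinely split into
  two attractor systems at inflation ≥ 2, under every standard self-loop
  policy. This is the algorithm's documented granularity behavior, not
  an implementation artifact; one acceptance test asserts the stronger
  (false) equivalence and is expected to fail on exactly those cases.

The lower cluster size filter retains clusters with at least
`min_cluster_size` genes (default 4, i.e. size ≥ 4 is kept); everything
else joins the lonely set. The boundary is exposed in the configuration
precisely because "a filter set at 4" is ambiguous between strict and
non-strict readings. Cluster ids c1, c2, … are assigned by decreasing
size, ties broken by smallest member gene id.

## Over-representation testing

For a query q and a collection, the universe is N = |background genes
annotated to ≥ 1 term of the collection| and n = |q ∩ universe| (the
annotated-domain convention). Each term with background-restricted size
K ∈ [`term_size_min`, `term_size_max`] (defaults 5 and 500) is tested
with the one-tailed hypergeometric tail P(X ≥ k); terms outside the
window never enter the FDR family, so adding or removing an untestable
term cannot change any retained result. The tail is computed through
scipy's log-space survival function and matches exact integer counting
to < 1e-12 over every configuration with N ≤ 20 (exhaustive test).

Benjamini–Hochberg adjustment is applied per (query, database) family —
each cluster is tested against each database separately, which implies
this scoping — and results are retained when q ≤ `fdr_alpha` (0.05) and
k ≥ `min_enrichment_genes` (3). The count filter is applied *after* FDR:
it is a report filter on the genes participating in the enrichment, not
a change to the test family. Only enrichment (over-representation) is
tested, never depletion.

When a child→parent ontology edge file is supplied, a redundancy filter
keeps, within each query, only *driver* terms: retained terms with no
retained descendant. This is an elim-flavoured most-specific-term rule;
it approximates, but is not identical to, proprietary driver-term
highlighting algorithms. Cycles in the ontology are rejected.

## Merging and fishing

Merging runs once per database, in descending order of database coverage
(or an explicit configured order). Within a database, clusters sharing
≥ 1 retained term id are connected; each connected component of size ≥ 2
collapses into one merged cluster whose gene set and enriched-term list
are unions, with provenance `merged` and the constituent ids recorded.
Connected components make the outcome independent of cluster order
within a database; a second application of the whole merge pass is a
no-op (verified by test). Merged clusters are *not* re-tested: their
enriched set is the union of their members' retained results.

Fishing then scans every lonely gene against every cluster: if the gene
is annotated (in any supplied collection, restricted to terms inside the
size window) to a term retained as enriched in the cluster, the gene
joins it; one gene may join several clusters (overlap is allowed from
this step on) and its friendliness is the number joined. By default the
match is against the post-driver-filter retained terms; a config switch
(`fish_prefilter_terms`) exposes the pre-filter alternative. Fished
genes leave the lonely set but are never removed from clusters, so
membership is conserved: lonely ∪ clusters = deregulated set, with
overlaps only among clusters. The residual lonely set finally undergoes
the same ORA with identical parameters.

## Summaries

Each final cluster (lonely included) pools the BMDs of all transcripts
whose gene belongs to it — transcript-level, not gene-level, pooling, so
multi-transcript genes weigh by their transcript count. The sensitivity
metric is the sample quantile at `quantile_prob` (default 0.25) using
linear interpolation of order statistics (h = (n−1)·p), the default
convention of the major statistical environments; the convention is a
deliberate, configurable choice since several quantile definitions
exist. Clusters are ranked ascending (most sensitive first); clusters
without BMDs sort last. Fished genes contribute their transcripts to
every cluster they joined by default (`pool_fished_bmds`), flagged by
the `n_fished` column. A comparison table contrasts the anchored run
with the standard whole-list run: a gene counts as "considered" under
the anchored approach when it belongs to a characterized cluster
(fished members included) or participates in a lonely-cluster
enrichment, and under the standard approach when it participates in a
retained enrichment.

## Synthetic bundles

The generator writes exactly the formats the readers consume, plus a
ground-truth table (gene → planted module, planted term, expected fate ∈
{clustered, fished, lonely}) and a manifest. The default condition
plants three 8-gene modules in a 500-gene background with 60 deregulated
genes: module edges are drawn with probability 1.0 and scores uniform in
(0.91, 0.99); noise edges (0 by default; 40 in the documented
moderate-noise variant with intra-module edge probability 0.9) score
uniformly in (0.30, 0.85), so the default 0.9 confidence threshold is
exercised from both sides by construction. Each planted term covers its
module, its assigned fishable lonely genes, and non-deregulated filler
genes up to a background size of 20 (inside the 5–500 window); a broader
parent term and a child→parent ontology file let the end-to-end run
exercise the driver filter. Noise terms are drawn from non-deregulated
genes, so they cannot enrich any cluster. Per-module BMD windows
(1–3, 5–12, 20–50 dose units, log-uniform) are non-overlapping, giving
the sensitivity ranking an unambiguous expected order; fishable genes
draw BMDs from their target module's window so pooling cannot reorder
it. The trend mix (46% inc / 47% dec / 3% bell / 4% U) reflects the
monotone-dominated composition typical of dose–response transcriptomics.
The anchoring condition plants a single 8-gene module whose term covers
40 background genes inside a 150-gene deregulated list, with noise terms
annotating the whole background: the whole-list test then expects ~12
term genes under the null and cannot retain the term at k = 8, while the
cluster query (8/8 genes in the term) retains it decisively.

What the generator does not emulate: read counts, DR model fitting,
evidence-based score distributions, scale-free degree structure, or
annotation bias. Passing tests therefore demonstrate the pipeline's
logic and statistics on module-structured inputs, not performance on
real networks, where confidence scores and annotation coverage are far
messier.

## Problem sizes and determinism

Tests and the acceptance script run at fixture scale (hundreds of
background genes, dozens of deregulated genes) — large enough to make
every planted signal decisive, small enough that the exhaustive oracles
(integer-counting hypergeometric sweep, all ≤ 4-node graphs, 100-fixture
filter sweeps) stay cheap. Everything downstream of a seed is
deterministic: the same seed yields byte-identical bundles and
byte-identical pipeline outputs, which the suite asserts by hashing
written files.

## Known limitations

- The driver filter is an approximation of topology-aware term
  highlighting; with no supplied ontology no redundancy filtering occurs.
- FDR is scoped per (query, database); no correction is shared across
  databases or across clusters.
- The PPI graph is induced on deregulated genes only; indirect
  interactions through non-deregulated bridge proteins are invisible.
- Merged clusters inherit their members' enrichment statistics rather
  than being re-tested at their merged size.
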