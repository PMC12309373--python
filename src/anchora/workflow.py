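"""Pipeline orchestration: cluster-wise ORA, merging, fishing, lonely ORA.

The full run is: build the confidence-thresholded PPI graph over the
deregulated genes, partition it with MCL, drop under-sized clusters into
the lonely set, anchor one ORA per (cluster, database), optionally apply
the ontology driver filter, merge clusters that share retained terms
(per database, in descending coverage order), fish lonely genes into
clusters through shared annotations, and finally run ORA on the residual
lonely set. The standard whole-list ORA is available separately for
comparison.
"""
from __future__ import annotations

import logging
import re

from .enrichment import driver_filter, ora_query
from .model import (
    Cluster,
    Clustering,
    FishingRecord,
    GeneLists,
    PipelineConfig,
    PipelineResult,
)
from .network import build_graph, mcl_cluster, partition_and_filter

log = logging.getLogger(__name__)

__all__ = [
    "merge_clusters",
    "fish_lonely",
    "run_pipeline",
    "run_standard",
    "compare_approaches",
    "db_sequence",
]


def db_sequence(collections, cfg: PipelineConfig) -> list:
    """Merge order over databases: explicit config order, or descending
    coverage (number of background genes annotated in the database)."""
    by_name = {c.db_name: c for c in collections}
    if cfg.db_order is not None:
        missing = [d for d in cfg.db_order if d not in by_name]
        if missing:
            raise ValueError(f"db_order names unknown databases: {missing}")
        return [by_name[d] for d in cfg.db_order]
    return sorted(collections, key=lambda c: (-c.coverage, c.db_name))


def _id_key(cluster_id: str):
    """Natural ordering for cluster ids: numeric suffix, then the string."""
    m = re.search(r"(\d+)$", cluster_id)
    return (int(m.group(1)) if m else 0, cluster_id)


def merge_clusters(
    clustering: Clustering, collections, cfg: PipelineConfig
) -> Clustering:
    """Merge clusters sharing at least one retained enriched term.

    Processed one database at a time (descending coverage or explicit
    order). Within a database, sharing is transitive: connected components
    of the term-sharing graph collapse into one merged cluster whose genes
    and enriched terms are unions. Merged clusters are not re-tested; the
    next database sees the updated clustering.
    """
    current = list(clustering.clusters)
    for coll in db_sequence(collections, cfg):
        db = coll.db_name
        n = len(current)
        # union-find over clusters sharing a term id of this database
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        term_owner = {}
        for i, c in enumerate(current):
            for _, t in c.enriched_terms(db):
                if t in term_owner:
                    a, b = find(term_owner[t]), find(i)
                    if a != b:
                        parent[max(a, b)] = min(a, b)
                else:
                    term_owner[t] = i
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)

        merged = []
        for members in groups.values():
            if len(members) == 1:
                merged.append(current[members[0]])
                continue
            parts = [current[i] for i in members]
            parts.sort(key=lambda c: _id_key(c.cluster_id))
            genes = frozenset().union(*(c.genes for c in parts))
            enriched = [r for c in parts for r in c.enriched]
            merged.append(
                Cluster(
                    cluster_id="m" + parts[0].cluster_id,
                    genes=genes,
                    provenance="merged",
                    enriched=enriched,
                    merged_from=[c.cluster_id for c in parts],
                )
            )
            log.info(
                "merged %s on shared %s terms -> %s",
                [c.cluster_id for c in parts], db, "m" + parts[0].cluster_id,
            )
        merged.sort(key=lambda c: _id_key(c.cluster_id))
        current = merged
    return Clustering(clusters=current, lonely=clustering.lonely)


def _annotation_index(collections, cfg: PipelineConfig) -> dict:
    """gene -> set of (db, term_id) pairs, restricted to terms eligible for
    enrichment (inside the size window)."""
    index = {}
    for coll in collections:
        for t in coll.sized_terms(cfg.term_size_min, cfg.term_size_max):
            for g in coll.genes_of(t):
                index.setdefault(g, set()).add((coll.db_name, t))
    return index


def fish_lonely(clustering: Clustering, collections, cfg: PipelineConfig):
    """Incorporate lonely genes into clusters through shared annotations.

    A lonely gene joins every cluster in which at least one of the gene's
    eligible term annotations is retained as enriched; from this step on
    clusters may overlap. Returns the expanded clustering and one
    FishingRecord per fished gene (friendliness = number of clusters
    joined).
    """
    index = _annotation_index(collections, cfg)
    cluster_terms = {
        c.cluster_id: c.enriched_terms() for c in clustering.clusters
    }
    additions = {c.cluster_id: set() for c in clustering.clusters}
    records = []
    for g in sorted(clustering.lonely):
        annots = index.get(g, set())
        if not annots:
            continue
        joined = []
        via = {}
        for c in clustering.clusters:
            shared = annots & cluster_terms[c.cluster_id]
            if shared:
                joined.append(c.cluster_id)
                via[c.cluster_id] = {t for _, t in shared}
        if joined:
            for cid in joined:
                additions[cid].add(g)
            records.append(
                FishingRecord(gene_id=g, joined_clusters=joined, via_terms=via)
            )
    fished = {r.gene_id for r in records}
    clusters = []
    for c in clustering.clusters:
        extra = additions[c.cluster_id]
        if extra:
            clusters.append(
                Cluster(
                    cluster_id=c.cluster_id,
                    genes=c.genes | extra,
                    provenance="expanded",
                    enriched=c.enriched,
                    merged_from=[],
                )
            )
        else:
            clusters.append(c)
    log.info(
        "fishing: %d genes joined clusters, %d remain lonely",
        len(fished), len(clustering.lonely) - len(fished),
    )
    return (
        Clustering(clusters=clusters, lonely=clustering.lonely - fished),
        records,
    )


def run_pipeline(
    lists: GeneLists,
    edges,
    collections,
    cfg: PipelineConfig,
    ontology_edges=None,
) -> PipelineResult:
    """Execute the full cluster-anchored workflow."""
    logbook = []

    def note(step, **counts):
        logbook.append({"step": step, **counts})
        log.info("%s: %s", step, counts)

    if not lists.deregulated:
        note("short_circuit", reason="empty deregulated list")
        return PipelineResult(
            clustering=Clustering(clusters=[], lonely=frozenset()),
            enrichments=[],
            fishing=[],
            config=cfg,
            log=logbook,
        )

    graph = build_graph(lists, edges, cfg)
    note("build_graph", nodes=graph.number_of_nodes(), edges=graph.number_of_edges())

    partition = mcl_cluster(graph, cfg)
    note("mcl_cluster", cells=len(partition))

    clustering = partition_and_filter(lists, partition, cfg)
    note(
        "size_filter",
        clusters=len(clustering.clusters),
        lonely=len(clustering.lonely),
    )

    enrichments = []
    for cluster in clustering.clusters:
        results = []
        for coll in collections:
            results.extend(
                ora_query(cluster.genes, coll, lists, cfg, cluster.cluster_id)
            )
        if ontology_edges:
            results = driver_filter(results, ontology_edges)
        cluster.enriched = results
        enrichments.extend(results)
    note(
        "cluster_ora",
        retained_results=len(enrichments),
        characterized_clusters=sum(1 for c in clustering.clusters if c.enriched),
    )

    clustering = merge_clusters(clustering, collections, cfg)
    note("merge", clusters=len(clustering.clusters))

    clustering, fishing = fish_lonely(clustering, collections, cfg)
    note(
        "fishing",
        fished=len(fishing),
        lonely=len(clustering.lonely),
        expanded=sum(1 for c in clustering.clusters if c.provenance == "expanded"),
    )

    lonely_results = []
    for coll in collections:
        lonely_results.extend(
            ora_query(clustering.lonely, coll, lists, cfg, "lonely")
        )
    if ontology_edges:
        lonely_results = driver_filter(lonely_results, ontology_edges)
    note("lonely_ora", retained_results=len(lonely_results))

    all_results = [r for c in clustering.clusters for r in c.enriched]
    # de-duplicate results shared between merged members' unions
    seen = set()
    unique = []
    for r in all_results + lonely_results:
        key = (r.query_id, r.db_name, r.term_id)
        if key not in seen:
            seen.add(key)
            unique.append(r)
    return PipelineResult(
        clustering=clustering,
        enrichments=unique,
        fishing=fishing,
        config=cfg,
        log=logbook,
    )


def run_standard(lists: GeneLists, collections, cfg: PipelineConfig,
                 ontology_edges=None) -> list:
    """Whole-list ORA with the same parameters (query_id 'standard')."""
    results = []
    for coll in collections:
        results.extend(
            ora_query(lists.deregulated, coll, lists, cfg, "standard")
        )
    if ontology_edges:
        results = driver_filter(results, ontology_edges)
    return results


def enriched_genes(results) -> frozenset:
    """Genes participating in at least one retained enrichment."""
    out = set()
    for r in results:
        out |= r.intersection
    return frozenset(out)


def compare_approaches(result: PipelineResult, standard_results, lists: GeneLists) -> dict:
    """Gene- and term-level overlap between the anchored and standard runs.

    Mirrors the usual Venn comparison: which deregulated genes are
    considered for interpretation under each approach, and which terms
    each approach retains per database. For the anchored run a gene is
    considered when it belongs to a cluster with at least one retained
    enrichment (fished members included) or participates in a lonely-
    cluster enrichment; for the standard run, when it participates in at
    least one retained enrichment.
    """
    anchored_genes = set()
    for c in result.clustering.clusters:
        if c.enriched:
            anchored_genes |= c.genes
    anchored_genes |= enriched_genes(
        [r for r in result.enrichments if r.query_id == "lonely"]
    )
    anchored_genes = frozenset(anchored_genes)
    standard_genes = enriched_genes(standard_results)
    anchored_terms = {(r.db_name, r.term_id) for r in result.enrichments}
    standard_terms = {(r.db_name, r.term_id) for r in standard_results}
    dereg = lists.deregulated
    return {
        "n_deregulated": len(dereg),
        "genes_anchored": len(anchored_genes),
        "genes_standard": len(standard_genes),
        "genes_both": len(anchored_genes & standard_genes),
        "genes_only_anchored": len(anchored_genes - standard_genes),
        "genes_only_standard": len(standard_genes - anchored_genes),
        "genes_neither": len(dereg - anchored_genes - standard_genes),
        "terms_anchored": len(anchored_terms),
        "terms_standard": len(standard_terms),
        "terms_both": len(anchored_terms & standard_terms),
        "terms_only_anchored": len(anchored_terms - standard_terms),
        "terms_only_standard": len(standard_terms - anchored_terms),
    }
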