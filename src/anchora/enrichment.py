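"""Over-representation testing with FDR control and the three filters.

The test universe N for a collection is the set of background genes
annotated to at least one of its terms (the "annotated" domain), matching
an ORA run against a background of annotated protein-coding genes. Terms
are only tested when their background-restricted size lies inside the
biological-function size window, so the FDR family never contains
untestable terms; the enrichment gene count filter is applied after FDR
as a report filter and does not shrink the family.
"""
from __future__ import annotations

import logging

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputFormatError
from .model import EnrichmentResult, GeneLists, GeneSetCollection, PipelineConfig

log = logging.getLogger(__name__)

__all__ = ["hypergeom_p", "bh_adjust", "ora_query", "driver_filter"]


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """One-tailed enrichment p-value P(X >= k), X ~ Hypergeometric(N, K, n).

    Of N universe genes, K belong to the term; the query draws n genes and
    hits k of them. Computed through the log-space survival function of the
    hypergeometric distribution for numerical stability.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"invalid hypergeometric configuration k={k} n={n} K={K} N={N}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the tail via logpmf internally
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora_query(
    query,
    collection: GeneSetCollection,
    lists: GeneLists,
    cfg: PipelineConfig,
    query_id: str,
) -> list:
    """Test one query gene set against one collection; return retained results.

    Retained results satisfy all three filters: term size within
    [term_size_min, term_size_max] (enforced before testing), BH-adjusted
    q <= fdr_alpha, and overlap >= min_enrichment_genes (applied after FDR).
    """
    query = frozenset(query)
    if not query <= lists.background:
        raise ValueError(f"query {query_id!r} is not a subset of the background")
    universe = collection.universe
    q = query & universe
    if not query:
        log.info("query %r is empty; no tests run", query_id)
        return []
    term_ids = collection.sized_terms(cfg.term_size_min, cfg.term_size_max)
    if not term_ids:
        return []
    n = len(q)
    N = collection.coverage
    rows = []
    for t in term_ids:
        genes = collection.genes_of(t) & universe
        inter = q & genes
        rows.append((t, inter, len(inter), len(genes)))
    pvals = [hypergeom_p(k, n, K, N) for _, _, k, K in rows]
    qvals = bh_adjust(pvals)
    out = []
    for (t, inter, k, K), p, qv in zip(rows, pvals, qvals):
        if qv <= cfg.fdr_alpha and k >= cfg.min_enrichment_genes:
            out.append(
                EnrichmentResult(
                    query_id=query_id,
                    db_name=collection.db_name,
                    term_id=t,
                    term_name=collection.term_name(t),
                    p_raw=p,
                    q_fdr=float(qv),
                    k_overlap=k,
                    n_query=n,
                    K_term_bg=K,
                    N_background=N,
                    intersection=inter,
                )
            )
    out.sort(key=lambda r: (r.q_fdr, r.p_raw, r.term_id))
    return out


def driver_filter(results, ontology_edges) -> list:
    """Keep only the most specific retained term along each ancestry chain.

    ``ontology_edges`` are (child, parent) pairs forming a DAG. Within each
    query's retained results, a term with a retained descendant (a more
    specific retained term) is marked non-driver and removed. Terms absent
    from the ontology are untouched. Redundancy filtering of this kind keeps
    the deepest representative of each enriched branch of the hierarchy.
    """
    dag = nx.DiGraph()
    dag.add_edges_from(ontology_edges)  # edge child -> parent
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise InputFormatError(f"ontology contains a cycle: {cycle}")

    by_query = {}
    for r in results:
        by_query.setdefault(r.query_id, []).append(r)

    kept = []
    for rs in by_query.values():
        retained_ids = {r.term_id for r in rs}
        for r in rs:
            if r.term_id in dag:
                # descendants in the ontology = nodes with a path to r.term_id
                descendants = nx.ancestors(dag, r.term_id)
                r.driver = not (descendants & retained_ids)
            else:
                r.driver = True
            if r.driver:
                kept.append(r)
    return kept
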