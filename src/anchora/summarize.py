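"""Per-cluster dose-response summaries and the sensitivity ranking.

Each final cluster (including the residual lonely cluster) is summarized
by pooling the BMDs of all transcripts whose gene belongs to the cluster;
the 25th-percentile BMD orders clusters from most to least sensitive.
Trend composition and regulator counts come along for interpretation.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .model import ClusterSummary, GeneLists, PipelineConfig, PipelineResult, TREND_LABELS

__all__ = ["cluster_bmd_quantile", "build_summary", "summary_frame"]


def cluster_bmd_quantile(bmds, prob: float) -> Optional[float]:
    """Linear-interpolation sample quantile of a BMD list.

    Uses the order-statistic convention h = (n-1)*prob with linear
    interpolation between the bracketing order statistics (the default of
    the major statistical environments). Empty input returns None and the
    caller renders NA.
    """
    arr = np.asarray(list(bmds), dtype=float)
    if arr.size == 0:
        return None
    return float(np.quantile(arr, prob))


def build_summary(
    result: PipelineResult,
    lists: GeneLists,
    cfg: PipelineConfig,
) -> list:
    """One ClusterSummary per final cluster, most sensitive first.

    Fished genes contribute their transcripts to every cluster they joined
    (when ``cfg.pool_fished_bmds``); the lonely cluster appears as its own
    row. Clusters without any BMD sort last.
    """
    fished = {r.gene_id for r in result.fishing}
    by_gene = {}
    for t in lists.transcripts:
        if t.gene_id is not None:
            by_gene.setdefault(t.gene_id, []).append(t)

    pre_fishing = {}
    if not cfg.pool_fished_bmds:
        for c in result.clustering.clusters:
            pre_fishing[c.cluster_id] = c.genes - fished

    rows = []
    entries = [(c.cluster_id, c.provenance, c.genes, c.enriched)
               for c in result.clustering.clusters]
    entries.append(("lonely", "lonely", result.clustering.lonely, []))
    for cid, prov, genes, enriched in entries:
        pool = genes if cfg.pool_fished_bmds else pre_fishing.get(cid, genes)
        transcripts = [t for g in sorted(pool) for t in by_gene.get(g, [])]
        bmds = sorted(t.bmd for t in transcripts if t.bmd is not None)
        trend_counts = {lab: 0 for lab in TREND_LABELS}
        for t in transcripts:
            if t.trend is not None:
                trend_counts[t.trend] += 1
        regulators = {
            t.gene_id for t in transcripts if t.regulator in ("TF", "CoTF")
        }
        terms = sorted(
            {(r.db_name, r.term_id, r.term_name) for r in enriched}
        )
        rows.append(
            ClusterSummary(
                cluster_id=cid,
                provenance=prov,
                n_genes=len(genes),
                n_transcripts=len(transcripts),
                bmd_q25=cluster_bmd_quantile(bmds, cfg.quantile_prob),
                bmd_values=bmds,
                trend_counts=trend_counts,
                n_regulators=len(regulators),
                n_fished=len(genes & fished),
                enriched_terms=terms,
            )
        )
    rows.sort(
        key=lambda s: (
            s.bmd_q25 is None,
            s.bmd_q25 if s.bmd_q25 is not None else 0.0,
            s.cluster_id,
        )
    )
    return rows


def summary_frame(summaries) -> pd.DataFrame:
    """Tabular view of the summaries (one row per cluster)."""
    return pd.DataFrame(
        {
            "cluster_id": [s.cluster_id for s in summaries],
            "provenance": [s.provenance for s in summaries],
            "n_genes": [s.n_genes for s in summaries],
            "n_transcripts": [s.n_transcripts for s in summaries],
            "bmd_q25": [s.bmd_q25 for s in summaries],
            **{
                lab: [s.trend_counts.get(lab, 0) for s in summaries]
                for lab in TREND_LABELS
            },
            "n_regulators": [s.n_regulators for s in summaries],
            "n_fished": [s.n_fished for s in summaries],
            "n_enriched_terms": [len(s.enriched_terms) for s in summaries],
        }
    )
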