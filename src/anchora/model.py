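"""Shared data model of the pipeline.

The pipeline moves four kinds of objects between stages: gene lists with
their per-transcript dose-response metrics, gene-set collections sized
against the experimental background, clusters of the protein-protein
interaction (PPI) network, and enrichment test results. All of them are
plain dataclasses so that results serialize deterministically.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConfigError, ConsistencyError

TREND_LABELS = ("inc", "dec", "bell", "U")
REGULATOR_CLASSES = ("TF", "CoTF")

__all__ = [
    "TREND_LABELS",
    "REGULATOR_CLASSES",
    "TranscriptRecord",
    "GeneLists",
    "GeneSetCollection",
    "PipelineConfig",
    "Cluster",
    "Clustering",
    "EnrichmentResult",
    "FishingRecord",
    "PipelineResult",
    "ClusterSummary",
]


@dataclass
class TranscriptRecord:
    """One deregulated transcript with its gene mapping and DR metrics.

    ``bmd`` is the benchmark dose (BMD-1SD): the dose at which the modelled
    dose-response departs from the control level by one residual standard
    deviation. Lower values mean a more sensitive transcript. The confidence
    interval may be asymmetric around the point estimate, so only
    ``bmd_ci_low <= bmd_ci_high`` is enforced, not containment of ``bmd``.
    """

    transcript_id: str
    gene_id: Optional[str]
    gene_name: Optional[str] = None
    bmd: Optional[float] = None
    bmd_ci_low: Optional[float] = None
    bmd_ci_high: Optional[float] = None
    trend: Optional[str] = None
    model: Optional[str] = None
    regulator: str = "none"

    def __post_init__(self) -> None:
        if self.trend is not None and self.trend not in TREND_LABELS:
            raise ConsistencyError(
                f"transcript {self.transcript_id!r}: trend {self.trend!r} "
                f"not one of {list(TREND_LABELS)}"
            )
        if self.regulator not in REGULATOR_CLASSES + ("none",):
            raise ConsistencyError(
                f"transcript {self.transcript_id!r}: regulator class "
                f"{self.regulator!r} not one of {list(REGULATOR_CLASSES)} or 'none'"
            )
        if (
            self.bmd_ci_low is not None
            and self.bmd_ci_high is not None
            and self.bmd_ci_low > self.bmd_ci_high
        ):
            raise ConsistencyError(
                f"transcript {self.transcript_id!r}: bmd_ci_low > bmd_ci_high"
            )


@dataclass
class GeneLists:
    """Background and deregulated gene sets plus transcript-level records.

    ``deregulated`` must be a subset of ``background`` (the ORA universe is
    always the experimental background). ``n_unmapped`` counts transcripts
    that carried no gene id and were dropped from the gene-level sets.
    """

    background: frozenset
    deregulated: frozenset
    transcripts: list = field(default_factory=list)
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        self.background = frozenset(self.background)
        self.deregulated = frozenset(self.deregulated)
        if not self.deregulated <= self.background:
            extra = sorted(self.deregulated - self.background)[:5]
            raise ConsistencyError(
                f"deregulated genes absent from background: {extra} ..."
            )
        for rec in self.transcripts:
            if rec.bmd is not None and rec.gene_id is not None:
                if rec.gene_id not in self.deregulated:
                    raise ConsistencyError(
                        f"transcript {rec.transcript_id!r} carries a BMD but "
                        f"gene {rec.gene_id!r} is not deregulated"
                    )

    def transcripts_for(self, genes: Iterable[str]) -> list:
        genes = set(genes)
        return [t for t in self.transcripts if t.gene_id in genes]


class GeneSetCollection:
    """One database's term -> gene-set mapping sized against the background.

    ``bg_sizes[t]`` is the number of term genes present in the background;
    ``coverage`` is the number of background genes annotated to at least one
    term of the collection (the ORA universe size N for this database).
    Genes never seen in the background are retained in ``terms`` — they are
    needed for annotation lookups during lonely-gene fishing — but excluded
    from every test count.
    """

    def __init__(self, db_name: str, terms: Mapping[str, tuple], background: Iterable[str]):
        self.db_name = db_name
        # term_id -> (term_name, frozenset of genes), insertion order preserved
        self.terms = {t: (name, frozenset(genes)) for t, (name, genes) in terms.items()}
        bg = frozenset(background)
        self.bg_sizes = {t: len(g & bg) for t, (_, g) in self.terms.items()}
        universe = set()
        for _, genes in self.terms.values():
            universe |= genes & bg
        self.universe = frozenset(universe)

    @property
    def coverage(self) -> int:
        return len(self.universe)

    def term_name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def genes_of(self, term_id: str) -> frozenset:
        return self.terms[term_id][1]

    def sized_terms(self, lo: int, hi: int) -> list:
        """Term ids whose background-restricted size lies in [lo, hi]."""
        return [t for t, s in self.bg_sizes.items() if lo <= s <= hi]

    def __len__(self) -> int:
        return len(self.terms)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GeneSetCollection({self.db_name!r}, {len(self.terms)} terms, "
            f"coverage={self.coverage})"
        )


@dataclass
class PipelineConfig:
    """Every threshold of the workflow, with the published defaults.

    confidence_min: minimum STRING-style combined confidence for a PPI edge
        (probability the interaction exists). 0.9 keeps only high-confidence
        interactions; the upstream database's own default is 0.4.
    inflation: MCL inflation; larger values give more, smaller clusters.
    min_cluster_size: lower cluster size filter — clusters with fewer genes
        than this are dissolved into the lonely set.
    fdr_alpha: Benjamini-Hochberg significance limit per (query, database).
    term_size_min/max: biological function size filter on the background-
        restricted term size; terms outside the window are never tested.
    min_enrichment_genes: enrichment gene count filter, applied after FDR.
    db_order: None for descending-coverage merge order, or an explicit list
        of database names.
    quantile_prob: probability for the per-cluster BMD sensitivity quantile.
    fish_prefilter_terms: when True, fishing matches lonely-gene annotations
        against clusters' pre-driver-filter enriched terms instead of the
        retained (post-filter) ones.
    pool_fished_bmds: when True, fished genes contribute their transcripts'
        BMDs to every cluster they joined.
    """

    confidence_min: float = 0.9
    inflation: float = 4.0
    min_cluster_size: int = 4
    fdr_alpha: float = 0.05
    term_size_min: int = 5
    term_size_max: int = 500
    min_enrichment_genes: int = 3
    db_order: Optional[Sequence[str]] = None
    quantile_prob: float = 0.25
    seed: int = 0
    mcl_expansion: int = 2
    mcl_prune: float = 1e-6
    mcl_tol: float = 1e-6
    mcl_max_iter: int = 200
    fish_prefilter_terms: bool = False
    pool_fished_bmds: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_min <= 1.0:
            raise ConfigError("confidence_min must lie in [0, 1]")
        if self.inflation <= 1.0:
            raise ConfigError("inflation must be > 1")
        if self.min_cluster_size < 1:
            raise ConfigError("min_cluster_size must be >= 1")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ConfigError("fdr_alpha must lie in (0, 1)")
        if self.term_size_min < 1 or self.term_size_max < 1:
            raise ConfigError("term size limits must be strictly positive")
        if self.term_size_min > self.term_size_max:
            raise ConfigError("term_size_min must be <= term_size_max")
        if self.min_enrichment_genes < 1:
            raise ConfigError("min_enrichment_genes must be >= 1")
        if not 0.0 < self.quantile_prob < 1.0:
            raise ConfigError("quantile_prob must lie in (0, 1)")
        if self.mcl_expansion < 2:
            raise ConfigError("mcl_expansion must be >= 2")
        if self.mcl_max_iter < 1:
            raise ConfigError("mcl_max_iter must be >= 1")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


@dataclass
class EnrichmentResult:
    """One (query, term) over-representation test.

    k_overlap of n_query query genes hit a term covering K_term_bg of the
    N_background annotated background genes; p_raw is the one-tailed
    hypergeometric tail P(X >= k) and q_fdr its BH-adjusted value within the
    (query, database) family.
    """

    query_id: str
    db_name: str
    term_id: str
    term_name: str
    p_raw: float
    q_fdr: float
    k_overlap: int
    n_query: int
    K_term_bg: int
    N_background: int
    intersection: frozenset
    driver: bool = True


@dataclass
class Cluster:
    """A named gene group with provenance and its enriched functions."""

    cluster_id: str
    genes: frozenset
    provenance: str = "mcl"  # mcl | merged | expanded | lonely
    enriched: list = field(default_factory=list)
    merged_from: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ConsistencyError(f"cluster {self.cluster_id!r} has no genes")
        if (self.provenance == "merged") != bool(self.merged_from):
            raise ConsistencyError(
                f"cluster {self.cluster_id!r}: merged_from must be non-empty "
                "iff provenance is 'merged'"
            )

    def enriched_terms(self, db_name: Optional[str] = None) -> set:
        """Set of (db_name, term_id) pairs retained for this cluster."""
        return {
            (r.db_name, r.term_id)
            for r in self.enriched
            if db_name is None or r.db_name == db_name
        }

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class Clustering:
    """Retained clusters plus the lonely gene set."""

    clusters: list
    lonely: frozenset

    def __post_init__(self) -> None:
        self.lonely = frozenset(self.lonely)

    def members(self) -> frozenset:
        out = set(self.lonely)
        for c in self.clusters:
            out |= c.genes
        return frozenset(out)

    def by_id(self, cluster_id: str) -> Cluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)


@dataclass
class FishingRecord:
    """One lonely gene recovered into clusters through shared annotations."""

    gene_id: str
    joined_clusters: list
    via_terms: dict  # cluster id -> set of term ids

    @property
    def friendliness(self) -> int:
        return len(self.joined_clusters)


@dataclass
class PipelineResult:
    """Everything the full pipeline produced, plus a provenance log."""

    clustering: Clustering
    enrichments: list
    fishing: list
    config: PipelineConfig
    log: list = field(default_factory=list)


@dataclass
class ClusterSummary:
    """Per-cluster dose-response summary row."""

    cluster_id: str
    provenance: str
    n_genes: int
    n_transcripts: int
    bmd_q25: Optional[float]
    bmd_values: list
    trend_counts: dict
    n_regulators: int
    n_fished: int
    enriched_terms: list  # (db, term_id, term_name)
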