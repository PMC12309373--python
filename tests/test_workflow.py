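"""Merging, fishing, and end-to-end pipeline orchestration."""
import pytest

from anchora import (
    Cluster,
    Clustering,
    FixtureSpec,
    PipelineConfig,
    compare_approaches,
    fish_lonely,
    generate_fixture,
    merge_clusters,
    read_bundle,
    run_pipeline,
    run_standard,
)
from anchora.model import EnrichmentResult
from anchora.workflow import db_sequence, enriched_genes

from conftest import make_collection, make_lists


def res(query, term, db="db"):
    return EnrichmentResult(
        query_id=query, db_name=db, term_id=term, term_name=term,
        p_raw=1e-4, q_fdr=1e-3, k_overlap=3, n_query=4, K_term_bg=10,
        N_background=100, intersection=frozenset({"x", "y", "z"}),
    )


def cluster(cid, genes, terms, db="db"):
    return Cluster(
        cluster_id=cid, genes=frozenset(genes), provenance="mcl",
        enriched=[res(cid, t, db) for t in terms],
    )


def one_db_collection(background=("x",)):
    return make_collection("db", {"F1": {"x"}, "F2": {"y"}}, background)


class TestMergeClusters:
    def make(self, spec):
        return Clustering(
            clusters=[cluster(cid, genes, terms) for cid, genes, terms in spec],
            lonely=frozenset(),
        )

    def test_direct_sharing(self, default_cfg):
        cl = self.make([
            ("c1", "ab", ["F1"]), ("c2", "cd", ["F1"]), ("c3", "ef", ["F2"]),
        ])
        out = merge_clusters(cl, [one_db_collection()], default_cfg)
        by_id = {c.cluster_id: c for c in out.clusters}
        assert set(by_id) == {"mc1", "c3"}
        assert by_id["mc1"].genes == frozenset("abcd")
        assert by_id["mc1"].provenance == "merged"
        assert by_id["mc1"].merged_from == ["c1", "c2"]
        assert by_id["c3"].provenance == "mcl"

    def test_transitive_chain_collapses(self, default_cfg):
        cl = self.make([
            ("c1", "ab", ["F1"]), ("c2", "cd", ["F1", "F2"]), ("c3", "ef", ["F2"]),
        ])
        out = merge_clusters(cl, [one_db_collection()], default_cfg)
        assert len(out.clusters) == 1
        only = out.clusters[0]
        assert only.genes == frozenset("abcdef")
        assert only.cluster_id == "mc1"
        assert sorted(only.merged_from) == ["c1", "c2", "c3"]

    def test_no_shared_terms_is_identity(self, default_cfg):
        cl = self.make([("c1", "ab", ["F1"]), ("c2", "cd", ["F2"])])
        out = merge_clusters(cl, [one_db_collection()], default_cfg)
        assert [(c.cluster_id, c.provenance) for c in out.clusters] == [
            ("c1", "mcl"), ("c2", "mcl"),
        ]

    def test_idempotence(self, default_cfg):
        cl = self.make([
            ("c1", "ab", ["F1"]), ("c2", "cd", ["F1", "F2"]), ("c3", "ef", ["F2"]),
        ])
        colls = [one_db_collection()]
        once = merge_clusters(cl, colls, default_cfg)
        twice = merge_clusters(once, colls, default_cfg)
        assert [(c.cluster_id, c.genes, c.provenance) for c in twice.clusters] == [
            (c.cluster_id, c.genes, c.provenance) for c in once.clusters
        ]

    def test_databases_processed_separately(self, default_cfg):
        """Sharing requires a common term within one database; equal term
        ids in different databases do not merge."""
        cl = Clustering(
            clusters=[
                cluster("c1", "ab", ["F1"], db="db1"),
                cluster("c2", "cd", ["F1"], db="db2"),
            ],
            lonely=frozenset(),
        )
        colls = [
            make_collection("db1", {"F1": {"x"}}, {"x"}),
            make_collection("db2", {"F1": {"x"}}, {"x"}),
        ]
        out = merge_clusters(cl, colls, default_cfg)
        assert len(out.clusters) == 2

    def test_db_sequence_descending_coverage(self):
        colls = [
            make_collection("small", {"T": {"a"}}, {"a", "b", "c"}),
            make_collection("big", {"T": {"a", "b", "c"}}, {"a", "b", "c"}),
        ]
        assert [c.db_name for c in db_sequence(colls, PipelineConfig())] == [
            "big", "small",
        ]
        cfg = PipelineConfig(db_order=["small", "big"])
        assert [c.db_name for c in db_sequence(colls, cfg)] == ["small", "big"]


class TestFishLonely:
    def build_case(self):
        background = {"g1", "l1", "l2", "a", "b", "c", "d", "e", "f", "p", "q", "r"}
        coll = make_collection(
            "db",
            {
                "F1": {"l1", "a", "b", "c", "d"},
                "F3": {"l1", "e", "f", "p", "q"},
                "SMALL": {"l2", "r"},  # below the size window: never counts
            },
            background,
        )
        clustering = Clustering(
            clusters=[
                cluster("c1", "abcd", ["F1"]),
                cluster("c2", "ef", ["F3"]),
            ],
            lonely=frozenset({"l1", "l2"}),
        )
        return clustering, [coll]

    def test_gene_joins_all_matching_clusters(self, default_cfg):
        clustering, colls = self.build_case()
        out, records = fish_lonely(clustering, colls, default_cfg)
        assert [r.gene_id for r in records] == ["l1"]
        assert records[0].friendliness == 2
        assert records[0].joined_clusters == ["c1", "c2"]
        assert records[0].via_terms == {"c1": {"F1"}, "c2": {"F3"}}
        by_id = {c.cluster_id: c for c in out.clusters}
        assert "l1" in by_id["c1"].genes and "l1" in by_id["c2"].genes
        assert by_id["c1"].provenance == "expanded"
        assert out.lonely == frozenset({"l2"})

    def test_unmatched_annotations_stay_lonely(self, default_cfg):
        clustering, colls = self.build_case()
        out, records = fish_lonely(clustering, colls, default_cfg)
        # l2 is annotated only to a term below the size window
        assert "l2" in out.lonely
        assert all(r.gene_id != "l2" for r in records)

    def test_fishing_never_shrinks_clusters_nor_grows_lonely(self, default_cfg):
        clustering, colls = self.build_case()
        out, _ = fish_lonely(clustering, colls, default_cfg)
        for before, after in zip(clustering.clusters, out.clusters):
            assert before.genes <= after.genes
        assert out.lonely <= clustering.lonely

    def test_conservation_with_overlaps(self, default_cfg):
        clustering, colls = self.build_case()
        out, _ = fish_lonely(clustering, colls, default_cfg)
        covered = out.lonely | frozenset().union(*(c.genes for c in out.clusters))
        before = clustering.lonely | frozenset().union(
            *(c.genes for c in clustering.clusters)
        )
        assert covered == before

    def test_friendliness_histogram_sums_to_fished(self, default_cfg):
        clustering, colls = self.build_case()
        _, records = fish_lonely(clustering, colls, default_cfg)
        hist = {}
        for r in records:
            hist[r.friendliness] = hist.get(r.friendliness, 0) + 1
        assert sum(hist.values()) == len(records)
        assert all(f >= 1 for f in hist)


class TestRunPipeline:
    def test_noiseless_fixture_recovers_ground_truth(self, tmp_path):
        _, truth = generate_fixture(FixtureSpec(seed=11), tmp_path)
        b = read_bundle(tmp_path)
        cfg = PipelineConfig(seed=11)
        result = run_pipeline(
            b["lists"], b["edges"], b["collections"], cfg, b["ontology"]
        )
        truth = b["truth"]
        modules = {
            m: frozenset(truth.loc[truth.module == m, "gene_id"])
            for m in sorted(set(truth.module) - {""})
        }
        # pre-fishing membership: expanded clusters minus fished genes
        fished = {r.gene_id for r in result.fishing}
        cores = {c.genes - fished for c in result.clustering.clusters}
        assert cores == set(modules.values())
        # each cluster enriches exactly its planted term
        for c in result.clustering.clusters:
            planted = set(
                truth.loc[truth.gene_id.isin(c.genes - fished), "planted_term"]
            )
            assert {t for _, t in c.enriched_terms()} == planted
        # fished genes and the lonely residue match the truth table
        assert fished == set(truth.loc[truth.expected_fate == "fished", "gene_id"])
        assert result.clustering.lonely == frozenset(
            truth.loc[truth.expected_fate == "lonely", "gene_id"]
        )

    def test_shared_term_forces_module_merge(self, tmp_path):
        """Two planted modules annotated to one shared term merge."""
        _, _ = generate_fixture(FixtureSpec(seed=3), tmp_path)
        b = read_bundle(tmp_path)
        lists = b["lists"]
        truth = b["truth"]
        m1 = set(truth.loc[truth.module == "m1", "gene_id"])
        m2 = set(truth.loc[truth.module == "m2", "gene_id"])
        m3 = set(truth.loc[truth.module == "m3", "gene_id"])
        shared = {
            "SHARED": m1 | m2 | set(sorted(lists.background - lists.deregulated)[:4]),
            "T3": m3 | set(sorted(lists.background - lists.deregulated)[4:16]),
        }
        # pad the universe with noise terms over non-deregulated genes
        rest = sorted(lists.background - lists.deregulated)[16:]
        for j in range(8):
            shared[f"N{j}"] = set(rest[20 * j : 20 * (j + 1)])
        coll = make_collection("db", shared, lists.background)
        result = run_pipeline(lists, b["edges"], [coll], PipelineConfig())
        merged = [c for c in result.clustering.clusters if c.provenance == "merged"]
        assert len(merged) == 1
        assert merged[0].genes >= frozenset(m1 | m2)

    def test_empty_deregulated_short_circuits(self, default_cfg):
        lists = make_lists("abc", [])
        result = run_pipeline(lists, [], [], default_cfg)
        assert result.clustering.clusters == []
        assert result.enrichments == []
        assert result.log[0]["step"] == "short_circuit"


class TestRunStandard:
    def test_degenerate_full_background_query(self, default_cfg):
        background = [f"g{i}" for i in range(40)]
        terms = {f"T{j}": set(background[5 * j : 5 * (j + 1) + 3]) for j in range(6)}
        lists = make_lists(background, background)
        coll = make_collection("db", terms, background)
        assert run_standard(lists, [coll], default_cfg) == []

    def test_comparison_counts_are_set_consistent(self, tmp_path):
        generate_fixture(FixtureSpec(seed=2), tmp_path)
        b = read_bundle(tmp_path)
        cfg = PipelineConfig()
        result = run_pipeline(
            b["lists"], b["edges"], b["collections"], cfg, b["ontology"]
        )
        std = run_standard(b["lists"], b["collections"], cfg, b["ontology"])
        comp = compare_approaches(result, std, b["lists"])
        assert (
            comp["genes_both"] + comp["genes_only_anchored"]
            + comp["genes_only_standard"] + comp["genes_neither"]
            == comp["n_deregulated"]
        )
        assert enriched_genes(result.enrichments) <= b["lists"].deregulated
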