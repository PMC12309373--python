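"""Readers and writers for every external format the pipeline touches.

Inputs: a dose-response results CSV (one row per transcript, shaped like the
output of upstream DR modelling), an optional one-column background gene
list, a PPI edge list (STRING-style export, 0-1 or 0-1000 score dialect),
GMT gene-set collections, a child->parent ontology edge file and a
transcription-(co)factor list. Parsing is total: malformed input raises a
typed error naming the offending column or line, never a silent partial
load.
"""
from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import InputFormatError, ConsistencyError
from .model import (
    GeneLists,
    GeneSetCollection,
    TranscriptRecord,
    TREND_LABELS,
    REGULATOR_CLASSES,
)

log = logging.getLogger(__name__)

_DR_REQUIRED = ("transcript_id", "gene_id")
_DR_OPTIONAL = (
    "gene_name",
    "bmd",
    "bmd_ci_low",
    "bmd_ci_high",
    "trend",
    "model",
    "deregulated",
)

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def _opt_float(value, column: str, row: int) -> Optional[float]:
    s = _opt_str(value)
    if s is None:
        return None
    try:
        return float(s)
    except ValueError:
        raise InputFormatError(
            f"row {row}: column {column!r} has non-numeric value {s!r}"
        ) from None


def read_dr_results(path, background: Optional[object] = None) -> GeneLists:
    """Load the deregulated transcript table into a validated GeneLists.

    ``background`` is either a path to a one-column gene-id file (in which
    case every CSV row is deregulated) or None, in which case the CSV must
    carry a boolean ``deregulated`` column and the background is the set of
    all gene ids in the table.
    """
    df = pd.read_csv(path, dtype=str)
    for col in _DR_REQUIRED:
        if col not in df.columns:
            raise InputFormatError(f"{path}: missing required column {col!r}")
    if background is None and "deregulated" not in df.columns:
        raise InputFormatError(
            f"{path}: need a 'deregulated' column or a separate background file"
        )

    seen = set()
    records = []
    dereg_flags = []
    n_unmapped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        tid = _opt_str(row["transcript_id"])
        if tid is None:
            raise InputFormatError(f"row {i}: empty transcript_id")
        if tid in seen:
            raise InputFormatError(f"row {i}: duplicate transcript_id {tid!r}")
        seen.add(tid)
        trend = _opt_str(row.get("trend"))
        if trend is not None and trend not in TREND_LABELS:
            raise InputFormatError(
                f"row {i}: trend {trend!r} not one of {list(TREND_LABELS)}"
            )
        gid = _opt_str(row["gene_id"])
        if gid is None:
            n_unmapped += 1
            log.warning("row %d: transcript %r has no gene id; dropped from gene-level sets", i, tid)
        rec = TranscriptRecord(
            transcript_id=tid,
            gene_id=gid,
            gene_name=_opt_str(row.get("gene_name")),
            bmd=_opt_float(row.get("bmd"), "bmd", i),
            bmd_ci_low=_opt_float(row.get("bmd_ci_low"), "bmd_ci_low", i),
            bmd_ci_high=_opt_float(row.get("bmd_ci_high"), "bmd_ci_high", i),
            trend=trend,
            model=_opt_str(row.get("model")),
        )
        if background is None:
            flag = _opt_str(row.get("deregulated"))
            flag = (flag or "").lower()
            if flag in _TRUTHY:
                dereg_flags.append(True)
            elif flag in _FALSY:
                dereg_flags.append(False)
            else:
                raise InputFormatError(
                    f"row {i}: 'deregulated' value {flag!r} is not boolean"
                )
        records.append(rec)

    if background is not None:
        bg = read_gene_list(background)
        dereg = {r.gene_id for r in records if r.gene_id is not None}
    else:
        bg = {r.gene_id for r in records if r.gene_id is not None}
        dereg = {
            r.gene_id
            for r, f in zip(records, dereg_flags)
            if f and r.gene_id is not None
        }
        # a BMD on a non-deregulated row is a contradiction; GeneLists raises
    if n_unmapped:
        log.info("%d transcripts lacked a gene id and were reported only", n_unmapped)
    return GeneLists(
        background=frozenset(bg),
        deregulated=frozenset(dereg),
        transcripts=records,
        n_unmapped=n_unmapped,
    )


def read_gene_list(path) -> frozenset:
    """One gene id per line; a 'gene_id' header line is tolerated."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            g = line.strip()
            if not g or (i == 1 and g.lower() == "gene_id"):
                continue
            out.append(g)
    return frozenset(out)


def read_gmt(path, db_name: str, background: Iterable[str]) -> GeneSetCollection:
    """Parse a GMT file: term_id <tab> description <tab> gene <tab> gene ...

    Duplicate term ids are an error (no silent union); lines with fewer than
    three fields are rejected with their line number.
    """
    terms = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputFormatError(
                    f"{path}: line {i}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            term_id, name = fields[0].strip(), fields[1].strip()
            if term_id in terms:
                raise InputFormatError(
                    f"{path}: line {i}: duplicate term id {term_id!r}"
                )
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            terms[term_id] = (name, genes)
    return GeneSetCollection(db_name, terms, background)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Inverse of read_gmt (genes written sorted for determinism)."""
    with open(path, "w") as fh:
        for term_id, (name, genes) in collection.terms.items():
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def read_ppi_edges(path) -> list:
    """Parse a PPI edge list into (node_a, node_b, score in [0,1]) triples.

    Accepts tab- or comma-separated files with a header. If any score
    exceeds 1 the whole file is treated as the 0-1000 integer dialect and
    all scores are divided by 1000. Self-edges are dropped; duplicate
    undirected pairs keep the maximum score. Output is sorted, so the
    edge multiset is independent of input row order.
    """
    with open(path) as fh:
        first = fh.readline()
        sep = "\t" if "\t" in first else ","
        rows = []
        for i, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split(sep)
            if len(fields) < 3:
                raise InputFormatError(
                    f"{path}: line {i}: expected 3 {sep!r}-separated fields"
                )
            a, b, s = fields[0].strip(), fields[1].strip(), fields[2].strip()
            if not a or not b:
                raise InputFormatError(f"{path}: line {i}: empty node name")
            try:
                score = float(s)
            except ValueError:
                raise InputFormatError(
                    f"{path}: line {i}: non-numeric score {s!r}"
                ) from None
            if not 0.0 <= score <= 1000.0:
                raise InputFormatError(
                    f"{path}: line {i}: score {score} outside [0, 1000]"
                )
            rows.append((a, b, score, i))

    if any(s > 1.0 for _, _, s, _ in rows):
        log.info("%s: scores exceed 1; interpreting as 0-1000 dialect", path)
        rows = [(a, b, s / 1000.0, i) for a, b, s, i in rows]

    best = {}
    for a, b, s, i in rows:
        if a == b:
            log.warning("%s: line %d: self-edge on %r dropped", path, i, a)
            continue
        key = (a, b) if a <= b else (b, a)
        if key not in best or s > best[key]:
            best[key] = s
    return sorted((a, b, s) for (a, b), s in best.items())


def annotate_regulators(lists: GeneLists, path) -> GeneLists:
    """Flag each transcript's gene as TF / CoTF / none from a two-column file.

    A gene listed under both classes is flagged TF (logged). The step is
    optional: call sites may simply skip it, leaving every flag at 'none'.
    """
    classes = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputFormatError(
                    f"{path}: line {i}: expected 2 tab-separated fields"
                )
            gid, cls = fields[0].strip(), fields[1].strip()
            if i == 1 and cls.lower() in ("class", "regulator"):
                continue
            if cls not in REGULATOR_CLASSES:
                raise InputFormatError(
                    f"{path}: line {i}: class {cls!r} not one of "
                    f"{list(REGULATOR_CLASSES)}"
                )
            prev = classes.get(gid)
            if prev is not None and prev != cls:
                log.warning(
                    "%s: gene %r listed as both TF and CoTF; TF wins", path, gid
                )
                classes[gid] = "TF"
            else:
                classes[gid] = cls
    records = []
    for rec in lists.transcripts:
        cls = classes.get(rec.gene_id, "none") if rec.gene_id else "none"
        records.append(
            TranscriptRecord(
                transcript_id=rec.transcript_id,
                gene_id=rec.gene_id,
                gene_name=rec.gene_name,
                bmd=rec.bmd,
                bmd_ci_low=rec.bmd_ci_low,
                bmd_ci_high=rec.bmd_ci_high,
                trend=rec.trend,
                model=rec.model,
                regulator=cls,
            )
        )
    return GeneLists(
        background=lists.background,
        deregulated=lists.deregulated,
        transcripts=records,
        n_unmapped=lists.n_unmapped,
    )


def read_ontology_edges(path) -> list:
    """Child <tab> parent term-id pairs (acyclicity checked at use site)."""
    edges = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise InputFormatError(
                    f"{path}: line {i}: expected child<TAB>parent"
                )
            if i == 1 and fields[0].strip().lower() == "child":
                continue
            edges.append((fields[0].strip(), fields[1].strip()))
    return edges


# ---------------------------------------------------------------------------
# writers for tabular outputs


def write_enrichment_csv(results, path) -> None:
    cols = [
        "query_id", "db_name", "term_id", "term_name", "p_raw", "q_fdr",
        "k_overlap", "K_term_bg", "n_query", "N_background", "intersection",
        "driver",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for r in results:
            w.writerow([
                r.query_id, r.db_name, r.term_id, r.term_name,
                f"{r.p_raw:.6e}", f"{r.q_fdr:.6e}",
                r.k_overlap, r.K_term_bg, r.n_query, r.N_background,
                ";".join(sorted(r.intersection)),
                str(r.driver).lower(),
            ])


def write_clusters_tsv(clustering, path) -> None:
    """Two-column gene_id, cluster_id export (lonely genes included)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcluster_id\tprovenance\n")
        for c in clustering.clusters:
            for g in sorted(c.genes):
                fh.write(f"{g}\t{c.cluster_id}\t{c.provenance}\n")
        for g in sorted(clustering.lonely):
            fh.write(f"{g}\tlonely\tlonely\n")


def write_graph_tsv(graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tscore\n")
        for u, v, d in sorted(
            (min(u, v), max(u, v), d) for u, v, d in graph.edges(data=True)
        ):
            fh.write(f"{u}\t{v}\t{d['weight']:.3f}\n")


def write_fishing_csv(fishing, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gene_id", "friendliness", "joined_clusters", "via_terms"])
        for r in fishing:
            via = ";".join(
                f"{c}:{'|'.join(sorted(r.via_terms[c]))}" for c in r.joined_clusters
            )
            w.writerow([r.gene_id, r.friendliness, ";".join(r.joined_clusters), via])


def write_summary_csv(summaries, path) -> None:
    cols = [
        "cluster_id", "provenance", "n_genes", "n_transcripts", "bmd_q25",
        "inc", "dec", "bell", "U", "n_regulators", "n_fished",
        "enriched_terms",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for s in summaries:
            w.writerow([
                s.cluster_id, s.provenance, s.n_genes, s.n_transcripts,
                "" if s.bmd_q25 is None else f"{s.bmd_q25:.6g}",
                *(s.trend_counts.get(t, 0) for t in ("inc", "dec", "bell", "U")),
                s.n_regulators, s.n_fished,
                ";".join(f"{db}:{tid}" for db, tid, _ in s.enriched_terms),
            ])


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
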