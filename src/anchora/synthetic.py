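"""Deterministic generator of complete synthetic input bundles.

The generator plants known-truth structure shaped like the statistical
assumptions of the workflow: interaction-dense functional modules whose
members share a planted annotation term, a fishable fraction of lonely
genes annotated to planted terms but disconnected from the network, noise
edges below the confidence threshold, noise terms over non-deregulated
genes, and per-module benchmark-dose windows so the cluster sensitivity
ranking has an unambiguous expected order. The same seed always produces a
byte-identical bundle.

It emulates module structure and annotation overlap, not real expression
data: no read counts, no dose-response model fitting, and PPI confidence
scores drawn uniformly within per-class ranges straddling the default 0.9
threshold rather than from an evidence model.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import io as aio
from .errors import ConfigError
from .model import TREND_LABELS

__all__ = ["ModuleSpec", "FixtureSpec", "generate_fixture", "read_bundle"]

_MODELS = ("Hill", "linear", "exponential", "Gauss-probit", "log-Gauss-probit")


@dataclass(frozen=True)
class ModuleSpec:
    """One planted interaction-dense, co-annotated gene module."""

    size: int = 8
    term_bg_size: int = 20
    intra_edge_prob: float = 1.0
    score_range: Tuple[float, float] = (0.91, 0.99)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic input bundle.

    Defaults describe the noiseless reference condition: three 8-gene
    planted modules in a 500-gene background with 60 deregulated genes,
    five fishable lonely genes (annotated to a planted term, drawing their
    BMD from that module's window), no noise edges, and non-overlapping
    per-module BMD windows. ``trend_mix`` reproduces the monotone-dominated
    trend composition typical of dose-response transcriptomics (about 93%
    increasing or decreasing).
    """

    seed: int = 0
    n_background: int = 500
    n_deregulated: int = 60
    modules: Tuple[ModuleSpec, ...] = (ModuleSpec(), ModuleSpec(), ModuleSpec())
    n_lonely_annotated: int = 5
    noise_edges: int = 0
    noise_score_range: Tuple[float, float] = (0.30, 0.85)
    noise_terms: int = 12
    noise_term_size: Tuple[int, int] = (8, 25)
    bmd_windows: Optional[Tuple[Tuple[float, float], ...]] = (
        (1.0, 3.0),
        (5.0, 12.0),
        (20.0, 50.0),
    )
    lonely_bmd_window: Tuple[float, float] = (1.0, 100.0)
    trend_mix: Tuple[float, float, float, float] = (0.46, 0.47, 0.03, 0.04)
    n_regulators: int = 10
    second_transcript_prob: float = 0.25
    annotate_background: bool = False
    parent_extra: int = 10

    def __post_init__(self) -> None:
        planted = sum(m.size for m in self.modules) + self.n_lonely_annotated
        if planted > self.n_deregulated:
            raise ConfigError("planted genes exceed the deregulated list size")
        if self.n_deregulated > self.n_background:
            raise ConfigError("deregulated list larger than background")
        if abs(sum(self.trend_mix) - 1.0) > 1e-9:
            raise ConfigError("trend_mix probabilities must sum to 1")
        if self.bmd_windows is not None and len(self.bmd_windows) != len(self.modules):
            raise ConfigError("need one BMD window per module")

    @classmethod
    def moderate_noise(cls, seed: int = 0) -> "FixtureSpec":
        """Documented moderate-noise condition: slightly incomplete modules
        (intra-module edge probability 0.9) plus 40 sub-threshold noise
        edges among deregulated genes."""
        return cls(
            seed=seed,
            modules=tuple(replace(m, intra_edge_prob=0.9) for m in cls().modules),
            noise_edges=40,
        )

    @classmethod
    def anchoring(cls, seed: int = 0) -> "FixtureSpec":
        """Condition for the anchoring-sensitivity comparison: one 8-gene
        module inside a 150-gene deregulated list whose planted term covers
        40 background genes, with noise terms annotating the whole
        background so the whole-list test has no power advantage."""
        return cls(
            seed=seed,
            n_background=500,
            n_deregulated=150,
            modules=(ModuleSpec(size=8, term_bg_size=40),),
            n_lonely_annotated=0,
            noise_terms=30,
            noise_term_size=(15, 25),
            bmd_windows=((1.0, 5.0),),
            annotate_background=True,
        )


def _log_uniform(rng, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_fixture(spec: FixtureSpec, out_dir):
    """Write a complete input bundle and its ground truth to ``out_dir``.

    Returns (manifest, truth) DataFrames. The manifest lists every written
    file with its role and row count; the truth table records, per
    deregulated gene, its planted module, planted term and expected fate
    (clustered / fished / lonely) plus the expected fishing friendliness.
    """
    out = aio.ensure_dir(out_dir)
    rng = np.random.default_rng(spec.seed)

    width = max(4, len(str(spec.n_background)))
    background = [f"g{i:0{width}d}" for i in range(1, spec.n_background + 1)]
    dereg = sorted(
        rng.choice(background, size=spec.n_deregulated, replace=False).tolist()
    )
    shuffled = list(rng.permutation(dereg))

    modules = []
    pos = 0
    for m in spec.modules:
        modules.append(sorted(shuffled[pos : pos + m.size]))
        pos += m.size
    fishable = sorted(shuffled[pos : pos + spec.n_lonely_annotated])
    pos += spec.n_lonely_annotated
    plain_lonely = sorted(shuffled[pos:])

    fish_target = {g: i % len(modules) for i, g in enumerate(fishable)} if modules else {}

    # --- gene sets -------------------------------------------------------
    non_dereg = [g for g in background if g not in set(dereg)]
    filler_pool = list(rng.permutation(non_dereg))
    fp = 0

    def take_filler(n):
        nonlocal fp
        if fp + n > len(filler_pool):
            raise ConfigError("background too small for requested term sizes")
        out = filler_pool[fp : fp + n]
        fp += n
        return out

    planted_terms = {}  # term_id -> (name, genes)
    parent_terms = {}
    ontology = []
    for i, (m, genes) in enumerate(zip(spec.modules, modules), start=1):
        members = list(genes) + [g for g, t in fish_target.items() if t == i - 1]
        n_fill = m.term_bg_size - len(members)
        if n_fill < 0:
            raise ConfigError(f"module {i}: term_bg_size smaller than members")
        members += take_filler(n_fill)
        tid = f"T{i:03d}"
        planted_terms[tid] = (f"planted function {i}", sorted(members))
        pid = f"P{i:03d}"
        parent_terms[pid] = (
            f"planted parent function {i}",
            sorted(members + take_filler(spec.parent_extra)),
        )
        ontology.append((tid, pid))

    noise_pool = background if spec.annotate_background else non_dereg
    noise_terms = {}
    for j in range(1, spec.noise_terms + 1):
        size = int(rng.integers(spec.noise_term_size[0], spec.noise_term_size[1] + 1))
        genes = sorted(rng.choice(noise_pool, size=size, replace=False).tolist())
        noise_terms[f"N{j:03d}"] = (f"noise function {j}", genes)

    # --- edges -----------------------------------------------------------
    edge_rows = []
    for m, genes in zip(spec.modules, modules):
        for a_i in range(len(genes)):
            for b_i in range(a_i + 1, len(genes)):
                if rng.random() < m.intra_edge_prob:
                    s = rng.uniform(*m.score_range)
                    edge_rows.append((genes[a_i], genes[b_i], int(round(s * 1000))))
    placed = 0
    attempts = 0
    seen_pairs = {(a, b) for a, b, _ in edge_rows}
    while placed < spec.noise_edges and attempts < spec.noise_edges * 50:
        attempts += 1
        a, b = rng.choice(dereg, size=2, replace=False)
        key = (min(a, b), max(a, b))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        s = rng.uniform(*spec.noise_score_range)
        edge_rows.append((key[0], key[1], int(round(s * 1000))))
        placed += 1
    edge_rows.sort()

    # --- transcripts with DR metrics -------------------------------------
    gene_window = {}
    for i, genes in enumerate(modules):
        for g in genes:
            gene_window[g] = spec.bmd_windows[i] if spec.bmd_windows else spec.lonely_bmd_window
    for g, t in fish_target.items():
        gene_window[g] = spec.bmd_windows[t] if spec.bmd_windows else spec.lonely_bmd_window
    for g in plain_lonely:
        gene_window[g] = spec.lonely_bmd_window

    dereg_set = set(dereg)
    transcripts = []
    for g in background:
        n_tx = 1
        if g in dereg_set and rng.random() < spec.second_transcript_prob:
            n_tx = 2
        for j in range(1, n_tx + 1):
            tid = f"t_{g}_{j}"
            if g in dereg_set:
                lo, hi = gene_window[g]
                bmd = round(_log_uniform(rng, lo, hi), 4)
                trend = str(rng.choice(TREND_LABELS, p=list(spec.trend_mix)))
                model = _MODELS[int(rng.integers(0, len(_MODELS)))]
                transcripts.append(
                    (tid, g, f"name_{g}", f"{bmd:.4f}", f"{bmd * 0.8:.4f}",
                     f"{bmd * 1.25:.4f}", trend, model, "true")
                )
            else:
                transcripts.append((tid, g, f"name_{g}", "", "", "", "", "", "false"))

    # --- regulators -------------------------------------------------------
    reg_pool = list(rng.permutation(background))[: spec.n_regulators]
    regulators = [
        (g, "TF" if i % 2 == 0 else "CoTF") for i, g in enumerate(sorted(reg_pool))
    ]

    # --- write files ------------------------------------------------------
    files = {}

    path = out / "dr_results.csv"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["transcript_id", "gene_id", "gene_name", "bmd", "bmd_ci_low",
                    "bmd_ci_high", "trend", "model", "deregulated"])
        w.writerows(transcripts)
    files["dr_results"] = (path, len(transcripts))

    path = out / "ppi_edges.tsv"
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tcombined_score\n")
        for a, b, s in edge_rows:
            fh.write(f"{a}\t{b}\t{s}\n")
    files["ppi_edges"] = (path, len(edge_rows))

    path = out / "gobp.gmt"
    all_terms = {**planted_terms, **parent_terms, **noise_terms}
    with open(path, "w") as fh:
        for tid in sorted(all_terms):
            name, genes = all_terms[tid]
            fh.write("\t".join([tid, name, *genes]) + "\n")
    files["gmt_gobp"] = (path, len(all_terms))

    # second, pathway-style collection: noise only (no deregulated genes)
    path = out / "kegg.gmt"
    kegg = {}
    for j in range(1, max(3, spec.noise_terms // 2) + 1):
        size = int(rng.integers(spec.noise_term_size[0], spec.noise_term_size[1] + 1))
        genes = sorted(rng.choice(non_dereg, size=size, replace=False).tolist())
        kegg[f"K{j:03d}"] = (f"noise pathway {j}", genes)
    with open(path, "w") as fh:
        for tid in sorted(kegg):
            name, genes = kegg[tid]
            fh.write("\t".join([tid, name, *genes]) + "\n")
    files["gmt_kegg"] = (path, len(kegg))

    path = out / "ontology.tsv"
    with open(path, "w") as fh:
        fh.write("child\tparent\n")
        for child, parent in ontology:
            fh.write(f"{child}\t{parent}\n")
    files["ontology"] = (path, len(ontology))

    path = out / "regulators.tsv"
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\n")
        for g, cls in regulators:
            fh.write(f"{g}\t{cls}\n")
    files["regulators"] = (path, len(regulators))

    # --- ground truth -----------------------------------------------------
    truth_rows = []
    for i, genes in enumerate(modules, start=1):
        for g in genes:
            truth_rows.append((g, f"m{i}", f"T{i:03d}", "clustered", ""))
    for g in fishable:
        t = fish_target[g]
        truth_rows.append((g, "", f"T{t + 1:03d}", "fished", "1"))
    for g in plain_lonely:
        truth_rows.append((g, "", "", "lonely", ""))
    truth_rows.sort()
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "module", "planted_term", "expected_fate",
                 "expected_friendliness"],
    )
    path = out / "truth.csv"
    truth.to_csv(path, index=False)
    files["truth"] = (path, len(truth))

    manifest = pd.DataFrame(
        [(role, p.name, n) for role, (p, n) in sorted(files.items())],
        columns=["role", "file", "rows"],
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest, truth


def read_bundle(out_dir) -> dict:
    """Read a generated bundle back through the standard readers."""
    out = Path(out_dir)
    lists = aio.read_dr_results(out / "dr_results.csv")
    lists = aio.annotate_regulators(lists, out / "regulators.tsv")
    edges = aio.read_ppi_edges(out / "ppi_edges.tsv")
    collections = [
        aio.read_gmt(out / "gobp.gmt", "gobp", lists.background),
        aio.read_gmt(out / "kegg.gmt", "kegg", lists.background),
    ]
    ontology = aio.read_ontology_edges(out / "ontology.tsv")
    truth = pd.read_csv(out / "truth.csv", dtype=str).fillna("")
    return {
        "lists": lists,
        "edges": edges,
        "collections": collections,
        "ontology": ontology,
        "truth": truth,
    }
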