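"""Genome-wide degradome-validated target calling and the bipartite
sRNA-transcript regulatory network.

Annotated sRNAs with a combined raw count of at least 50 across libraries
are searched against the transcriptome; each candidate cleavage event is
scored with the multi-library target_deg_score (category weights 5 / 4 /
0.5) and validated at a fixed threshold (default 15, which selects roughly
the 1% ECDF tail of event scores in large multi-library compendia).
Validated interactions, together with
biogenesis relationships (precursor transcript -> sRNA), form a directed
bipartite network whose structure (weakly connected components, density,
clustering, per-class degree distributions with log-log degree-frequency
regression) and GO-slim term representation (hypergeometric over/under
tests with Benjamini-Hochberg correction) are summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .degradome import (
    DEFAULT_WEIGHTS,
    DegradomeProfile,
    find_target_alignments,
    score_alignment,
)
from .features import GenomeAnnotation
from .seqio import DegradomeLibrary, SrnaLibrary


@dataclass(frozen=True)
class SrnaCandidate:
    srna_id: str
    sequence: str
    kind: str  # 'miRNA' | 'phasiRNA'
    precursor_id: str  # MIR precursor or PHAS locus id
    combined_count: int


@dataclass(frozen=True)
class Interaction:
    srna_id: str
    srna_sequence: str
    kind: str
    precursor_id: str
    transcript_id: str
    slice_position: int  # transcript coordinate (nt 5' of the cut)
    target_deg_score: float
    allen_score: float
    validated: bool


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    t: float
    df: int
    p: float


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # network genes in term
    K: int  # universe genes in term
    n: int  # network genes
    N: int  # universe size
    direction: str  # 'over' | 'under'
    raw_p: float
    corrected_p: float
    significant: bool


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    n_biogenesis_edges: int
    n_cleavage_edges: int
    n_components: int
    component_sizes: list[int]
    density: float
    avg_clustering: float
    degree_distributions: dict[str, dict[int, float]]
    degree_regressions: dict[str, CorrelationResult | None]
    co_regulated_fraction: float


def select_active_candidates(
    srnas: Iterable[SrnaCandidate], min_combined: int = 50
) -> list[SrnaCandidate]:
    """Keep sRNAs whose raw collapsed counts summed over all libraries reach
    ``min_combined`` (inclusive boundary)."""
    return [s for s in srnas if s.combined_count >= min_combined]


def combined_raw_count(sequence: str, libraries: Sequence[SrnaLibrary]) -> int:
    """Raw collapsed counts summed across libraries (before multimapper division)."""
    total = 0
    for lib in libraries:
        read = lib.reads.get(sequence)
        if read is not None:
            total += read.count
    return total


def validate_targets(
    candidates: Sequence[SrnaCandidate],
    transcripts: Mapping[str, str],
    degradome_libraries: Sequence[DegradomeLibrary],
    threshold: float = 15.0,
    max_allen: float = 7.0,
    weights: Mapping[int, float] = DEFAULT_WEIGHTS,
) -> list[Interaction]:
    """Score every candidate sRNA against every transcript and validate
    interactions whose summed score reaches the threshold.

    Monotone in libraries: adding a degradome library never invalidates a
    previously validated interaction (weights are non-negative).
    """
    profiles: dict[str, dict[str, DegradomeProfile]] = {
        tid: {
            lib.library_id: DegradomeProfile.build(tid, tseq, lib)
            for lib in degradome_libraries
        }
        for tid, tseq in transcripts.items()
    }
    out: list[Interaction] = []
    for cand in candidates:
        for tid in sorted(transcripts):
            for aln in find_target_alignments(
                cand.sequence, tid, transcripts[tid], max_allen
            ):
                ws = score_alignment(aln, profiles[tid], weights)
                if ws.score <= 0:
                    continue
                out.append(
                    Interaction(
                        cand.srna_id, cand.sequence, cand.kind, cand.precursor_id,
                        tid, aln.slice_position, ws.score, aln.allen_score,
                        ws.score >= threshold,
                    )
                )
    out.sort(key=lambda ix: (ix.srna_id, ix.transcript_id, ix.slice_position))
    return out


def map_target_site(
    interaction: Interaction,
    annotation: GenomeAnnotation,
    gene_id: str | None = None,
) -> tuple[str, int, str]:
    """Convert a transcript-space slice site to genomic coordinates and the
    overlapping gene-region label (5'UTR / CDS / 3'UTR / biotype)."""
    gene = annotation.by_id(gene_id or interaction.transcript_id)
    gpos = annotation.transcript_to_genomic(gene, interaction.slice_position)
    return gene.chrom, gpos, annotation.region_label(gene, gpos)


def build_network(
    candidates: Sequence[SrnaCandidate],
    interactions: Sequence[Interaction],
) -> nx.DiGraph:
    """Assemble the bipartite directed network.

    sRNA nodes are restricted to *active* sRNAs (>=1 validated target);
    transcript nodes are their precursors plus validated targets.  Edges:
    ``biogenesis`` (precursor transcript -> sRNA) and ``cleavage``
    (sRNA -> transcript).
    """
    known = {c.srna_id for c in candidates}
    for ix in interactions:
        if ix.srna_id not in known:
            raise ValueError(f"interaction references unknown sRNA {ix.srna_id}")
    active = {ix.srna_id for ix in interactions if ix.validated}
    g = nx.DiGraph()
    for cand in candidates:
        if cand.srna_id not in active:
            continue
        g.add_node(cand.srna_id, node_type="sRNA", node_class=cand.kind)
        if cand.precursor_id:
            pclass = "PHAS_locus" if cand.kind == "phasiRNA" else "miRNA_precursor"
            if not g.has_node(cand.precursor_id):
                g.add_node(cand.precursor_id, node_type="transcript", node_class=pclass)
            g.add_edge(cand.precursor_id, cand.srna_id, edge_type="biogenesis")
    for ix in interactions:
        if not ix.validated or ix.srna_id not in active:
            continue
        if not g.has_node(ix.transcript_id):
            g.add_node(ix.transcript_id, node_type="transcript", node_class="target")
        g.add_edge(ix.srna_id, ix.transcript_id, edge_type="cleavage")
    return g


def co_regulated_fraction(network: nx.DiGraph) -> float:
    """Fraction of cleavage-targeted transcripts hit by both a miRNA and a
    phasiRNA."""
    targets = [
        n
        for n, d in network.nodes(data=True)
        if d.get("node_type") == "transcript"
        and any(
            network.edges[u, n].get("edge_type") == "cleavage"
            for u in network.predecessors(n)
        )
    ]
    if not targets:
        return 0.0
    co = 0
    for n in targets:
        kinds = {
            network.nodes[u].get("node_class")
            for u in network.predecessors(n)
            if network.edges[u, n].get("edge_type") == "cleavage"
        }
        if "miRNA" in kinds and "phasiRNA" in kinds:
            co += 1
    return co / len(targets)


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with t = r sqrt(df / (1 - r^2)), df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, _ = stats.pearsonr(x, y)
    df = len(x) - 2
    denom = max(1e-300, 1 - r * r)
    t = r * np.sqrt(df / denom)
    p = 2 * stats.t.sf(abs(t), df)
    return CorrelationResult(float(r), float(r * r), float(t), df, float(p))


def network_metrics(network: nx.DiGraph) -> NetworkMetrics:
    """Structural summary of the directed bipartite network."""
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("density undefined for networks with fewer than 2 nodes")
    e = network.number_of_edges()
    comps = sorted((len(c) for c in nx.weakly_connected_components(network)), reverse=True)
    und = network.to_undirected()
    degree_dists: dict[str, dict[int, float]] = {}
    regressions: dict[str, CorrelationResult | None] = {}
    for cls, direction in (
        ("sRNA", "in"), ("sRNA", "out"), ("transcript", "in"), ("transcript", "out"),
    ):
        nodes = [x for x, d in network.nodes(data=True) if d.get("node_type") == cls]
        if not nodes:
            continue
        degs = [
            (network.in_degree(x) if direction == "in" else network.out_degree(x))
            for x in nodes
        ]
        dist = {}
        for k in sorted(set(degs)):
            dist[k] = degs.count(k) / len(degs)
        key = f"{cls}_{direction}degree"
        degree_dists[key] = dist
        pts = [(k, p) for k, p in dist.items() if k > 0 and p > 0]
        if len(pts) >= 3 and len({k for k, _ in pts}) >= 3:
            lx = [np.log10(k) for k, _ in pts]
            ly = [np.log10(p) for _, p in pts]
            try:
                regressions[key] = correlate(lx, ly)
            except ValueError:
                regressions[key] = None
        else:
            regressions[key] = None
    n_bio = sum(1 for *_e, d in network.edges(data=True) if d.get("edge_type") == "biogenesis")
    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        n_biogenesis_edges=n_bio,
        n_cleavage_edges=e - n_bio,
        n_components=len(comps),
        component_sizes=comps,
        density=e / (n * (n - 1)),
        avg_clustering=nx.average_clustering(und),
        degree_distributions=degree_dists,
        degree_regressions=regressions,
        co_regulated_fraction=co_regulated_fraction(network),
    )


def go_enrichment(
    network_genes: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over/under-representation of flat GO-slim terms.

    ``term_map`` maps term id -> gene ids.  Over- and under-representation
    run as two one-sided test families, each Benjamini-Hochberg corrected.
    """
    universe = set(universe)
    net = set(network_genes)
    missing = net - universe
    if missing:
        raise ValueError(f"network genes absent from universe: {sorted(missing)[:5]}")
    N, n = len(universe), len(net)
    rows = []
    for term in sorted(term_map):
        genes = set(term_map[term]) & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & net)
        over_p = float(stats.hypergeom.sf(k - 1, N, K, n))
        under_p = float(stats.hypergeom.cdf(k, N, K, n))
        rows.append((term, k, K, over_p, under_p))
    results: list[EnrichmentResult] = []
    for direction, idx in (("over", 3), ("under", 4)):
        raw = [row[idx] for row in rows]
        if not raw:
            continue
        rej, corrected, *_ = multipletests(raw, alpha=alpha, method="fdr_bh")
        for (term, k, K, *_p), cp, rj in zip(rows, corrected, rej):
            results.append(
                EnrichmentResult(term, k, K, n, N, direction, _p[idx - 3], float(cp), bool(rj))
            )
    return results


def export_graphml(network: nx.DiGraph, path) -> None:
    nx.write_graphml(network, path)


def export_sif(network: nx.DiGraph, path) -> None:
    """Simple interaction format: source <edge_type> target."""
    with open(path, "w") as fh:
        for u, v, d in sorted(network.edges(data=True)):
            fh.write(f"{u}\t{d.get('edge_type', 'edge')}\t{v}\n")
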