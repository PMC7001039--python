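"""End-to-end orchestration: preprocess -> map -> detect -> annotate ->
validate targets -> network -> enrichment, with plain-text outputs.

Every stage is an importable function elsewhere in the package; this
module wires them together under one :class:`PipelineConfig`, carries the
numeric defaults of the method in a single place, and writes inspectable
TSV/GFF3/GraphML/JSON artifacts with a provenance header (config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import network as net
from . import phas, triggers
from .features import GenomeAnnotation
from .seqio import (
    DegradomeLibrary,
    ReadAlignment,
    SrnaLibrary,
    filter_library,
    map_reads,
    qc_library,
    read_genome_fasta,
)
from .simulate import SimulatedBundle

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All stage parameters, with the method's published defaults."""

    min_count: int = 50
    min_len: int = 20
    max_len: int = 40
    min_unique: int = 100
    max_locations: int = 10
    top_fraction: float = 0.15
    phasing_min_score: float = 15.0
    min_libraries: int = 3
    pad: int = 220
    cycle: int = 21
    window_cycles: int = 11
    deg_weights: dict[int, float] = field(
        default_factory=lambda: {0: 5.0, 1: 4.0, 2: 0.5, 3: 0.0, 4: 0.0}
    )
    bin_weights: tuple[float, ...] = (5.0, 2.0, 0.5)
    trigger_min_score: float = 10.0
    target_threshold: float = 15.0
    min_combined: int = 50
    min_overlap: float = 0.70
    max_rounds: int = 3
    max_allen: float = 7.0
    filter_degradome_counts: bool = False  # degradome tags unfiltered by count
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineInputs:
    genome: dict[str, str]
    annotation: GenomeAnnotation
    srna_libraries: list[SrnaLibrary]
    degradome_libraries: list[DegradomeLibrary]
    mirnas: list[dict]  # {mirna_id, sequence, precursor_id}
    go_table: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_bundle(cls, bundle: SimulatedBundle) -> "PipelineInputs":
        return cls(
            genome=bundle.genome,
            annotation=bundle.annotation,
            srna_libraries=bundle.srna_libraries,
            degradome_libraries=bundle.degradome_libraries,
            mirnas=bundle.truth.mirnas,
            go_table=bundle.go_table,
        )

    @classmethod
    def from_paths(
        cls,
        genome_fa: str | Path,
        gff3: str | Path,
        srna_fastas: Sequence[str | Path],
        degradome_fastas: Sequence[str | Path],
        mirna_tsv: str | Path,
        go_tsv: str | Path | None = None,
    ) -> "PipelineInputs":
        for p in [genome_fa, gff3, mirna_tsv, *srna_fastas, *degradome_fastas]:
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input: {p}")
        mirnas = []
        with open(mirna_tsv) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                mirnas.append(
                    {
                        "mirna_id": row["mirna_id"],
                        "sequence": row["sequence"].upper().replace("U", "T"),
                        "precursor_id": row.get("precursor_id", ""),
                    }
                )
        go_table = []
        if go_tsv and Path(go_tsv).exists():
            with open(go_tsv) as fh:
                fh.readline()
                go_table = [tuple(line.rstrip("\n").split("\t")[:2]) for line in fh if line.strip()]
        return cls(
            genome=read_genome_fasta(genome_fa),
            annotation=GenomeAnnotation.from_gff3(gff3),
            srna_libraries=[SrnaLibrary.from_fasta(p) for p in srna_fastas],
            degradome_libraries=[DegradomeLibrary.from_fasta(p) for p in degradome_fastas],
            mirnas=mirnas,
            go_table=go_table,
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    filtered_libraries: list[SrnaLibrary]
    alignments: dict[str, list[ReadAlignment]]
    consensus_loci: list[phas.ConsensusPhasLocus]
    annotation_result: triggers.AnnotationResult
    recall: float | None
    classification: dict[str, int]
    candidates: list[net.SrnaCandidate]
    interactions: list[net.Interaction]
    target_sites: list[dict]
    network: "net.nx.DiGraph"
    metrics: net.NetworkMetrics | None
    enrichment: list[net.EnrichmentResult]
    correlations: dict[str, net.CorrelationResult | None]
    log: list[dict]


def run_pipeline(
    inputs: PipelineInputs,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs; optionally write all artifacts."""
    config = config or PipelineConfig()
    log: list[dict] = []

    def stage(name: str, **counts) -> None:
        log.append({"stage": name, "time": round(time.time(), 2), **counts})

    # 1. preprocess sRNA libraries
    filtered: list[SrnaLibrary] = []
    for lib in inputs.srna_libraries:
        f = filter_library(lib, config.min_count, config.min_len, config.max_len)
        if qc_library(f, config.min_unique):
            filtered.append(f)
    stage("preprocess", libraries_in=len(inputs.srna_libraries), libraries_kept=len(filtered))
    deg_libs = inputs.degradome_libraries
    if config.filter_degradome_counts:
        deg_libs = [
            filter_library(d, config.min_count, 1, 10**6) for d in deg_libs
        ]

    # 2. genome-wide exact mapping, 21/22-nt reads, fractional multimappers
    alignments = {
        lib.library_id: map_reads(
            lib, inputs.genome, {21, 22}, config.max_locations
        )
        for lib in filtered
    }
    stage("map", alignments=sum(len(a) for a in alignments.values()))

    # 3. per-library detection and cross-library consensus
    calls: list[phas.PhasLocusCall] = []
    for lib_id, aligns in alignments.items():
        regions = phas.select_candidate_regions(aligns, config.top_fraction)
        calls.extend(
            phas.call_phas_loci(
                lib_id, regions, aligns, config.phasing_min_score,
                config.cycle, config.window_cycles,
            )
        )
    consensus = phas.merge_consensus(calls, config.min_libraries)
    chrom_lengths = {c: len(s) for c, s in inputs.genome.items()}
    consensus = phas.extend_loci(consensus, chrom_lengths, config.pad)
    stage("detect", calls=len(calls), consensus_loci=len(consensus))

    # 4. trigger / phasiRNA annotation
    raw_counts: dict[str, int] = {}
    for lib in filtered:
        for read in lib:
            raw_counts[read.sequence] = raw_counts.get(read.sequence, 0) + read.count
    states = triggers.prepare_locus_states(consensus, inputs.genome, alignments, deg_libs)
    ann_result = triggers.iterate_annotation(
        states, inputs.mirnas, raw_counts, config.max_rounds,
        config.trigger_min_score, config.max_allen, config.deg_weights,
    )
    stage(
        "annotate",
        triggers=len(ann_result.triggers),
        phasirnas=len(ann_result.phasirnas),
        rounds=ann_result.rounds_run,
    )

    # 5. feature assignment, naming, evaluation
    for lid in sorted(states):
        triggers.assign_locus_feature(states[lid], inputs.annotation, config.min_overlap)
    triggers.name_all_phasirnas(ann_result, inputs.annotation)
    try:
        recall = triggers.evaluate_annotation_recall(ann_result, alignments)
    except ValueError:
        recall = None
    classification = triggers.classify_phasirnas(ann_result.phasirnas)
    stage("evaluate", recall=recall)

    # 6. candidate selection and genome-wide target validation
    candidates: dict[str, net.SrnaCandidate] = {}
    for m in inputs.mirnas:
        candidates[m["sequence"]] = net.SrnaCandidate(
            m["mirna_id"], m["sequence"], "miRNA", m.get("precursor_id", ""),
            net.combined_raw_count(m["sequence"], filtered),
        )
    for rec in ann_result.phasirnas:
        if rec.sequence in candidates:
            continue
        candidates[rec.sequence] = net.SrnaCandidate(
            rec.name or f"{rec.locus_id}:{rec.eff5}{rec.genomic_strand}",
            rec.sequence, "phasiRNA", rec.locus_id, rec.combined_count,
        )
    active_candidates = net.select_active_candidates(
        candidates.values(), config.min_combined
    )
    transcripts = {
        g.feature_id: inputs.annotation.transcript_sequence(inputs.genome, g)
        for g in inputs.annotation.genes()
    }
    interactions = net.validate_targets(
        active_candidates, transcripts, deg_libs,
        config.target_threshold, config.max_allen, config.deg_weights,
    )
    target_sites = []
    for ix in interactions:
        if not ix.validated:
            continue
        try:
            chrom, gpos, label = net.map_target_site(ix, inputs.annotation)
        except (KeyError, ValueError):
            continue
        target_sites.append(
            {"srna_id": ix.srna_id, "transcript_id": ix.transcript_id,
             "chrom": chrom, "genomic_position": gpos, "region": label}
        )
    stage(
        "targets",
        candidates=len(active_candidates),
        interactions=len(interactions),
        validated=sum(ix.validated for ix in interactions),
    )

    # 7. network and structural/functional analysis
    graph = net.build_network(active_candidates, interactions)
    metrics = None
    if graph.number_of_nodes() >= 2:
        metrics = net.network_metrics(graph)
    enrichment: list[net.EnrichmentResult] = []
    if inputs.go_table and graph.number_of_nodes() > 0:
        term_map: dict[str, set[str]] = {}
        for gene, term in inputs.go_table:
            term_map.setdefault(term, set()).add(gene)
        universe = {g.feature_id for g in inputs.annotation.genes()}
        net_genes = network_gene_set(graph, states) & universe
        if net_genes:
            enrichment = net.go_enrichment(net_genes, universe, term_map)
    correlations = _locus_correlations(ann_result)
    stage(
        "network",
        nodes=graph.number_of_nodes(),
        edges=graph.number_of_edges(),
        components=metrics.n_components if metrics else 0,
    )

    result = PipelineResult(
        config, filtered, alignments, consensus, ann_result, recall,
        classification, active_candidates, interactions, target_sites,
        graph, metrics, enrichment, correlations, log,
    )
    if outdir is not None:
        write_outputs(result, inputs, Path(outdir))
    return result


def network_gene_set(graph, states: Mapping[str, triggers.LocusState]) -> set[str]:
    """Gene ids represented by transcript nodes (PHAS loci map through their
    feature assignment when one exists)."""
    genes: set[str] = set()
    assigned = {
        lid: s.assignment.assigned_id
        for lid, s in states.items()
        if s.assignment is not None and s.assignment.confidence in ("confirmed", "tentative")
    }
    for node, data in graph.nodes(data=True):
        if data.get("node_type") != "transcript":
            continue
        if node in assigned:
            genes.add(assigned[node].upper() if assigned[node].islower() else assigned[node])
        else:
            genes.add(node)
    return genes


def _locus_correlations(result: triggers.AnnotationResult):
    """Locus length vs trigger count, and deg_score vs locus length."""
    lengths, n_trig, tlen, tscore = [], [], [], []
    for lid in sorted(result.states):
        state = result.states[lid]
        if not state.triggers:
            continue
        lengths.append(state.locus.length)
        n_trig.append(len(state.triggers))
        for t in state.triggers:
            tlen.append(state.locus.length)
            tscore.append(t.deg_score)
    out: dict[str, net.CorrelationResult | None] = {}
    for key, (x, y) in {
        "length_vs_n_triggers": (lengths, n_trig),
        "length_vs_deg_score": (tlen, tscore),
    }.items():
        try:
            out[key] = net.correlate(x, y)
        except ValueError:
            out[key] = None
    return out


# ---------------------------------------------------------------------------
# output writing


def _header(config: PipelineConfig) -> str:
    return f"# phasinet {__version__} config={config.digest()}\n"


def write_outputs(result: PipelineResult, inputs: PipelineInputs, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    head = _header(result.config)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(
            {"version": __version__, "config": dataclasses.asdict(result.config),
             "config_digest": result.config.digest()},
            fh, indent=1, sort_keys=True, default=str,
        )
    with open(outdir / "consensus_loci.tsv", "w") as fh:
        fh.write(head)
        fh.write("chrom\tstart\tend\tlocus_id\tn_detections\tpolarity\tassigned\tconfidence\n")
        for locus in result.consensus_loci:
            st = result.annotation_result.states[locus.locus_id]
            a = st.assignment
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.locus_id}\t"
                f"{locus.n_detections}\t{locus.polarity}\t"
                f"{a.assigned_id if a else '.'}\t{a.confidence if a else '.'}\n"
            )
    gff = GenomeAnnotation()
    for locus in result.consensus_loci:
        gff.features.append(
            _locus_feature(locus, result.annotation_result.states[locus.locus_id])
        )
    gff.to_gff3(outdir / "phas_loci.gff3", header_lines=[head.strip("#\n ")])
    with open(outdir / "triggers.tsv", "w") as fh:
        fh.write(head)
        fh.write("srna_id\tsequence\tlocus_id\tpolarity\tslice_genomic\tdeg_score\tallen\trank\tregister_bin\tround\n")
        for t in result.annotation_result.triggers:
            fh.write(
                f"{t.srna_id}\t{t.srna_sequence}\t{t.locus_id}\t{t.polarity}\t"
                f"{t.slice_genomic}\t{t.deg_score:g}\t{t.allen_score:g}\t{t.rank}\t"
                f"{t.register_bin}\t{t.round_found}\n"
            )
    with open(outdir / "phasirnas.tsv", "w") as fh:
        fh.write(head)
        fh.write("name\tlocus_id\tsequence\tlength\tstrand\tbin\toffset\tregister\tcombined_count\n")
        for r in result.annotation_result.phasirnas:
            fh.write(
                f"{r.name}\t{r.locus_id}\t{r.sequence}\t{r.length}\t{r.strand}\t"
                f"{r.bin}\t{r.offset:+d}\t{r.register_index}\t{r.combined_count}\n"
            )
    with open(outdir / "interactions.tsv", "w") as fh:
        fh.write(head)
        fh.write("srna_id\tkind\ttranscript_id\tslice_position\ttarget_deg_score\tallen\tvalidated\n")
        for ix in result.interactions:
            fh.write(
                f"{ix.srna_id}\t{ix.kind}\t{ix.transcript_id}\t{ix.slice_position}\t"
                f"{ix.target_deg_score:g}\t{ix.allen_score:g}\t{int(ix.validated)}\n"
            )
    with open(outdir / "target_sites.tsv", "w") as fh:
        fh.write(head)
        fh.write("srna_id\ttranscript_id\tchrom\tgenomic_position\tregion\n")
        for row in result.target_sites:
            fh.write(
                f"{row['srna_id']}\t{row['transcript_id']}\t{row['chrom']}\t"
                f"{row['genomic_position']}\t{row['region']}\n"
            )
    net.export_graphml(result.network, outdir / "network.graphml")
    net.export_sif(result.network, outdir / "network.sif")
    with open(outdir / "enrichment.tsv", "w") as fh:
        fh.write(head)
        fh.write("term_id\tdirection\tk\tK\tn\tN\traw_p\tcorrected_p\tsignificant\n")
        for e in result.enrichment:
            fh.write(
                f"{e.term_id}\t{e.direction}\t{e.k}\t{e.K}\t{e.n}\t{e.N}\t"
                f"{e.raw_p:.4g}\t{e.corrected_p:.4g}\t{int(e.significant)}\n"
            )
    metrics = {
        "recall": result.recall,
        "classification": result.classification,
        "correlations": {
            k: dataclasses.asdict(v) if v else None
            for k, v in result.correlations.items()
        },
    }
    if result.metrics:
        m = dataclasses.asdict(result.metrics)
        m["degree_regressions"] = {
            k: dataclasses.asdict(v) if v else None
            for k, v in result.metrics.degree_regressions.items()
        }
        m["degree_distributions"] = {
            k: {str(kk): vv for kk, vv in dist.items()}
            for k, dist in result.metrics.degree_distributions.items()
        }
        metrics["network"] = m
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1, sort_keys=True, default=str)
    with open(outdir / "pipeline_log.jsonl", "w") as fh:
        for entry in result.log:
            fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")


def _locus_feature(locus: phas.ConsensusPhasLocus, state: triggers.LocusState):
    from .features import Feature

    attrs = {"n_detections": str(locus.n_detections)}
    if state.assignment:
        attrs["assigned"] = state.assignment.assigned_id
        attrs["confidence"] = state.assignment.confidence
    return Feature(
        locus.locus_id, locus.chrom, locus.start, locus.end,
        locus.polarity if locus.polarity in "+-" else ".",
        "phas_locus", attributes=attrs,
    )
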