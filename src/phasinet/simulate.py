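"""Ground-truthed simulator for phasiRNA biogenesis cascades.

Generates a random genome with planted *PHAS* host genes, plain target
genes and miRNA precursor genes; plants a miRNA trigger with perfect
complementarity upstream of each host's phased region (the slice site
between trigger positions 10/11 sets the 21-nt register); emits phased
sense/antisense sRNA duplexes with 2-nt 3' overhangs and geometrically
decaying abundance; optionally emits a 22-nt phasiRNA at one cycle which
shifts all later cycles to a +1 register; wires cross-locus (trans)
triggering by making a phasiRNA of one locus perfectly complementary to a
site in another; and simulates sRNA-seq libraries (per-library Bernoulli
locus expression, Poisson count jitter, uniform genomic background noise)
and degradome libraries (5'-end tag peaks at every planted slice site over
a uniform background).

Every simulated non-noise read is attributable to exactly one truth
record; the same seed and config give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .features import Feature, GenomeAnnotation
from .seqio import DegradomeLibrary, SrnaLibrary, revcomp

_BASES = np.array(list("ACGT"))


class SizingError(ValueError):
    """Requested features cannot be placed on chromosomes of this length."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic compendium.

    Defaults are the standing conditions used throughout: 20 planted loci
    over 2 chromosomes, 6 sRNA + 4 degradome libraries, per-library
    expression probability 0.8, 30% background noise, one trans edge and
    one locus carrying a 22-nt register shift.
    """

    seed: int = 1
    n_chromosomes: int = 2
    chrom_length: int = 30_000
    n_phas_loci: int = 20
    n_cycles_per_locus: int = 8
    trigger_length: int = 22
    shift_cycle: int | None = 7
    shift_loci: tuple[int, ...] = (0,)
    trans_edges: tuple[tuple[int, int], ...] = ((0, 1),)
    n_srna_libraries: int = 6
    n_degradome_libraries: int = 4
    locus_expression_rate: float = 0.8
    abundance_decay: float = 0.75
    base_abundance: int = 2400
    noise_fraction: float = 0.3
    degradome_background_rate: float = 0.05
    # knobs beyond the core field list
    poisson_jitter: bool = True
    degradome_peak_count: int = 60
    n_target_genes: int = 20
    n_co_regulated: int = 3
    trigger_gu_wobble: bool = False
    noise_count_max: int = 120
    upstream_pad: int = 40
    downstream_pad: int = 30
    gene_spacing: int = 200

    def __post_init__(self) -> None:
        if not (0 <= self.noise_fraction < 1):
            raise ValueError("noise_fraction must be in [0, 1)")
        if not (0 < self.abundance_decay <= 1):
            raise ValueError("abundance_decay must be in (0, 1]")
        if self.trigger_length not in (21, 22):
            raise ValueError("trigger_length must be 21 or 22")
        if self.shift_cycle is not None and not (
            1 <= self.shift_cycle < self.n_cycles_per_locus
        ):
            raise ValueError("shift_cycle must satisfy 1 <= shift_cycle < n_cycles")
        for src, tgt in self.trans_edges:
            if not (0 <= src < self.n_phas_loci and 0 <= tgt < self.n_phas_loci):
                raise ValueError(f"trans edge ({src},{tgt}) out of range")
            if src == tgt:
                raise ValueError("trans edge source == target")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "shift_loci" in data:
            data["shift_loci"] = tuple(data["shift_loci"])
        if "trans_edges" in data:
            data["trans_edges"] = tuple(tuple(e) for e in data["trans_edges"])
        return cls(**data)


@dataclass(frozen=True)
class PlantedPhasiRna:
    """One truth phased sRNA (transcript-space window on its host)."""

    sequence: str
    strand: str  # genomic strand
    length: int
    cycle: int  # 1-based duplex cycle
    offset: int  # nt vs the main phased register (0 or +1)
    t_start: int  # 1-based transcript window start on the host
    g_start: int  # genomic leftmost
    g_end: int


@dataclass
class PlantedLocusTruth:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    trigger_sequence: str
    trigger_kind: str  # 'miRNA' or 'phasiRNA'
    slice_position: int  # genomic coord of the transcript nt 5' of the cut
    register_anchor: int  # genomic coord of the first phased 5' end
    slice_t: int  # same slice in host-transcript coordinates
    phasirna_records: list[PlantedPhasiRna] = field(default_factory=list)
    trans_targets: list[str] = field(default_factory=list)
    host_gene: str = ""


@dataclass(frozen=True)
class PlantedInteraction:
    """A planted sRNA -> transcript cleavage, the degradome's ground truth."""

    srna_sequence: str
    srna_kind: str  # 'miRNA' or 'phasiRNA'
    srna_source: str  # miRNA id, or 'locus_id:cycle:strand'
    transcript_id: str
    slice_t: int  # transcript coord of the nt 5' of the cut
    kind: str  # 'trigger' | 'trans_trigger' | 'target' | 'cotarget'
    gate_locus: str  # locus whose degradome expression flag gates the tags


@dataclass
class TruthManifest:
    config: SimulationConfig
    loci: list[PlantedLocusTruth]
    interactions: list[PlantedInteraction]
    mirnas: list[dict]  # {mirna_id, sequence, precursor_id, host_locus}
    srna_expression: list[dict[str, bool]]
    degradome_expression: list[dict[str, bool]]

    def locus(self, locus_id: str) -> PlantedLocusTruth:
        for lt in self.loci:
            if lt.locus_id == locus_id:
                return lt
        raise KeyError(locus_id)

    def expressed_in(self, locus_id: str, min_libraries: int = 3) -> bool:
        return sum(f[locus_id] for f in self.srna_expression) >= min_libraries

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "loci": [dataclasses.asdict(lt) for lt in self.loci],
            "interactions": [dataclasses.asdict(ix) for ix in self.interactions],
            "mirnas": self.mirnas,
            "srna_expression": self.srna_expression,
            "degradome_expression": self.degradome_expression,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        cfg = data["config"]
        cfg["shift_loci"] = tuple(cfg["shift_loci"])
        cfg["trans_edges"] = tuple(tuple(e) for e in cfg["trans_edges"])
        loci = []
        for d in data["loci"]:
            d["phasirna_records"] = [PlantedPhasiRna(**r) for r in d["phasirna_records"]]
            loci.append(PlantedLocusTruth(**d))
        return cls(
            config=SimulationConfig(**cfg),
            loci=loci,
            interactions=[PlantedInteraction(**d) for d in data["interactions"]],
            mirnas=data["mirnas"],
            srna_expression=data["srna_expression"],
            degradome_expression=data["degradome_expression"],
        )


# ---------------------------------------------------------------------------
# genome layout


def _host_gene_length(config: SimulationConfig, shifted: bool) -> int:
    anchor_t = config.upstream_pad + config.trigger_length - 9
    n = config.n_cycles_per_locus
    shift = 1 if shifted and config.shift_cycle is not None else 0
    last_len = 22 if shifted and config.shift_cycle == n else 21
    # last duplex's antisense partner reaches t5 + L + 1
    return anchor_t + 21 * (n - 1) + shift + last_len + 1 + config.downstream_pad


_TARGET_EXON1 = 120
_TARGET_INTRON = 60
_TARGET_EXON2 = 160
_TARGET_GLEN = _TARGET_EXON1 + _TARGET_INTRON + _TARGET_EXON2
_MIR_GLEN = 100
_MIR_MATURE_T = 30  # transcript start of the mature miRNA inside its precursor
_TARGET_SITE_T = 180  # transcript start of the planted phasiRNA site (exon 2)
_COTARGET_SITE_T = 60  # transcript start of the planted miRNA site (exon 1)


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], GenomeAnnotation]:
    """Random chromosomes with planted host / target / miRNA-precursor genes.

    Raises :class:`SizingError` when the requested features (with spacing)
    do not fit on the chromosomes.
    """
    rng = np.random.default_rng([config.seed, 1])
    n_mirna = config.n_phas_loci - len({t for _, t in config.trans_edges})

    specs: list[tuple[str, str, int]] = []  # (feature_id, kind, genomic length)
    for i in range(config.n_phas_loci):
        specs.append((f"HOST_{i:02d}", "phas_host", _host_gene_length(config, i in config.shift_loci)))
    for j in range(config.n_target_genes):
        specs.append((f"TGT_{j:02d}", "target", _TARGET_GLEN))
    for k in range(n_mirna):
        specs.append((f"MIR{k + 1:03d}", "miRNA_primary_transcript", _MIR_GLEN))

    genome = {
        f"Chr{c + 1}": "".join(rng.choice(_BASES, size=config.chrom_length))
        for c in range(config.n_chromosomes)
    }
    ann = GenomeAnnotation()
    cursors = {chrom: config.gene_spacing for chrom in genome}
    chroms = list(genome)
    for idx, (fid, kind, glen) in enumerate(specs):
        chrom = chroms[idx % len(chroms)]
        start = cursors[chrom]
        end = start + glen - 1
        if end + config.gene_spacing > config.chrom_length:
            raise SizingError(
                f"cannot place {fid} ({glen} nt) on {chrom}: "
                f"chromosome length {config.chrom_length} exhausted at {start}"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gene = Feature(fid, chrom, start, end, strand, "gene", attributes={"biotype": kind})
        ann.features.append(gene)
        if kind == "target":
            _add_target_children(ann, gene)
        else:
            ann.features.append(Feature(f"{fid}.e1", chrom, start, end, strand, "exon", parent=fid))
        cursors[chrom] = end + config.gene_spacing + 1
    return genome, ann


def _add_target_children(ann: GenomeAnnotation, gene: Feature) -> None:
    """Two exons with 5'UTR / CDS / 3'UTR structure (transcript layout:
    UTR5 1-40, CDS 41-240, UTR3 241-280; intron after transcript pos 120)."""
    s, e, st, fid, chrom = gene.start, gene.end, gene.strand, gene.feature_id, gene.chrom
    if st == "+":
        spans = {
            "exon": [(s, s + _TARGET_EXON1 - 1), (s + _TARGET_EXON1 + _TARGET_INTRON, e)],
            "five_prime_UTR": [(s, s + 39)],
            "CDS": [(s + 40, s + _TARGET_EXON1 - 1),
                    (s + _TARGET_EXON1 + _TARGET_INTRON, s + _TARGET_EXON1 + _TARGET_INTRON + 119)],
            "three_prime_UTR": [(s + _TARGET_EXON1 + _TARGET_INTRON + 120, e)],
        }
    else:
        spans = {
            "exon": [(s, s + _TARGET_EXON2 - 1), (s + _TARGET_EXON2 + _TARGET_INTRON, e)],
            "five_prime_UTR": [(e - 39, e)],
            "CDS": [(s + _TARGET_EXON2 + _TARGET_INTRON, e - 40),
                    (s + _TARGET_EXON2 - 120, s + _TARGET_EXON2 - 1)],
            "three_prime_UTR": [(s, s + _TARGET_EXON2 - 121)],
        }
    n = {"exon": 0}
    for ftype, intervals in spans.items():
        for (a, b) in sorted(intervals):
            n.setdefault(ftype, 0)
            n[ftype] += 1
            ann.features.append(
                Feature(f"{fid}.{ftype[:3]}{n[ftype]}", chrom, a, b, st, ftype, parent=fid)
            )


# ---------------------------------------------------------------------------
# cascade planting


def _write_transcript_window(
    genome: dict[str, str], ann: GenomeAnnotation, gene: Feature, t_start: int, seq: str
) -> None:
    """Overwrite genome bases so the gene's transcript carries ``seq`` at
    ``t_start``; the window must be contiguous (single-exon) in the genome."""
    g1 = ann.transcript_to_genomic(gene, t_start)
    g2 = ann.transcript_to_genomic(gene, t_start + len(seq) - 1)
    left, right = min(g1, g2), max(g1, g2)
    if right - left + 1 != len(seq):
        raise ValueError("planted window spans an intron")
    out = seq if gene.strand == "+" else revcomp(seq)
    chrom = genome[gene.chrom]
    genome[gene.chrom] = chrom[: left - 1] + out + chrom[right:]


def _gu_wobble(trigger: str, window: str) -> str:
    """Inject one G:U pair into a perfect trigger at a 3'-half position."""
    t = list(trigger)
    for i in range(13, len(trigger)):  # sRNA positions 14.. (weight 1)
        wpos = len(window) - 1 - i
        if window[wpos] == "T":
            t[i] = "G"
            return "".join(t)
        if window[wpos] == "G":
            t[i] = "T"
            return "".join(t)
    return trigger


def plant_phas_cascade(
    genome: dict[str, str], annotation: GenomeAnnotation, config: SimulationConfig
) -> TruthManifest:
    """Plant triggers, phased duplexes, trans edges, target sites; derive truth."""
    rng = np.random.default_rng([config.seed, 2])
    hosts = [g for g in annotation.genes() if g.attributes.get("biotype") == "phas_host"]
    targets = [g for g in annotation.genes() if g.attributes.get("biotype") == "target"]
    mirgenes = [g for g in annotation.genes() if g.attributes.get("biotype") == "miRNA_primary_transcript"]
    trans_target_idx = {t for _, t in config.trans_edges}

    u = config.upstream_pad
    loci: list[PlantedLocusTruth] = []
    mirnas: list[dict] = []
    interactions: list[PlantedInteraction] = []

    # (a) miRNA triggers for non-trans-target loci: perfect reverse complement
    mirna_by_locus: dict[int, dict] = {}
    k = 0
    for i, host in enumerate(hosts):
        if i in trans_target_idx:
            continue
        lt = config.trigger_length
        tseq = annotation.transcript_sequence(genome, host)
        window = tseq[u : u + lt]
        trig = revcomp(window)
        if config.trigger_gu_wobble:
            trig = _gu_wobble(trig, window)
        mir = {
            "mirna_id": f"miR{k + 1:03d}",
            "sequence": trig,
            "precursor_id": mirgenes[k].feature_id,
            "host_locus": f"PHAS_{i:02d}",
        }
        mirnas.append(mir)
        mirna_by_locus[i] = mir
        k += 1

    # (b) trans triggers: write the source phasiRNA's complement into the
    # target host's upstream trigger window (21-nt window)
    trans_trigger: dict[int, tuple[str, str]] = {}  # target idx -> (seq, source tag)
    for src, tgt in config.trans_edges:
        rec = _phasirna_layout(config, src in config.shift_loci)
        # first canonical 21-nt cycle (not the shift cycle itself)
        cyc = next(c for (c, L, off) in rec if L == 21 and off == 0)
        src_host = hosts[src]
        src_t = annotation.transcript_sequence(genome, src_host)
        anchor_t = u + config.trigger_length - 9
        t5 = anchor_t + 21 * (cyc - 1)
        pha = src_t[t5 - 1 : t5 + 20]
        _write_transcript_window(genome, annotation, hosts[tgt], u + 1, revcomp(pha))
        trans_trigger[tgt] = (pha, f"PHAS_{src:02d}:{cyc}:+")

    # (c) truth phasiRNA records for every host (genome is now final for hosts)
    for i, host in enumerate(hosts):
        shifted = i in config.shift_loci
        tseq = annotation.transcript_sequence(genome, host)
        if i in trans_trigger:
            trig, src_tag = trans_trigger[i]
            lt, kind, source = 21, "phasiRNA", src_tag
        else:
            trig = mirna_by_locus[i]["sequence"]
            lt, kind, source = config.trigger_length, "miRNA", mirna_by_locus[i]["mirna_id"]
        slice_t = u + lt - 10
        anchor_t = slice_t + 1
        records = []
        for cyc, L, off in _phasirna_layout(config, shifted):
            t5 = anchor_t + 21 * (cyc - 1) + off
            sense = tseq[t5 - 1 : t5 - 1 + L]
            anti = revcomp(tseq[t5 + 1 : t5 + 1 + L])
            for seq, tw_start, strand_rel in ((sense, t5, "+"), (anti, t5 + 2, "-")):
                g1 = annotation.transcript_to_genomic(host, tw_start)
                g2 = annotation.transcript_to_genomic(host, tw_start + L - 1)
                gstrand = strand_rel if host.strand == "+" else ("-" if strand_rel == "+" else "+")
                records.append(
                    PlantedPhasiRna(seq, gstrand, L, cyc, off, tw_start, min(g1, g2), max(g1, g2))
                )
        locus = PlantedLocusTruth(
            locus_id=f"PHAS_{i:02d}",
            chrom=host.chrom,
            start=min(r.g_start for r in records),
            end=max(r.g_end for r in records),
            strand=host.strand,
            trigger_sequence=trig,
            trigger_kind=kind,
            slice_position=annotation.transcript_to_genomic(host, slice_t),
            register_anchor=annotation.transcript_to_genomic(host, anchor_t),
            slice_t=slice_t,
            phasirna_records=records,
            host_gene=host.feature_id,
        )
        loci.append(locus)
        interactions.append(
            PlantedInteraction(
                trig, kind, source, host.feature_id, slice_t,
                "trans_trigger" if i in trans_trigger else "trigger",
                locus.locus_id,
            )
        )
    for src, tgt in config.trans_edges:
        loci[src].trans_targets.append(f"PHAS_{tgt:02d}")

    # (d) write mature miRNA sequences into their precursor genes
    for mir in mirnas:
        gene = annotation.by_id(mir["precursor_id"])
        _write_transcript_window(genome, annotation, gene, _MIR_MATURE_T, mir["sequence"])

    # (e) target sites: locus i's first canonical phasiRNA cleaves TGT_i;
    # the first n_co_regulated targets additionally carry a miRNA site
    for i, locus in enumerate(loci):
        if i >= len(targets):
            break
        rec = next(
            r for r in locus.phasirna_records
            if r.length == 21 and r.offset == 0 and r.strand == locus.strand and r.cycle >= 2
        )
        gene = targets[i]
        _write_transcript_window(genome, annotation, gene, _TARGET_SITE_T, revcomp(rec.sequence))
        interactions.append(
            PlantedInteraction(
                rec.sequence, "phasiRNA", f"{locus.locus_id}:{rec.cycle}:+",
                gene.feature_id, _TARGET_SITE_T + rec.length - 1 - 10, "target", locus.locus_id,
            )
        )
    co_sources = [i for i in range(len(loci)) if i in mirna_by_locus]
    for j in range(min(config.n_co_regulated, len(targets), len(co_sources) - 1)):
        # the miRNA site is gated on a different locus than the phasiRNA site,
        # so per-library expression can separate the two degradome peaks
        src = next(s for s in co_sources[(j + len(co_sources) // 2):] + co_sources if s != j)
        mir = mirna_by_locus[src]
        gene = targets[j]
        _write_transcript_window(
            genome, annotation, gene, _COTARGET_SITE_T, revcomp(mir["sequence"])
        )
        interactions.append(
            PlantedInteraction(
                mir["sequence"], "miRNA", mir["mirna_id"], gene.feature_id,
                _COTARGET_SITE_T + len(mir["sequence"]) - 1 - 10, "cotarget",
                f"PHAS_{src:02d}",
            )
        )

    # (f) refresh truth sequences after genome writes touching target genes /
    # precursors never overlap host phased regions, so records stand as read.
    srna_expr = [
        {lt.locus_id: bool(rng.random() < config.locus_expression_rate) for lt in loci}
        for _ in range(config.n_srna_libraries)
    ]
    deg_expr = [
        {lt.locus_id: bool(rng.random() < config.locus_expression_rate) for lt in loci}
        for _ in range(config.n_degradome_libraries)
    ]
    return TruthManifest(config, loci, interactions, mirnas, srna_expr, deg_expr)


def _phasirna_layout(config: SimulationConfig, shifted: bool) -> list[tuple[int, int, int]]:
    """(cycle, length, offset) for each duplex cycle of a locus."""
    out = []
    sc = config.shift_cycle if (shifted and config.shift_cycle is not None) else None
    for c in range(1, config.n_cycles_per_locus + 1):
        length = 22 if sc is not None and c == sc else 21
        offset = 1 if sc is not None and c > sc else 0
        out.append((c, length, offset))
    return out


# ---------------------------------------------------------------------------
# library simulation


def _expected_counts(config: SimulationConfig) -> int:
    """Signal mass of a fully expressed library with jitter off."""
    total = 0
    for i in range(config.n_phas_loci):
        for c, _, _ in _phasirna_layout(config, i in config.shift_loci):
            total += 2 * math.floor(config.base_abundance * config.abundance_decay ** (c - 1))
    return total


def simulate_srna_library(
    truth: TruthManifest,
    genome: Mapping[str, str],
    library_index: int,
    config: SimulationConfig | None = None,
) -> SrnaLibrary:
    """One collapsed sRNA-seq library.

    Expressed loci contribute their phasiRNA duplex reads with counts
    floor(base * decay^(cycle-1)), Poisson-jittered when enabled; mature
    miRNAs are constitutively present at half the base abundance; a
    noise_fraction share of the library is uniform random genomic 20-40-mers
    with uniform counts in [1, noise_count_max].
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 10, library_index])
    lib = SrnaLibrary(f"srna_{library_index:02d}", metadata={"kind": "synthetic_sRNA"})
    expr = truth.srna_expression[library_index]
    for locus in truth.loci:
        if not expr[locus.locus_id]:
            continue
        for rec in locus.phasirna_records:
            lam = config.base_abundance * config.abundance_decay ** (rec.cycle - 1)
            count = int(rng.poisson(lam)) if config.poisson_jitter else math.floor(lam)
            if count > 0:
                lib.add(rec.sequence, count)
    mir_count = config.base_abundance // 2
    for mir in truth.mirnas:
        count = int(rng.poisson(mir_count)) if config.poisson_jitter else mir_count
        if count > 0:
            lib.add(mir["sequence"], count)
    if config.noise_fraction > 0:
        target = math.floor(
            _expected_counts(config) * config.noise_fraction / (1 - config.noise_fraction)
        )
        chroms = sorted(genome)
        mass = 0
        while mass < target:
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(20, 41))
            pos = int(rng.integers(0, len(genome[chrom]) - length))
            seq = genome[chrom][pos : pos + length]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            count = int(rng.integers(1, config.noise_count_max + 1))
            lib.add(seq, count)
            mass += count
    return lib


def simulate_degradome_library(
    truth: TruthManifest,
    genome: Mapping[str, str],
    annotation: GenomeAnnotation,
    library_index: int,
    config: SimulationConfig | None = None,
) -> DegradomeLibrary:
    """One degradome library of 20-nt 5'-end tags.

    Every planted interaction whose gating locus is expressed in this
    library yields a tag peak at the slice site (transcript position
    slice+1); a uniform Poisson background of single-count tags covers each
    transcript at degradome_background_rate per position.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 20, library_index])
    lib = DegradomeLibrary(f"deg_{library_index:02d}", metadata={"kind": "synthetic_degradome"})
    expr = truth.degradome_expression[library_index]
    tseqs = {
        g.feature_id: annotation.transcript_sequence(genome, g) for g in annotation.genes()
    }
    for ix in truth.interactions:
        if not expr.get(ix.gate_locus, False):
            continue
        tseq = tseqs[ix.transcript_id]
        tag = tseq[ix.slice_t : ix.slice_t + 20]  # starts at slice + 1
        count = (
            int(rng.poisson(config.degradome_peak_count))
            if config.poisson_jitter
            else config.degradome_peak_count
        )
        if len(tag) == 20 and count > 0:
            lib.add(tag, count)
    if config.degradome_background_rate > 0:
        for gid in sorted(tseqs):
            tseq = tseqs[gid]
            if len(tseq) < 21:
                continue
            n_bg = int(rng.poisson(config.degradome_background_rate * len(tseq)))
            for _ in range(n_bg):
                pos = int(rng.integers(0, len(tseq) - 20))
                lib.add(tseq[pos : pos + 20], 1)
    return lib


def expected_interaction_scores(
    truth: TruthManifest,
    genome: Mapping[str, str],
    annotation: GenomeAnnotation,
    degradome_libraries: Sequence[DegradomeLibrary],
    weights: Mapping[int, float] | None = None,
    min_srna_libraries: int = 3,
) -> dict[tuple[str, str, int], float]:
    """Truth-derived deg_scores for every planted interaction.

    Works directly from the truth manifest and raw library tag counts (no
    alignment or profile machinery): per library, the tag count of each
    expressed planted site is looked up by its 20-mer; within a transcript
    the highest site is category 0 (1 when tied), lower expressed sites
    category 2, singleton tags category 4.  Only interactions whose sRNA the
    pipeline can know about are reported: miRNAs, and phasiRNAs from loci
    expressed in at least ``min_srna_libraries`` sRNA libraries.

    Returns {(srna_sequence, transcript_id, slice_t): expected score}.
    """
    weights = dict(weights or {0: 5.0, 1: 4.0, 2: 0.5, 3: 0.0, 4: 0.0})
    tseqs = {
        g.feature_id: annotation.transcript_sequence(genome, g)
        for g in annotation.genes()
    }
    usable = []
    for ix in truth.interactions:
        if ix.srna_kind == "phasiRNA":
            source_locus = ix.srna_source.split(":")[0]
            if not truth.expressed_in(source_locus, min_srna_libraries):
                continue
        usable.append(ix)
    by_transcript: dict[str, list[PlantedInteraction]] = {}
    for ix in usable:
        by_transcript.setdefault(ix.transcript_id, []).append(ix)
    scores: dict[tuple[str, str, int], float] = {
        (ix.srna_sequence, ix.transcript_id, ix.slice_t): 0.0 for ix in usable
    }
    for lib_index, lib in enumerate(degradome_libraries):
        expr = truth.degradome_expression[lib_index]
        for tid, ixs in by_transcript.items():
            counts = {}
            for ix in ixs:
                tag = tseqs[tid][ix.slice_t : ix.slice_t + 20]
                read = lib.reads.get(tag)
                counts[(ix.srna_sequence, tid, ix.slice_t)] = read.count if read else 0
            present = {k: c for k, c in counts.items() if c > 0}
            if not present:
                continue
            peak = max(present.values())
            n_at_peak = sum(1 for c in present.values() if c == peak)
            for key, c in present.items():
                if c == 1:
                    cat = 4
                elif c == peak:
                    cat = 0 if n_at_peak == 1 else 1
                else:
                    cat = 2
                scores[key] += weights[cat]
    return scores


def make_go_table(annotation: GenomeAnnotation, seed: int, n_terms: int = 12) -> list[tuple[str, str]]:
    """Synthetic GO-slim map: every gene gets 1-3 of ``n_terms`` flat terms."""
    rng = np.random.default_rng([seed, 30])
    terms = [f"GO:{7000 + t:07d}" for t in range(n_terms)]
    rows = []
    for gene in annotation.genes():
        for t in sorted(rng.choice(n_terms, size=int(rng.integers(1, 4)), replace=False)):
            rows.append((gene.feature_id, terms[int(t)]))
    return rows


@dataclass
class SimulatedBundle:
    """Everything one synthetic study produces, in memory."""

    genome: dict[str, str]
    annotation: GenomeAnnotation
    truth: TruthManifest
    srna_libraries: list[SrnaLibrary]
    degradome_libraries: list[DegradomeLibrary]
    go_table: list[tuple[str, str]]


def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Run the full generator for one config."""
    genome, annotation = generate_genome(config)
    truth = plant_phas_cascade(genome, annotation, config)
    srna = [
        simulate_srna_library(truth, genome, i, config)
        for i in range(config.n_srna_libraries)
    ]
    deg = [
        simulate_degradome_library(truth, genome, annotation, i, config)
        for i in range(config.n_degradome_libraries)
    ]
    return SimulatedBundle(genome, annotation, truth, srna, deg, make_go_table(annotation, config.seed))


def write_bundle(bundle: SimulatedBundle, outdir: str | Path) -> None:
    """Write a bundle as FASTA / GFF3 / JSON / TSV files."""
    from .seqio import write_genome_fasta

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome_fasta(bundle.genome, out / "genome.fa")
    bundle.annotation.to_gff3(out / "annotation.gff3")
    bundle.truth.to_json(out / "truth.json")
    bundle.truth.config.to_yaml(out / "config.yaml")
    for lib in bundle.srna_libraries:
        lib.to_fasta(out / f"{lib.library_id}.fa", prefix="sim")
    for lib in bundle.degradome_libraries:
        lib.to_fasta(out / f"{lib.library_id}.fa", prefix="tag")
    with open(out / "mirnas.tsv", "w") as fh:
        fh.write("mirna_id\tsequence\tprecursor_id\n")
        for m in bundle.truth.mirnas:
            fh.write(f"{m['mirna_id']}\t{m['sequence']}\t{m['precursor_id']}\n")
    with open(out / "go_terms.tsv", "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for gene, term in bundle.go_table:
            fh.write(f"{gene}\t{term}\n")
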