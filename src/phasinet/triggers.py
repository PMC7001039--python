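"""Trigger assignment, 21-bin phase tables and phasiRNA annotation.

For each consensus *PHAS* locus the extended interval is searched on both
strands with known miRNAs as queries; cleavage events are scored with the
multi-library deg_score and the best event at or above the minimum score
becomes the primary trigger, fixing the locus polarity (the strand the
trigger base-pairs to) and the main phased register (anchored one
nucleotide 3' of the cut).

Mapped 21/22-nt reads inside the original (pre-extension) interval are
assigned to 21 positional bins per strand; minus-strand reads are
duplex-corrected so both members of a dicer duplex share a bin.  Per
library the three most abundant bins earn 5 / 2 / 0.5 rank points, summed
across libraries.  PhasiRNAs are the reads in the trigger's register bin
and its immediate neighbours (or the top-ranked bin for triggerless
loci).  Extracted phasiRNAs pool with the miRNAs as queries for further
rounds, discovering secondary/tertiary and cross-locus triggers, until a
fixed point (at most ``max_rounds`` rounds).

PhasiRNA names encode biogenesis:  ``LOCUS(locus_strand)_REGISTER``
followed by the read strand, a parenthesised non-zero offset to the main
phased register, and ``_22`` for 22-nt products — e.g.
``AT2G39675(-)_20-(+1)`` or ``AT3G17185(+)_18+(-1)_22``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .degradome import (
    DEFAULT_WEIGHTS,
    DegradomeProfile,
    TargetAlignment,
    WeightedEventScore,
    find_target_alignments,
    score_alignment,
)
from .features import Feature, GenomeAnnotation, overlap_length
from .phas import CYCLE, ConsensusPhasLocus
from .seqio import DegradomeLibrary, ReadAlignment, revcomp

BIN_WEIGHTS = (5.0, 2.0, 0.5)


def wrap_bin(b: int) -> int:
    """Fold an integer into the 1..21 bin range."""
    return (b - 1) % CYCLE + 1


def adjacent_bins(bins: Iterable[int]) -> set[int]:
    """Each bin with its -1/+1 neighbours (mod-21 wraparound)."""
    out: set[int] = set()
    for b in bins:
        out.update({wrap_bin(b - 1), wrap_bin(b), wrap_bin(b + 1)})
    return out


def symmetric_offset(delta: int, cycle: int = CYCLE) -> int:
    """Map a register difference to the signed range -10..+10."""
    m = delta % cycle
    return m if m <= cycle // 2 else m - cycle


@dataclass(frozen=True)
class TriggerAssignment:
    srna_id: str
    srna_sequence: str
    locus_id: str
    polarity: str  # strand the trigger base-pairs to
    slice_genomic: int  # genomic coord of the transcript nt 5' of the cut
    slice_t: int  # same, in extended-locus strand coordinates
    deg_score: float
    allen_score: float
    rank: str  # primary | secondary | tertiary
    register_bin: int
    round_found: int


@dataclass
class PhasiRna:
    locus_id: str
    sequence: str
    length: int
    strand: str  # '+' = mRNA (transcript) strand, '-' = complementary
    genomic_strand: str
    eff5: int  # duplex-corrected genomic coordinate
    bin: int
    offset: int  # signed nt vs the main phased register (0 = canonical slot)
    register_index: int
    dist: int = 0  # duplex-slot distance from the locus 5' end
    combined_count: int = 0
    name: str = ""

    @property
    def canonical(self) -> bool:
        return self.length == 21 and self.offset == 0


@dataclass
class LocusAnnotation:
    locus_id: str
    assigned_id: str  # gene id, lowercased gene id, or coordinate name
    confidence: str  # confirmed | tentative | unassigned
    overlap_fraction: float
    feature_type: str
    all_matches: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class LocusState:
    """Working annotation state for one consensus locus."""

    locus: ConsensusPhasLocus
    strand_seqs: dict[str, str]
    profiles: dict[str, dict[str, DegradomeProfile]]  # strand -> lib -> profile
    alignments: list[ReadAlignment]  # 21/22-nt reads inside the original interval
    bin_tables: dict[str, dict[str, dict[int, Fraction]]]  # lib -> strand -> bins
    rank_scores: dict[int, float] = field(default_factory=dict)
    polarity: str = "unknown"
    triggers: list[TriggerAssignment] = field(default_factory=list)
    phasirnas: dict[tuple, PhasiRna] = field(default_factory=dict)
    assignment: LocusAnnotation | None = None

    @property
    def locus_id(self) -> str:
        return self.locus.locus_id

    # -- coordinate arithmetic ----------------------------------------------

    def t2g(self, strand: str, p: int) -> int:
        """Extended-locus strand coordinate -> genomic coordinate."""
        if strand == "+":
            return self.locus.extended_start + p - 1
        return self.locus.extended_end - p + 1

    def read_bin(self, eff5: int) -> int:
        return (eff5 - self.locus.start) % CYCLE + 1

    def register_bin_of_anchor(self, g_anchor: int, polarity: str) -> int:
        """Bin a canonical first-cycle 21-nt phasiRNA of this register gets."""
        eff = g_anchor if polarity == "+" else g_anchor - 22
        return self.read_bin(eff)

    def slot_dist(self, genomic_strand: str, leftmost: int, length: int, polarity: str) -> int:
        """Transcript-direction distance of a read's duplex slot from the
        locus 5' end.  The slot is the 5' end of the duplex's sense member,
        so it is independent of read length on both strands (a 22-nt
        product with an on-register 5' end has offset 0)."""
        if polarity == "-":
            sense5 = leftmost + length - 1 if genomic_strand == "-" else leftmost + length + 1
            return self.locus.end - sense5
        sense5 = leftmost if genomic_strand == "+" else leftmost - 2
        return sense5 - self.locus.start

    def anchor_dist(self) -> int:
        """Main-register anchor in transcript-distance units."""
        if self.triggers:
            t = self.triggers[0]
            g_anchor = t.slice_genomic + (1 if t.polarity == "+" else -1)
            if t.polarity == "-":
                return self.locus.end - g_anchor
            return g_anchor - self.locus.start
        top = self.top_bins(1)
        if not top:
            return 0
        pol = self.polarity if self.polarity in "+-" else "+"
        # smallest non-negative distance congruent to the top bin's phase
        for d in range(CYCLE):
            if self._dist_to_bin(d, pol) == top[0]:
                return d
        return 0

    def _dist_to_bin(self, dist: int, polarity: str) -> int:
        if polarity == "-":
            eff = self.locus.end - 22 - dist
        else:
            eff = self.locus.start + dist
        return self.read_bin(eff)

    def top_bins(self, n: int = 3) -> list[int]:
        ranked = sorted(self.rank_scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return [b for b, s in ranked[:n] if s > 0]

    def window_genomic(self, strand: str, w_start: int, w_end: int) -> tuple[int, int]:
        """Genomic interval of an extended-locus strand window."""
        a, b = self.t2g(strand, w_start), self.t2g(strand, w_end)
        return (a, b) if a <= b else (b, a)

    def register_index_of(self, dist: int, gene: Feature | None = None) -> int:
        """Register number (21-nt steps from the transcript 5' end) of a read
        slot, anchored on the main phased register so off-register trimming
        of the locus boundary cannot shift whole-register numbering."""
        m = self.anchor_dist()
        if gene is not None:
            pol = self.polarity if self.polarity in "+-" else "+"
            shift = (
                self.locus.start - gene.start if pol == "+" else gene.end - self.locus.end
            )
            dist += shift
            m += shift
        return (dist - m) // CYCLE + max(0, m) // CYCLE + 1


# ---------------------------------------------------------------------------
# bin tables


def build_phase_bins(
    locus: ConsensusPhasLocus,
    alignments: Sequence[ReadAlignment],
    library_id: str,
) -> dict[str, dict[int, Fraction]]:
    """Per-strand 21-bin fractional abundance table for one library.

    Only 21/22-nt reads whose duplex-corrected 5' end lies inside the
    original (pre-extension) interval are counted; bin index is the
    corrected 5' position modulo 21 relative to the locus start, so duplex
    partners land in the same bin on their two strand tables.
    """
    tables: dict[str, dict[int, Fraction]] = {"+": {}, "-": {}}
    for a in alignments:
        if a.reference_id != locus.chrom or a.read.length not in (21, 22):
            continue
        eff = a.effective_five_prime
        if not (locus.start <= eff <= locus.end):
            continue
        b = (eff - locus.start) % CYCLE + 1
        tables[a.strand][b] = tables[a.strand].get(b, Fraction(0)) + a.fractional_count
    return tables


def rank_bins(
    tables_by_library: Mapping[str, dict[str, dict[int, Fraction]]],
    weights: Sequence[float] = BIN_WEIGHTS,
) -> dict[int, float]:
    """Cross-library bin ranking: per library the three most abundant bins
    (strands combined) earn the rank weights; scores add over libraries.
    Abundance ties rank the lower bin index first."""
    scores: dict[int, float] = {}
    for lib in sorted(tables_by_library):
        combined: dict[int, Fraction] = {}
        for strand_table in tables_by_library[lib].values():
            for b, ab in strand_table.items():
                combined[b] = combined.get(b, Fraction(0)) + ab
        ranked = sorted(combined.items(), key=lambda kv: (-kv[1], kv[0]))
        for w, (b, ab) in zip(weights, ranked):
            if ab > 0:
                scores[b] = scores.get(b, 0.0) + w
    return scores


# ---------------------------------------------------------------------------
# triggers


def assign_primary_trigger(
    state: LocusState,
    events: Sequence[tuple[str, TargetAlignment, WeightedEventScore, str]],
    min_score: float = 10.0,
    round_found: int = 1,
) -> TriggerAssignment | None:
    """Highest-scoring event (ties: lower Allen penalty, then 5'-most slice)
    becomes the trigger and fixes locus polarity; absence is a valid outcome."""
    best = None
    for strand, aln, ws, srna_id in events:
        key = (-ws.score, aln.allen_score, aln.slice_position, strand, aln.srna_sequence)
        if best is None or key < best[0]:
            best = (key, strand, aln, ws, srna_id)
    if best is None or best[3].score < min_score:
        return None
    _, strand, aln, ws, srna_id = best
    g_slice = state.t2g(strand, aln.slice_position)
    g_anchor = g_slice + (1 if strand == "+" else -1)
    trig = TriggerAssignment(
        srna_id, aln.srna_sequence, state.locus_id, strand, g_slice,
        aln.slice_position, ws.score, aln.allen_score, "primary",
        state.register_bin_of_anchor(g_anchor, strand), round_found,
    )
    state.triggers.append(trig)
    state.polarity = strand
    state.locus.polarity = strand
    return trig


def find_secondary_triggers(
    state: LocusState,
    events: Sequence[tuple[str, TargetAlignment, WeightedEventScore, str]],
    min_score: float = 10.0,
    round_found: int = 2,
) -> list[TriggerAssignment]:
    """Additional triggers: polarity must match the primary's and the slice
    register must fall in the three top-ranked bins or their neighbours."""
    if not state.triggers:
        return []
    allowed = adjacent_bins(state.top_bins(3))
    existing = {(t.srna_sequence, t.slice_genomic) for t in state.triggers}
    rank = {2: "secondary", 3: "tertiary"}.get(round_found, "tertiary")
    found = []
    for strand, aln, ws, srna_id in sorted(
        events, key=lambda e: (-e[2].score, e[1].allen_score, e[1].slice_position)
    ):
        if ws.score < min_score or strand != state.polarity:
            continue
        g_slice = state.t2g(strand, aln.slice_position)
        if (aln.srna_sequence, g_slice) in existing:
            continue
        g_anchor = g_slice + (1 if strand == "+" else -1)
        rbin = state.register_bin_of_anchor(g_anchor, strand)
        if rbin not in allowed:
            continue
        trig = TriggerAssignment(
            srna_id, aln.srna_sequence, state.locus_id, strand, g_slice,
            aln.slice_position, ws.score, aln.allen_score, rank, rbin, round_found,
        )
        state.triggers.append(trig)
        existing.add((aln.srna_sequence, g_slice))
        found.append(trig)
    return found


# ---------------------------------------------------------------------------
# phasiRNA extraction


def extract_phasirnas(
    state: LocusState,
    raw_counts: Mapping[str, int],
) -> list[PhasiRna]:
    """Collect 21/22-nt reads from the annotated register bins (+-1).

    The register set is the union over assigned triggers (or the top-ranked
    bin when no trigger exists); offsets are measured against the main
    (primary-trigger) register anchor.  Returns newly added records.
    """
    if state.triggers:
        registers = adjacent_bins(t.register_bin for t in state.triggers)
    else:
        top = state.top_bins(1)
        if not top:
            return []
        registers = adjacent_bins(top)
    pol = state.polarity if state.polarity in "+-" else "+"
    m = state.anchor_dist()
    new: list[PhasiRna] = []
    seen_keys = set()
    for a in state.alignments:
        eff = a.effective_five_prime
        b = state.read_bin(eff)
        if b not in registers:
            continue
        key = (a.read.sequence, a.strand, eff)
        if key in seen_keys or key in state.phasirnas:
            continue
        seen_keys.add(key)
        dist = state.slot_dist(a.strand, a.start, a.read.length, pol)
        rec = PhasiRna(
            locus_id=state.locus_id,
            sequence=a.read.sequence,
            length=a.read.length,
            strand="+" if a.strand == pol else "-",
            genomic_strand=a.strand,
            eff5=eff,
            bin=b,
            offset=symmetric_offset(dist - m),
            register_index=state.register_index_of(dist),
            dist=dist,
            combined_count=raw_counts.get(a.read.sequence, 0),
        )
        state.phasirnas[key] = rec
        new.append(rec)
    return new


# ---------------------------------------------------------------------------
# recursive annotation


@dataclass
class AnnotationResult:
    states: dict[str, LocusState]
    rounds_run: int

    @property
    def phasirnas(self) -> list[PhasiRna]:
        out = []
        for lid in sorted(self.states):
            out.extend(
                self.states[lid].phasirnas[k] for k in sorted(self.states[lid].phasirnas)
            )
        return out

    @property
    def triggers(self) -> list[TriggerAssignment]:
        out = []
        for lid in sorted(self.states):
            out.extend(self.states[lid].triggers)
        return out


def prepare_locus_states(
    loci: Sequence[ConsensusPhasLocus],
    genome: Mapping[str, str],
    alignments_by_library: Mapping[str, Sequence[ReadAlignment]],
    degradome_libraries: Sequence[DegradomeLibrary],
) -> dict[str, LocusState]:
    """Precompute strand sequences, degradome profiles and bin tables."""
    states: dict[str, LocusState] = {}
    for locus in loci:
        plus = genome[locus.chrom][locus.extended_start - 1 : locus.extended_end]
        seqs = {"+": plus, "-": revcomp(plus)}
        profiles = {
            strand: {
                lib.library_id: DegradomeProfile.build(
                    f"{locus.locus_id}:{strand}", seqs[strand], lib
                )
                for lib in degradome_libraries
            }
            for strand in "+-"
        }
        local = [
            a
            for lib_aligns in alignments_by_library.values()
            for a in lib_aligns
            if a.reference_id == locus.chrom
            and a.read.length in (21, 22)
            and locus.start <= a.effective_five_prime <= locus.end
        ]
        tables = {
            lib_id: build_phase_bins(locus, aligns, lib_id)
            for lib_id, aligns in alignments_by_library.items()
        }
        state = LocusState(locus, seqs, profiles, local, tables)
        state.rank_scores = rank_bins(tables)
        states[locus.locus_id] = state
    return states


def iterate_annotation(
    states: Mapping[str, LocusState],
    mirnas: Sequence[Mapping[str, str]],
    raw_counts: Mapping[str, int],
    max_rounds: int = 3,
    min_score: float = 10.0,
    max_allen: float = 7.0,
    weights: Mapping[int, float] = DEFAULT_WEIGHTS,
) -> AnnotationResult:
    """Recursive trigger discovery to a fixed point.

    Round 1 uses known miRNAs as queries; later rounds pool all extracted
    phasiRNAs with the miRNAs.  Loci without a trigger take the best
    qualifying event as primary; loci with one accept additional triggers
    under the polarity and top-bin constraints.  Deterministic and
    invariant to library order.
    """
    query_ids: dict[str, str] = {}
    for m in mirnas:
        query_ids.setdefault(m["sequence"], m["mirna_id"])
    # genomic footprints of phasiRNA queries: a query aligned on top of its
    # own footprint is its dicer duplex, not a cleavage site, and is skipped
    footprints: dict[str, set[tuple[str, int, int]]] = {}
    event_cache: dict[tuple[str, str], list] = {}
    scanned: set[tuple[str, str]] = set()
    rounds_run = 0
    for rnd in range(1, max_rounds + 1):
        rounds_run = rnd
        changed = False
        for lid in sorted(states):
            state = states[lid]
            for qseq in query_ids:
                ck = (lid, qseq)
                if ck in scanned:
                    continue
                scanned.add(ck)
                hits = []
                for strand in "+-":
                    for aln in find_target_alignments(
                        qseq, f"{lid}:{strand}", state.strand_seqs[strand], max_allen
                    ):
                        g1, g2 = state.window_genomic(
                            strand, aln.window_start, aln.window_end
                        )
                        if any(
                            fc == state.locus.chrom and g1 <= fe and g2 >= fs
                            for fc, fs, fe in footprints.get(qseq, ())
                        ):
                            continue
                        ws = score_alignment(aln, state.profiles[strand], weights)
                        if ws.score > 0:
                            hits.append((strand, aln, ws, query_ids[qseq]))
                event_cache.setdefault((lid, qseq), []).extend(hits)
        for lid in sorted(states):
            state = states[lid]
            events = [
                e for qseq in query_ids for e in event_cache.get((lid, qseq), ())
            ]
            if not state.triggers:
                if assign_primary_trigger(state, events, min_score, rnd):
                    changed = True
            else:
                if find_secondary_triggers(state, events, min_score, rnd):
                    changed = True
            if extract_phasirnas(state, raw_counts):
                changed = True
        for lid in sorted(states):
            chrom = states[lid].locus.chrom
            for rec in states[lid].phasirnas.values():
                left = rec.eff5 if rec.genomic_strand == "+" else rec.eff5 + 2
                footprints.setdefault(rec.sequence, set()).add(
                    (chrom, left, left + rec.length - 1)
                )
                if rec.sequence not in query_ids:
                    query_ids[rec.sequence] = f"{rec.locus_id}:{rec.eff5}{rec.genomic_strand}"
                    changed = True
        if not changed:
            break
    return AnnotationResult(dict(states), rounds_run)


# ---------------------------------------------------------------------------
# nomenclature


_NAME_RE = re.compile(
    r"^(?P<label>.+)\((?P<lpol>[+-])\)_(?P<reg>\d+)(?P<rstrand>[+-])"
    r"(?:\((?P<off>[+-]?\d+)\))?(?P<is22>_22)?$"
)


def name_phasirna(
    record: PhasiRna, locus_label: str, locus_strand: str
) -> str:
    """Canonical phasiRNA name from locus label, register, strand, offset, size."""
    name = f"{locus_label}({locus_strand})_{record.register_index}{record.strand}"
    if record.offset != 0:
        name += f"({record.offset:+d})"
    if record.length == 22:
        name += "_22"
    return name


def parse_phasirna_name(name: str) -> dict:
    """Inverse of :func:`name_phasirna`; unsigned offsets parse as positive."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"malformed phasiRNA name: {name!r}")
    return {
        "locus_label": m.group("label"),
        "locus_strand": m.group("lpol"),
        "register_index": int(m.group("reg")),
        "strand": m.group("rstrand"),
        "offset": int(m.group("off")) if m.group("off") else 0,
        "length": 22 if m.group("is22") else 21,
    }


def name_all_phasirnas(
    result: AnnotationResult, annotation: GenomeAnnotation | None = None
) -> None:
    """Assign names; registers count from the assigned feature's transcript
    5' end when an assignment exists, else from the locus 5' end."""
    for lid in sorted(result.states):
        state = result.states[lid]
        gene = None
        if state.assignment is not None and state.assignment.confidence in (
            "confirmed", "tentative",
        ):
            label = state.assignment.assigned_id
            if annotation is not None:
                try:
                    gene = annotation.by_id(
                        label.upper() if label.islower() else label
                    )
                except KeyError:
                    gene = None
        else:
            label = f"{state.locus.chrom}:{state.locus.start}-{state.locus.end}"
        pol = state.polarity if state.polarity in "+-" else "+"
        for rec in state.phasirnas.values():
            if gene is not None:
                rec.register_index = state.register_index_of(rec.dist, gene)
            rec.name = name_phasirna(rec, label, pol)


# ---------------------------------------------------------------------------
# feature assignment & evaluation


def assign_locus_feature(
    state: LocusState,
    annotation: GenomeAnnotation,
    min_overlap: float = 0.70,
) -> LocusAnnotation:
    """Assign the locus to an annotated feature by >70% overlap.

    Overlap fraction uses the end-minus-start length convention.  With
    known polarity a matching-strand feature is a confirmed assignment;
    without a trigger the polarity check is waived and the assignment is
    tentative, notated in lowercase; otherwise the locus keeps a
    coordinate name.  All super-threshold features are reported; the
    greatest overlap is principal.
    """
    locus = state.locus
    length = max(1, locus.end - locus.start)
    matches: list[tuple[Feature, float]] = []
    for gene in annotation.genes():
        if gene.chrom != locus.chrom:
            continue
        ov = overlap_length(locus.start, locus.end, gene.start, gene.end)
        frac = ov / length
        if frac > min_overlap:
            matches.append((gene, frac))
    matches.sort(key=lambda gf: (-gf[1], gf[0].feature_id))
    coord_name = f"{locus.chrom}:{locus.start}-{locus.end}"
    if not matches:
        ann = LocusAnnotation(locus.locus_id, coord_name, "unassigned", 0.0, ".")
    elif state.polarity in "+-":
        stranded = [(g, f) for g, f in matches if g.strand == state.polarity]
        if stranded:
            g, f = stranded[0]
            ann = LocusAnnotation(
                locus.locus_id, g.feature_id, "confirmed", f,
                g.attributes.get("biotype", g.ftype),
                [(x.feature_id, xf) for x, xf in matches],
            )
        else:
            ann = LocusAnnotation(
                locus.locus_id, coord_name, "unassigned", matches[0][1], ".",
                [(x.feature_id, xf) for x, xf in matches],
            )
    else:
        g, f = matches[0]
        ann = LocusAnnotation(
            locus.locus_id, g.feature_id.lower(), "tentative", f,
            g.attributes.get("biotype", g.ftype),
            [(x.feature_id, xf) for x, xf in matches],
        )
    state.assignment = ann
    return ann


def evaluate_annotation_recall(
    result: AnnotationResult,
    alignments_by_library: Mapping[str, Sequence[ReadAlignment]],
) -> float:
    """Fraction of 21/22-nt read abundance inside locus regions that falls
    in the annotated register bins."""
    total = Fraction(0)
    hit = Fraction(0)
    for state in result.states.values():
        if state.triggers:
            registers = adjacent_bins(t.register_bin for t in state.triggers)
        else:
            registers = adjacent_bins(state.top_bins(1))
        locus = state.locus
        for aligns in alignments_by_library.values():
            for a in aligns:
                if a.reference_id != locus.chrom or a.read.length not in (21, 22):
                    continue
                eff = a.effective_five_prime
                if not (locus.start <= eff <= locus.end):
                    continue
                total += a.fractional_count
                if state.read_bin(eff) in registers:
                    hit += a.fractional_count
    if total == 0:
        raise ValueError("no reads in locus regions")
    return float(hit / total)


def classify_phasirnas(records: Iterable[PhasiRna]) -> dict[str, int]:
    """Four-way tabulation over size (21/22) x register (canonical or not)."""
    counts = {
        "21_canonical": 0,
        "21_noncanonical": 0,
        "22_canonical": 0,
        "22_noncanonical": 0,
    }
    for r in records:
        size = "21" if r.length == 21 else "22"
        kind = "canonical" if r.canonical else "noncanonical"
        counts[f"{size}_{kind}"] += 1
    return counts
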