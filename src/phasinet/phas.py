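"""Per-library phasing detection and cross-library consensus *PHAS* loci.

Detection runs per library over high-accumulation candidate regions
(coverage islands, gaps up to one 21-nt cycle bridged; only the top
fraction by fractional abundance is analysed).  A sliding window of 11
cycles (231 nt, step 21) is scored with

    S = (k - 2) * ln(1 + 10 P / (1 + U))   for k >= 3, else 0

where the 21 positional registers of the window are occupied by the
duplex-corrected 5' ends of 21-nt reads, P is the fractional abundance in
the dominant register, k the number of distinct occupied cycles in it, and
U the 21-nt abundance outside it.  Qualifying windows merge into
per-library calls; calls overlapping across libraries merge into
maximum-length consensus loci, kept when detected in at least
``min_libraries`` libraries and padded by 220 nt per side for the trigger
search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .seqio import ReadAlignment

CYCLE = 21


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int
    end: int
    total_abundance: Fraction


@dataclass(frozen=True)
class WindowScore:
    chrom: str
    start: int
    end: int
    score: float
    dominant_register: int  # 0..20, phase of the 5' ends relative to window start


@dataclass(frozen=True)
class PhasLocusCall:
    library_id: str
    chrom: str
    start: int
    end: int
    phasing_score: float
    dominant_register: int  # 0..20 relative to call start


@dataclass
class ConsensusPhasLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    n_detections: int
    extended_start: int = 0
    extended_end: int = 0
    polarity: str = "unknown"
    contributing: list[PhasLocusCall] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start  # end-minus-start convention


def select_candidate_regions(
    alignments: Sequence[ReadAlignment],
    top_fraction: float = 0.15,
    max_gap: int = CYCLE,
) -> list[CandidateRegion]:
    """Coverage islands ranked by abundance; top ceil(fraction * n) returned.

    Islands are maximal runs of covered positions merged across gaps of at
    most ``max_gap`` nt; each alignment's fractional count accrues to the
    island holding its leftmost coordinate.  Ties at the cutoff break
    deterministically toward lower (chrom, start).
    """
    if not alignments:
        return []
    by_chrom: dict[str, list[ReadAlignment]] = {}
    for a in alignments:
        by_chrom.setdefault(a.reference_id, []).append(a)
    islands: list[CandidateRegion] = []
    for chrom in sorted(by_chrom):
        aligns = sorted(by_chrom[chrom], key=lambda a: a.start)
        cur_start, cur_end = aligns[0].start, aligns[0].end
        cur_ab = Fraction(0)
        for a in aligns:
            if a.start > cur_end + max_gap:
                islands.append(CandidateRegion(chrom, cur_start, cur_end, cur_ab))
                cur_start, cur_end, cur_ab = a.start, a.end, Fraction(0)
            cur_end = max(cur_end, a.end)
            cur_ab += a.fractional_count
        islands.append(CandidateRegion(chrom, cur_start, cur_end, cur_ab))
    n_keep = max(1, math.ceil(top_fraction * len(islands)))
    ranked = sorted(islands, key=lambda r: (-r.total_abundance, r.chrom, r.start))
    return sorted(ranked[:n_keep], key=lambda r: (r.chrom, r.start))


def phasing_score(
    region: CandidateRegion,
    alignments: Sequence[ReadAlignment],
    cycle: int = CYCLE,
    window_cycles: int = 11,
) -> list[WindowScore]:
    """Sliding-window phasing scores over one candidate region.

    Only 21-nt reads enter P/U; effective 5' ends are duplex-corrected
    (minus-strand leftmost - 2).  Windows step by one cycle; a region
    shorter than the window is scored as a single window.
    """
    win = cycle * window_cycles
    reads = [
        (a.effective_five_prime, a.fractional_count)
        for a in alignments
        if a.reference_id == region.chrom
        and a.read.length == cycle
        and region.start <= a.effective_five_prime <= region.end
    ]
    scores: list[WindowScore] = []
    starts = range(region.start, max(region.start, region.end - win + 1) + 1, cycle)
    for w_start in starts:
        w_end = min(w_start + win - 1, region.end)
        in_win = [(p, c) for p, c in reads if w_start <= p <= w_end]
        if not in_win:
            scores.append(WindowScore(region.chrom, w_start, w_end, 0.0, 0))
            continue
        p_reg: dict[int, Fraction] = {}
        occ: dict[int, set[int]] = {}
        total = Fraction(0)
        for pos, cnt in in_win:
            reg = (pos - w_start) % cycle
            p_reg[reg] = p_reg.get(reg, Fraction(0)) + cnt
            occ.setdefault(reg, set()).add((pos - w_start) // cycle)
            total += cnt
        dom = min(p_reg, key=lambda r: (-p_reg[r], r))
        k = len(occ[dom])
        p = float(p_reg[dom])
        u = float(total - p_reg[dom])
        s = (k - 2) * math.log(1 + 10 * p / (1 + u)) if k >= 3 and p > 0 else 0.0
        scores.append(WindowScore(region.chrom, w_start, w_end, s, dom))
    return scores


def call_phas_loci(
    library_id: str,
    regions: Iterable[CandidateRegion],
    alignments: Sequence[ReadAlignment],
    min_score: float = 15.0,
    cycle: int = CYCLE,
    window_cycles: int = 11,
) -> list[PhasLocusCall]:
    """Merge qualifying windows into per-library locus calls.

    Boundaries are trimmed to the outermost duplex-corrected 5' ends of
    reads in the dominant register or its immediately adjacent registers
    (the +-1 convention used throughout, so 22-nt-induced register shifts
    stay inside the call).
    """
    calls: list[PhasLocusCall] = []
    for region in regions:
        windows = phasing_score(region, alignments, cycle, window_cycles)
        qual = [w for w in windows if w.score >= min_score]
        if not qual:
            continue
        runs: list[list[WindowScore]] = [[qual[0]]]
        for w in qual[1:]:
            if w.start <= runs[-1][-1].end + 1:
                runs[-1].append(w)
            else:
                runs.append([w])
        for run in runs:
            best = max(run, key=lambda w: w.score)
            span_start, span_end = run[0].start, run[-1].end
            # registers expressed relative to span start
            dom = (best.start - span_start + best.dominant_register) % cycle
            keep = {dom, (dom - 1) % cycle, (dom + 1) % cycle}
            positions = [
                a.effective_five_prime
                for a in alignments
                if a.reference_id == region.chrom
                and a.read.length in (21, 22)
                and span_start <= a.effective_five_prime <= span_end
                and (a.effective_five_prime - span_start) % cycle in keep
            ]
            if not positions:
                continue
            start = min(positions)
            end = max(positions) + cycle - 1
            calls.append(
                PhasLocusCall(
                    library_id, region.chrom, start, end, best.score,
                    (best.start - start + best.dominant_register) % cycle,
                )
            )
    return sorted(calls, key=lambda c: (c.chrom, c.start, c.end))


def merge_consensus(
    calls: Iterable[PhasLocusCall], min_libraries: int = 3
) -> list[ConsensusPhasLocus]:
    """Union-merge overlapping per-library calls into maximum-length loci.

    Merging ignores strand; loci detected in fewer than ``min_libraries``
    distinct libraries are discarded.  Locus ids are assigned in
    (chrom, start) order.  Idempotent and invariant to call order.
    """
    by_chrom: dict[str, list[PhasLocusCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    merged: list[ConsensusPhasLocus] = []
    for chrom in sorted(by_chrom):
        chunk = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end, c.library_id))
        cur: list[PhasLocusCall] = []
        cur_end = -1
        for c in chunk:
            if cur and c.start > cur_end:
                merged.append(_consensus_from(cur))
                cur = []
            cur.append(c)
            cur_end = max(cur_end, c.end)
        if cur:
            merged.append(_consensus_from(cur))
    kept = [m for m in merged if m.n_detections >= min_libraries]
    kept.sort(key=lambda m: (m.chrom, m.start, m.end))
    for i, m in enumerate(kept):
        m.locus_id = f"PHASL_{i:03d}"
    return kept


def _consensus_from(calls: list[PhasLocusCall]) -> ConsensusPhasLocus:
    return ConsensusPhasLocus(
        locus_id="",
        chrom=calls[0].chrom,
        start=min(c.start for c in calls),
        end=max(c.end for c in calls),
        n_detections=len({c.library_id for c in calls}),
        contributing=list(calls),
    )


def extend_loci(
    loci: Iterable[ConsensusPhasLocus],
    chrom_lengths: Mapping[str, int],
    pad: int = 220,
) -> list[ConsensusPhasLocus]:
    """Pad each locus by ``pad`` nt per side, clamped to the chromosome."""
    out = []
    for locus in loci:
        out.append(
            replace(
                locus,
                extended_start=max(1, locus.start - pad),
                extended_end=min(chrom_lengths[locus.chrom], locus.end + pad),
            )
        )
    return out


def write_locus_bed(loci: Iterable[ConsensusPhasLocus], path) -> None:
    """BED-like TSV (1-based inclusive coordinates as used throughout)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlocus_id\tn_detections\tpolarity\n")
        for m in loci:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.locus_id}\t{m.n_detections}\t{m.polarity}\n")
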