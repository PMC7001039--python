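# Methods

## Overview

phasinet reconstructs a plant sRNA regulatory network in five coupled
stages: (1) preprocessing and exact mapping of collapsed sRNA-seq reads,
(2) per-library phasing detection and cross-library consensus of *PHAS*
loci, (3) degradome-supported recursive trigger assignment with phase-bin
bookkeeping and phasiRNA extraction, (4) genome-wide degradome validation
of sRNA→transcript interactions, and (5) bipartite network assembly with
structural and functional summaries.  A synthetic-data generator plays
the role of the multi-library sequencing compendium such a study needs,
with full ground truth.

## Coordinates, slices and registers

All coordinates are 1-based inclusive (GFF3 convention); the leftmost
coordinate is reported for reads on either strand.  Locus/feature overlap
lengths follow the end-minus-start convention (a locus `[s, e]` has
length `e − s`), which is how published locus tables tabulate overlap.

An sRNA cleaves its target between the nucleotides paired to sRNA
positions 10 and 11.  We store `slice_position` as the transcript
nucleotide immediately 5′ of the cut (paired to position 11).  Two
derived positions follow: the degradome 5′-tag peak of a true cleavage
and the first phased 5′ end (the register anchor) both sit at
`slice_position + 1`.  Fixing this convention in one place keeps the
trigger search, the degradome categoriser and the register arithmetic
mutually consistent.

Phase bins: 21 positional classes per strand, indexed by the
duplex-corrected 5′ end modulo 21 relative to the consensus-locus start.
The duplex correction maps a minus-strand read to `leftmost − 2`, the
position of its sense partner's 5′ end under the 2-nt 3′ overhang
geometry; this is the testable content of the "+2 shift" for reverse
reads (the sign depends on which coordinate an aligner reports, so the
package pins the convention with a duplex-invariant property test rather
than a sign).  Register *offsets* are measured between duplex slots — the
sense member's 5′ end — which, unlike the bin coordinate, is independent
of read length on both strands; a 22-nt product whose 5′ end is
on-register therefore has offset 0, and products downstream of it carry
offset +1.  Offsets are mapped to −10..+10 by symmetric modular
arithmetic, matching the printed `(+1)/(−1)/(2)` forms.

Register numbers for naming count 21-nt steps from the transcript 5′ end
(the assigned feature when one exists, else the locus boundary), anchored
on the main phased register so that a locus boundary trimmed a few
nucleotides off-register cannot shift whole-register numbering.

## Phasing statistic

The per-library detector scores sliding windows of 11 cycles (231 nt,
step 21) with `S = (k − 2)·ln(1 + 10·P/(1 + U))` for `k ≥ 3`, else 0,
where P is the fractional 21-nt abundance in the window's dominant
register, k its number of distinct occupied cycles and U the 21-nt
abundance outside it.  This family is a standard phasing score: monotone
in occupancy and in signal-to-noise, with a default call threshold of 15.
Candidate regions are coverage islands (gaps ≤ 21 nt bridged, one duplex
cycle as the natural granularity) ranked by fractional abundance; the top
15% (ceiling, at least one) are scanned.  Call boundaries are trimmed to
the outermost duplex-corrected 5′ ends in the dominant register *or its
immediate neighbours* — the same ±1 adjacency used everywhere else — so
that the +1-shifted tail downstream of a 22-nt phasiRNA stays inside the
call.  Trimming to the dominant register alone would truncate exactly the
non-canonical products the method is designed to keep.

Ties break lexicographically everywhere: (chrom, start, end) for
intervals, lower bin index for equal abundance, and
(score desc, penalty asc, 5′-most slice) for trigger events.

## Degradome scoring

Complementarity is ungapped with the Allen penalty convention (mismatch
1.0, G:U wobble 0.5, doubled over sRNA positions 2–13); the default
search ceiling is 7.0 — a conventional, permissive cut for plant
miRNA-target duplexes, recorded here as a package default.  Degradome
tags are matched to transcripts by exact alignment of their first 20 nt.
Categories per library: 0 unique transcript-wide maximum, 1 shared
maximum, 2 above the median of occupied positions, 3 the rest, 4
singleton tags; weights 5/4/0.5/0/0 summed across libraries give the
deg_score (triggers, minimum 10) and target_deg_score (targets, minimum
15 — a stringent cut corresponding to roughly the 1% ECDF tail of event
scores in large multi-library compendia; the ECDF threshold utility
returns the smallest observed score whose left-ECDF reaches the
quantile).

One subtlety the trigger search must handle: every phasiRNA aligns
perfectly to the opposite strand of its own genomic footprint — that
alignment is its dicer duplex, not a cleavage site, and planted-sequence
identity can place real degradome tags under it.  Query alignments whose
genomic window overlaps the query's own footprint are therefore excluded
from trigger evidence.  Genuine cis-targeting of a progenitor transcript
at a *different* position (the athTAS1c-D6 pattern) is unaffected.

Recursive annotation runs at most 3 rounds: miRNA queries first, then
miRNAs plus all extracted phasiRNAs.  A locus without a trigger takes the
best qualifying event in any round (this is how a trans cascade A→B is
discovered in round 2, when A's phasiRNAs first become queries); a locus
with a primary trigger accepts additional triggers only with matching
polarity and a slice register inside the three top-ranked bins ±1.  The
iteration is deterministic, invariant to library order, and stops at a
fixed point.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes:

- **Layout** — 2 chromosomes × 30 kb of uniform random sequence carrying
  20 *PHAS* host genes, 20 two-exon target genes (5′UTR/CDS/3′UTR
  structure, 60-nt intron) and one miRNA precursor per miRNA-triggered
  locus, on both strands.
- **Cascade** — each host gets a trigger with perfect complementarity
  (22-nt miRNA by default; an optional knob injects one G:U), the cut
  between trigger positions 10/11, and 8 phased duplex cycles downstream:
  sense/antisense pairs with 2-nt 3′ overhangs, abundance
  `⌊2400 · 0.75^(cycle−1)⌋` with optional Poisson jitter.  One locus
  emits a 22-nt phasiRNA at cycle 7, shifting later cycles to offset +1.
  One trans edge makes a canonical phasiRNA of locus 0 perfectly
  complementary to a site upstream of locus 1's phased region; locus 1
  has no miRNA trigger of its own.  Each locus's first canonical
  phasiRNA also targets one plain gene, and a few targets additionally
  carry a miRNA site gated on a different locus, creating potential
  miRNA/phasiRNA co-regulation.
- **sRNA libraries** — per-library Bernoulli(0.8) locus expression;
  mature miRNAs constitutively present at half the base abundance (they
  must clear the 50-copy candidate filter, as real miRNAs would); 30% of
  the library mass is uniform genomic noise, 20–40 nt, random strand,
  counts uniform on 1..120 so the abundance filter is exercised on both
  sides.  Noise mass is budgeted against the expected (not realised)
  signal so a zero-expression control still contains noise.
- **Degradome libraries** — a 20-nt 5′-tag at every planted slice site of
  every expressed interaction (Poisson around 60 copies), over a uniform
  background of singleton tags at 0.05 tags/nt.

Two generator constants deserve comment.  The base abundance (2400) sets
the signal-to-filter ratio so that all eight cycles survive the 50-copy
filter while the 30% noise share still produces a many-island landscape
in which the top-15% region cut is a real constraint (roughly 150–200
islands per library).  The shift cycle defaults to 7 of 8 because a
mid-locus register shift splits the locus into two short runs neither of
which can pass a k≥3-cycle window at threshold 15 — consistent with the
biology that motivated the shift (a late-cycle 22-nt product in the
TAS1c cascade); the shift position is per-locus configurable.

What the generator does **not** emulate: sequencing errors, adapter
artifacts, RNA secondary structure, hairpin miRNA biogenesis,
non-cleavage (translational) repression, NAT-siRNA biogenesis, and the
tissue/condition heterogeneity of a real compendium.  Passing tests
therefore demonstrate the pipeline's arithmetic and inference logic, not
its robustness to platform noise.

## Evaluation conventions

Recovery denominators are conditioned on attainability, mirroring the
detection thresholds themselves: locus recovery is measured over loci
expressed in ≥ 3 sRNA libraries (the consensus filter), trigger recovery
over loci whose degradome evidence spans ≥ 2 libraries (two category-0
events are the minimum that reaches deg_score 10), and interaction
validation over sRNAs the pipeline can know about.  Within-transcript
peak competition is real: only a transcript's maximal peak can be
category 0, so when two planted sites share a transcript the weaker site
may be structurally unable to reach the validation threshold with few
libraries.  The validation check therefore compares the pipeline's
validated set against a truth-derived oracle computed directly from the
manifest and raw tag counts (no alignment or profile machinery), which
applies the same category arithmetic to the planted sites.

## Numerical and degenerate-input choices

Fractional multimapper counts are exact `fractions.Fraction`s end to end,
making count-conservation invariants bit-exact.  Empty inputs are
non-errors where a valid empty result exists (collapsing an empty read
list, merging zero calls) and errors where the quantity is undefined
(ECDF of no scores, density of a < 2-node graph, Pearson correlation of a
constant vector).  The degree-frequency regression uses base-10 logs and
drops degree classes with zero frequency; the clustering coefficient is
averaged over all nodes of the undirected projection (degree < 2
contributing 0).  GO enrichment runs over- and under-representation as
two one-sided hypergeometric families, each Benjamini–Hochberg corrected.

## Problem sizes

The default study — 60 kb of genome, 20 loci, 6 + 4 libraries, ~2,600
alignments per run — was chosen so a full pipeline execution takes a few
seconds and the complete test suite under half a minute, while every
stage still faces a non-trivial instance (multi-island ranking,
multimapping reads, competing degradome peaks, a trans cascade, a
register shift).

## Known limitations

- Exact-match mapping only; one mismatch loses a read.  Real data would
  first pass through adapter and quality trimming, which this package
  only stubs (an optional exact-prefix 3' trimmer and a 5' clip).
- Ungapped target alignment; bulged duplexes (GSTAr-style) are out of
  scope.
- The phasing statistic replaces an external tool whose internal score is
  unpublished; absolute score values are not comparable to it, only the
  ranking behaviour is.
- Within-transcript peak competition caps sensitivity for multi-site
  transcripts at small library counts (see Evaluation conventions).
- The GO layer treats the slim vocabulary as flat; no DAG propagation.
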