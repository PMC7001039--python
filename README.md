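# phasinet

Genome-wide, degradome-supported inference of plant small-RNA regulatory
networks: detection of phasiRNA-producing (*PHAS*) loci from collapsed
sRNA-seq libraries, recursive identification of their cleavage triggers,
extraction and naming of canonical and non-canonical phasiRNAs,
genome-wide validation of sRNA→transcript interactions, and construction
and analysis of the resulting bipartite regulatory network.  A seeded
synthetic-data generator provides ground-truthed genomes, libraries and
degradome data so that every stage is testable without downloads.

The package is aimed at computational biologists studying
post-transcriptional gene silencing in plants — miRNA/phasiRNA cascades
such as miR173–TAS–PPR — who want a reproducible, scriptable pipeline
rather than a chain of GUI tools.

## The method

**PHAS locus detection.** Reads are collapsed to unique sequences with
counts, constrained to 20–40 nt, and sequences with fewer than 50 copies
are removed; libraries with fewer than 100 unique sequences are dropped.
21/22-nt reads are mapped exactly to both genomic strands; a read at *n*
locations contributes count/*n* at each (reads at more than 10 locations
are discarded).  Per library, coverage islands are ranked by abundance and
the top 15% are scanned with an 11-cycle (231-nt) sliding window.  With
*P* the fractional abundance of 21-nt reads in the dominant 21-nt
register, *U* the abundance outside it and *k* the number of occupied
cycles, the window score is

    S = (k − 2) · ln(1 + 10·P / (1 + U)),   k ≥ 3

and windows with S ≥ 15 become calls.  Calls merge across libraries into
maximum-length consensus loci; loci seen in fewer than 3 libraries are
discarded, and survivors are extended by 220 nt per side.

**Triggers and phasiRNAs.** Both strands of each extended locus are
searched with known miRNAs under an ungapped complementarity penalty
(mismatch 1, G:U wobble 0.5, doubled over sRNA positions 2–13).  Each
candidate slice site (between the target nucleotides paired to sRNA
positions 10 and 11) is checked against every degradome library: the
5′-tag count at the site is categorised against the transcript-wide
profile (0 unique maximum, 1 shared maximum, 2 above the median of
occupied positions, 4 singleton) and weighted 5/4/0.5/0/0; weights sum
across libraries into the deg_score.  The best event with deg_score ≥ 10
becomes the primary trigger, fixing locus polarity and the phased
register.  Reads in the register bin ±1 (21 bins per strand, minus-strand
reads duplex-corrected for the 2-nt 3′ overhang) become phasiRNAs, named
`LOCUS(locus_strand)_REGISTER read_strand (offset) [_22]` — e.g.
`AT2G39675(-)_20-(+1)`.  PhasiRNAs pool with the miRNAs as queries for up
to two further rounds, discovering secondary, tertiary and cross-locus
(trans) triggers.

**Targets and network.** Annotated sRNAs with ≥ 50 combined raw counts
are scored against every transcript; interactions with a summed
target_deg_score ≥ 15 (a stringent cut selecting roughly the 1% ECDF
tail of event scores in large compendia) are validated.  Active sRNAs, their precursors and targets form a directed
bipartite network (biogenesis edges transcript→sRNA, cleavage edges
sRNA→transcript) summarised by weakly connected components, density,
clustering, per-class degree distributions with log–log degree-frequency
regression, and GO-slim hypergeometric over/under-representation with
Benjamini–Hochberg correction.

## Worked example

```python
import phasinet as pn

bundle = pn.simulate_bundle(pn.SimulationConfig(seed=1))
result = pn.run_pipeline(pn.PipelineInputs.from_bundle(bundle))
```

Running the scripts in `examples/` on this study prints:

```
consensus loci (detected in >= 3 of 6 libraries): 19
  PHASL_000 Chr1:230-398 seen in 6 libraries
triggers assigned: 19 over 19 loci
  trans trigger for PHASL_010: PHASL_000:378- (deg_score 10, found in round 2)
phasiRNAs extracted: 309
classification: {'21_canonical': 300, '21_noncanonical': 4, '22_canonical': 0, '22_noncanonical': 5}
  HOST_00(-)_9+_22  len=22 offset=+0
  HOST_00(-)_10+(+1)  len=21 offset=+1
annotation recall: 0.968
validated interactions: 31 of 43 scored
network: 89 nodes, 60 edges (29 biogenesis, 31 cleavage)
weakly connected components: 29; density 0.0077; clustering 0.0000
```

Nineteen of the 20 planted loci are recovered (the twentieth is expressed
in only two libraries and is dropped by design); the planted trans
cascade is found in round 2; the one 22-nt-emitting locus yields `_22`
products at offset 0 and `(+1)`-shifted products afterwards, exactly as
planted.  Recall is the fraction of locus-region read abundance falling
in annotated registers.

The same run is available from a shell:

```bash
phasinet simulate --out bundle/
phasinet run-all --indir bundle/ --out run/
phasinet network --rundir run/
```

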