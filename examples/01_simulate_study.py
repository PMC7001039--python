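"""Generate a ground-truthed synthetic phasiRNA study.

Builds a random two-chromosome genome with 20 planted *PHAS* host genes,
plain target genes and miRNA precursors, then simulates 6 collapsed
sRNA-seq libraries and 4 degradome libraries.  Every phased read, trigger
and cleavage site is recorded in a truth manifest."""

import phasinet as pn

config = pn.SimulationConfig(seed=1)
bundle = pn.simulate_bundle(config)
truth = bundle.truth

print(f"chromosomes: {list(bundle.genome)} of {config.chrom_length} nt")
print(f"planted PHAS loci: {len(truth.loci)} "
      f"(one with a 22-nt register shift at cycle {config.shift_cycle}, "
      f"trans edges: {config.trans_edges})")
print(f"planted interactions (trigger/target/cotarget): {len(truth.interactions)}")
lib = bundle.srna_libraries[0]
print(f"sRNA library 0: {lib.n_unique} unique reads, {lib.total_reads} total copies")
deg = bundle.degradome_libraries[0]
print(f"degradome library 0: {deg.n_unique} unique 5'-end tags")

lt = truth.loci[0]
print(f"\nlocus {lt.locus_id} on {lt.chrom}:{lt.start}-{lt.end} ({lt.strand}), "
      f"triggered by a {len(lt.trigger_sequence)}-nt {lt.trigger_kind}")
print(f"  cut 5' of {lt.slice_position}; first phased 5' end at {lt.register_anchor}")
for rec in lt.phasirna_records[:4]:
    print(f"  cycle {rec.cycle} ({rec.strand}) offset {rec.offset:+d}: {rec.sequence}")
# The three leading numbers describe where phasing starts; each cycle line is
# one strand of a dicer duplex, 21 nt downstream of the previous cycle.
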