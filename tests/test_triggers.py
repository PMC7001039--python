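"""Phase bins, trigger assignment, phasiRNA extraction, nomenclature."""

from fractions import Fraction

import numpy as np
import pytest

import phasinet as pn
from phasinet.degradome import TargetAlignment, WeightedEventScore
from phasinet.phas import ConsensusPhasLocus
from phasinet.seqio import ReadAlignment, UniqueRead
from phasinet.triggers import (
    LocusState,
    adjacent_bins,
    assign_locus_feature,
    assign_primary_trigger,
    build_phase_bins,
    classify_phasirnas,
    extract_phasirnas,
    find_secondary_triggers,
    name_phasirna,
    parse_phasirna_name,
    rank_bins,
    symmetric_offset,
)
from phasinet.features import Feature, GenomeAnnotation
from conftest import locus_state_for


def locus(start=1000, end=1200, chrom="Chr1", pol="unknown"):
    lo = ConsensusPhasLocus("PHASL_000", chrom, start, end, 3)
    lo.extended_start, lo.extended_end, lo.polarity = start - 220, end + 220, pol
    return lo


def aln(start, strand="+", count=100, length=21, chrom="Chr1"):
    return ReadAlignment(
        UniqueRead("A" * length, count), chrom, start, strand, 1, Fraction(count)
    )


def make_state(lo, **kw):
    state = LocusState(lo, {"+": "", "-": ""}, {"+": {}, "-": {}}, [], {})
    for k, v in kw.items():
        setattr(state, k, v)
    return state


class TestPhaseBins:
    def test_forward_read_bin_arithmetic(self):
        lo = locus(start=1000)
        tables = build_phase_bins(lo, [aln(1000), aln(1021), aln(1001)], "lib")
        assert tables["+"] == {1: Fraction(200), 2: Fraction(100)}

    def test_duplex_partner_lands_in_same_bin(self):
        lo = locus(start=1000)
        # sense read at x=1000 spans [1000,1020]; partner covers [1002,1022]
        tables = build_phase_bins(lo, [aln(1000, "+"), aln(1002, "-")], "lib")
        assert tables["+"] == {1: Fraction(100)}
        assert tables["-"] == {1: Fraction(100)}

    def test_duplex_invariant_for_random_duplexes(self):
        """Both members of a 2-nt 3' overhang duplex share a bin, for 21-
        and 22-nt products anywhere in the locus."""
        rng = np.random.default_rng(8)
        lo = locus(start=1000, end=1500)
        for _ in range(200):
            x = int(rng.integers(1000, 1450))
            L = int(rng.integers(21, 23))
            t = build_phase_bins(
                lo, [aln(x, "+", length=L), aln(x + 2, "-", length=L)], "lib"
            )
            assert list(t["+"]) == list(t["-"])

    def test_reads_outside_original_interval_excluded(self):
        lo = locus(start=1000, end=1200)
        tables = build_phase_bins(lo, [aln(990), aln(1250)], "lib")
        assert tables["+"] == {} and tables["-"] == {}

    def test_binned_abundance_conserves_fractional_counts(self, pipeline_result):
        for state in pipeline_result.annotation_result.states.values():
            for lib_id, tables in state.bin_tables.items():
                binned = sum(ab for t in tables.values() for ab in t.values())
                direct = sum(
                    a.fractional_count
                    for a in pipeline_result.alignments.get(lib_id, [])
                    if a.reference_id == state.locus.chrom
                    and state.locus.start <= a.effective_five_prime <= state.locus.end
                )
                assert binned == direct


class TestRankBins:
    def test_top_three_weights(self):
        tables = {"lib1": {"+": {3: Fraction(100), 10: Fraction(50), 1: Fraction(10)}, "-": {}}}
        assert rank_bins(tables) == {3: 5.0, 10: 2.0, 1: 0.5}

    def test_two_identical_libraries_double_the_scores(self):
        t = {"+": {3: Fraction(100), 10: Fraction(50), 1: Fraction(10)}, "-": {}}
        assert rank_bins({"a": t, "b": t}) == {3: 10.0, 10: 4.0, 1: 1.0}

    def test_abundance_tie_ranks_lower_bin_first(self):
        tables = {"lib": {"+": {9: Fraction(50), 4: Fraction(50)}, "-": {}}}
        assert rank_bins(tables) == {4: 5.0, 9: 2.0}


def event(score, allen=0.0, slice_t=100, strand="+", seq="G" * 21, srna="q"):
    aln_ = TargetAlignment(seq, "x", slice_t - 10, slice_t + 10, allen, slice_t)
    return (strand, aln_, WeightedEventScore(aln_, score, []), srna)


class TestPrimaryTrigger:
    def test_argmax_by_score(self):
        state = make_state(locus())
        trig = assign_primary_trigger(state, [event(12.0, srna="a"), event(7.0, srna="b")])
        assert trig.srna_id == "a" and trig.deg_score == 12.0

    def test_below_minimum_score_assigns_nothing(self):
        state = make_state(locus())
        assert assign_primary_trigger(state, [event(9.5)]) is None
        assert state.polarity == "unknown"

    def test_polarity_is_targeted_strand(self):
        state = make_state(locus())
        assign_primary_trigger(state, [event(12.0, strand="-")])
        assert state.polarity == "-" and state.locus.polarity == "-"

    def test_score_tie_breaks_on_lower_allen_then_5prime_slice(self):
        state = make_state(locus())
        trig = assign_primary_trigger(
            state,
            [event(12.0, allen=2.0, srna="a"), event(12.0, allen=1.0, slice_t=150, srna="b"),
             event(12.0, allen=1.0, slice_t=120, srna="c")],
        )
        assert trig.srna_id == "c"

    def test_planted_trigger_recovered_on_synthetic_loci(self, bundle, pipeline_result):
        truth = bundle.truth
        hits = total = 0
        for lt in truth.loci:
            deg_n = sum(f[lt.locus_id] for f in truth.degradome_expression)
            if not truth.expressed_in(lt.locus_id) or deg_n < 2:
                continue
            total += 1
            state = locus_state_for(pipeline_result, lt)
            assert state is not None
            if any(
                t.srna_sequence == lt.trigger_sequence
                and t.slice_genomic == lt.slice_position
                and t.polarity == lt.strand
                for t in state.triggers
            ):
                hits += 1
        assert total >= 15 and hits == total


class TestSecondaryTriggers:
    def make_primary(self):
        state = make_state(locus(pol="+"))
        state.rank_scores = {4: 15.0, 9: 8.0, 13: 4.0, 2: 1.0}
        assign_primary_trigger(state, [event(12.0, srna="primary")])
        return state

    def test_requires_existing_primary(self):
        state = make_state(locus())
        assert find_secondary_triggers(state, [event(12.0)]) == []

    def test_accepts_matching_polarity_in_top_bin(self):
        state = self.make_primary()
        # choose a slice whose register bin falls in the top-3 (or +-1) set
        allowed = adjacent_bins(state.top_bins(3))
        for st in range(100, 130):
            g_anchor = state.t2g("+", st) + 1
            if state.register_bin_of_anchor(g_anchor, "+") in allowed:
                accepted = find_secondary_triggers(
                    state, [event(11.0, slice_t=st, srna="cand", seq="C" * 21)]
                )
                assert [t.srna_id for t in accepted] == ["cand"]
                assert accepted[0].rank == "secondary"
                return
        pytest.fail("no qualifying slice found")

    def test_rejects_bin_outside_top_three_adjacency(self):
        state = self.make_primary()
        allowed = adjacent_bins(state.top_bins(3))
        for st in range(100, 130):
            g_anchor = state.t2g("+", st) + 1
            if state.register_bin_of_anchor(g_anchor, "+") not in allowed:
                got = find_secondary_triggers(
                    state, [event(11.0, slice_t=st, seq="C" * 21)]
                )
                assert got == []
                return
        pytest.fail("no non-qualifying slice found")

    def test_rejects_opposite_polarity(self):
        state = self.make_primary()
        assert find_secondary_triggers(state, [event(11.0, strand="-", seq="C" * 21)]) == []


class TestExtraction:
    def build_state(self, trigger_bin=None, top_bin=7):
        lo = locus(start=1000, end=1200, pol="+")
        reads = [aln(1000 + 21 * c + b, "+") for c in range(4) for b in (2, 3, 4, 6)]
        state = make_state(lo, alignments=reads)
        state.bin_tables = {"lib": build_phase_bins(lo, reads, "lib")}
        state.rank_scores = {top_bin: 5.0}
        if trigger_bin is not None:
            # slice whose anchor falls in trigger_bin: anchor = start + bin-1
            g_slice = lo.start + trigger_bin - 2
            state.triggers.append(
                pn.TriggerAssignment("q", "G" * 21, lo.locus_id, "+", g_slice,
                                     g_slice - lo.extended_start + 1, 12.0, 0.0,
                                     "primary", trigger_bin, 1)
            )
            state.polarity = "+"
        return state

    def test_trigger_register_collects_adjacent_bins_only(self):
        state = self.build_state(trigger_bin=4)
        recs = extract_phasirnas(state, {})
        assert {r.bin for r in recs} == {3, 4, 5}

    def test_no_trigger_uses_top_ranked_bin(self):
        state = self.build_state(trigger_bin=None, top_bin=7)
        recs = extract_phasirnas(state, {})
        assert {r.bin for r in recs} == {7}  # bins 6,8 hold no reads at slot 5/7

    def test_offsets_relative_to_main_register(self):
        state = self.build_state(trigger_bin=4)
        offs = {(r.bin, r.offset) for r in extract_phasirnas(state, {})}
        assert offs == {(3, -1), (4, 0), (5, 1)}

    def test_shift_locus_offsets_zero_then_plus_one(self, bundle, pipeline_result):
        """The planted 22-nt emitting locus yields offset 0 through the shift
        cycle (including the 22-mer) and +1 afterwards."""
        truth = bundle.truth
        lt = truth.loci[truth.config.shift_loci[0]]
        state = locus_state_for(pipeline_result, lt)
        by_seq = {}
        for r in state.phasirnas.values():
            by_seq.setdefault((r.sequence, r.genomic_strand), []).append(r)
        for rec in lt.phasirna_records:
            matches = by_seq.get((rec.sequence, rec.strand), [])
            assert matches, f"cycle {rec.cycle} record not recovered"
            assert any(r.offset == rec.offset and r.length == rec.length for r in matches)


class TestNomenclature:
    def test_printed_exemplar_with_plus_one_offset(self):
        rec = pn.PhasiRna("x", "A" * 21, 21, "-", "-", 0, 1, 1, 20)
        assert name_phasirna(rec, "AT2G39675", "-") == "AT2G39675(-)_20-(+1)"

    def test_printed_exemplar_with_22_suffix(self):
        rec = pn.PhasiRna("x", "A" * 22, 22, "+", "+", 0, 1, -1, 18)
        assert name_phasirna(rec, "AT3G17185", "+") == "AT3G17185(+)_18+(-1)_22"

    def test_zero_offset_omits_parenthesis_and_suffix(self):
        rec = pn.PhasiRna("x", "A" * 21, 21, "+", "+", 0, 1, 0, 3)
        assert name_phasirna(rec, "AT1G11700", "+") == "AT1G11700(+)_3+"

    def test_roundtrip_on_10000_random_records(self):
        rng = np.random.default_rng(99)
        labels = ["AT2G39675", "at1g63130", "Chr5:7006522-7007118", "PHASL_012"]
        for _ in range(10_000):
            fields = {
                "locus_label": labels[int(rng.integers(len(labels)))],
                "locus_strand": "+-"[int(rng.integers(2))],
                "register_index": int(rng.integers(1, 60)),
                "strand": "+-"[int(rng.integers(2))],
                "offset": int(rng.integers(-10, 11)),
                "length": 21 if rng.random() < 0.7 else 22,
            }
            rec = pn.PhasiRna(
                "x", "A" * fields["length"], fields["length"], fields["strand"],
                fields["strand"], 0, 1, fields["offset"], fields["register_index"],
            )
            name = name_phasirna(rec, fields["locus_label"], fields["locus_strand"])
            assert parse_phasirna_name(name) == fields

    def test_unsigned_offset_parses_as_positive(self):
        fields = parse_phasirna_name("AT2G39681(-)_19-(2)")
        assert fields["offset"] == 2

    def test_malformed_name_raises(self):
        with pytest.raises(ValueError):
            parse_phasirna_name("not-a-name")

    def test_symmetric_offset_range(self):
        assert [symmetric_offset(d) for d in (0, 1, 10, 11, 20)] == [0, 1, 10, -10, -1]


class TestFeatureAssignment:
    def ann(self):
        a = GenomeAnnotation()
        a.features.append(Feature("AT9G00010", "Chr1", 950, 1250, "+", "gene"))
        a.features.append(Feature("AT9G00020", "Chr1", 940, 1260, "-", "gene"))
        return a

    def test_confirmed_needs_overlap_and_polarity(self):
        state = make_state(locus(pol="+"), polarity="+")
        state.triggers.append(object())  # trigger known
        got = assign_locus_feature(state, self.ann())
        assert (got.assigned_id, got.confidence) == ("AT9G00010", "confirmed")
        assert got.overlap_fraction > 0.7
        assert len(got.all_matches) == 2  # both strands reported

    def test_no_trigger_gives_lowercase_tentative(self):
        state = make_state(locus(pol="unknown"))
        got = assign_locus_feature(state, self.ann())
        assert got.confidence == "tentative"
        assert got.assigned_id == got.assigned_id.lower()

    def test_no_overlap_gives_coordinate_name(self):
        state = make_state(locus(start=5000, end=5200))
        got = assign_locus_feature(state, self.ann())
        assert got.assigned_id == "Chr1:5000-5200"
        assert got.confidence == "unassigned"


class TestClassification:
    def test_four_way_rules(self):
        recs = [
            pn.PhasiRna("x", "A" * 21, 21, "+", "+", 0, 1, 0, 1),
            pn.PhasiRna("x", "A" * 21, 21, "+", "+", 0, 1, 1, 1),
            pn.PhasiRna("x", "A" * 22, 22, "+", "+", 0, 1, 0, 1),
        ]
        got = classify_phasirnas(recs)
        assert got == {
            "21_canonical": 1,
            "21_noncanonical": 1,
            "22_canonical": 0,
            "22_noncanonical": 1,
        }


class TestIteration:
    def test_trans_cascade_discovered_in_round_two(self, bundle, pipeline_result):
        truth = bundle.truth
        src_i, tgt_i = truth.config.trans_edges[0]
        lt = truth.loci[tgt_i]
        state = locus_state_for(pipeline_result, lt)
        trans = [
            t for t in state.triggers
            if t.srna_sequence == lt.trigger_sequence and t.slice_genomic == lt.slice_position
        ]
        assert trans and trans[0].round_found == 2

    def test_fixed_point_without_trans_edges(self, noise_free_bundle):
        res = pn.run_pipeline(pn.PipelineInputs.from_bundle(noise_free_bundle))
        assert res.annotation_result.rounds_run <= 2
        assert all(
            t.round_found == 1 for t in res.annotation_result.triggers
        )

    def test_recall_meets_bound_and_matches_truth_value(self, bundle, pipeline_result):
        """>= 70% of locus-region reads fall in annotated registers, and the
        value equals one recomputed from the truth manifest."""
        assert pipeline_result.recall >= 0.7
        truth = bundle.truth
        planted = {}
        for lt in truth.loci:
            for r in lt.phasirna_records:
                planted[(r.sequence, r.strand)] = lt.locus_id
        total = hit = 0.0
        states = pipeline_result.annotation_result.states.values()
        for aligns in pipeline_result.alignments.values():
            for a in aligns:
                for state in states:
                    if (
                        a.reference_id == state.locus.chrom
                        and state.locus.start <= a.effective_five_prime <= state.locus.end
                    ):
                        total += float(a.fractional_count)
                        if (a.read.sequence, a.strand) in planted:
                            hit += float(a.fractional_count)
        truth_value = hit / total
        # annotated registers recover at least the planted reads
        assert pipeline_result.recall >= truth_value - 1e-9
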