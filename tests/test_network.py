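"""Target validation, bipartite network assembly, metrics and enrichment."""

import math

import networkx as nx
import numpy as np
import pytest

import phasinet as pn
from phasinet.features import Feature, GenomeAnnotation
from phasinet.network import (
    Interaction,
    SrnaCandidate,
    build_network,
    co_regulated_fraction,
    combined_raw_count,
    correlate,
    go_enrichment,
    map_target_site,
    network_metrics,
    select_active_candidates,
    validate_targets,
)
from phasinet.seqio import DegradomeLibrary, SrnaLibrary, revcomp


def cand(srna_id="s1", seq="A" * 21, kind="phasiRNA", prec="L1", count=100):
    return SrnaCandidate(srna_id, seq, kind, prec, count)


class TestCandidateSelection:
    def test_combined_count_boundary(self):
        assert select_active_candidates([cand(count=49)]) == []
        assert len(select_active_candidates([cand(count=50)])) == 1
        assert len(select_active_candidates([cand(count=55)])) == 1

    def test_combined_raw_count_sums_across_libraries(self):
        libs = []
        for i, c in enumerate((30, 25)):
            lib = SrnaLibrary(f"l{i}")
            lib.add("A" * 21, c)
            libs.append(lib)
        assert combined_raw_count("A" * 21, libs) == 55
        assert combined_raw_count("C" * 21, libs) == 0


class TestValidateTargets:
    def setup_case(self, n_libs, peak=5):
        rng = np.random.default_rng(21)
        srna = "".join(rng.choice(list("ACGT"), 21))
        transcript = (
            "".join(rng.choice(list("ACGT"), 80))
            + revcomp(srna)
            + "".join(rng.choice(list("ACGT"), 80))
        )
        libs = []
        for i in range(n_libs):
            lib = DegradomeLibrary(f"deg{i}")
            lib.add(transcript[91:111], peak)  # peak at slice+1 = position 92
            libs.append(lib)
        return srna, transcript, libs

    def test_three_category_zero_events_reach_threshold(self):
        srna, transcript, libs = self.setup_case(3)
        out = validate_targets([cand(seq=srna)], {"T1": transcript}, libs)
        validated = [ix for ix in out if ix.validated]
        assert len(validated) == 1
        assert validated[0].target_deg_score == 15.0
        assert validated[0].slice_position == 91

    def test_score_below_threshold_not_validated(self):
        srna, transcript, libs = self.setup_case(2)
        out = validate_targets([cand(seq=srna)], {"T1": transcript}, libs)
        assert out and not any(ix.validated for ix in out)

    def test_adding_a_library_never_invalidates(self):
        srna, transcript, libs = self.setup_case(4)
        for k in range(1, 5):
            sub = validate_targets([cand(seq=srna)], {"T1": transcript}, libs[:k])
            full = validate_targets([cand(seq=srna)], {"T1": transcript}, libs)
            before = {(i.srna_id, i.transcript_id, i.slice_position) for i in sub if i.validated}
            after = {(i.srna_id, i.transcript_id, i.slice_position) for i in full if i.validated}
            assert before <= after

    def test_planted_interactions_in_three_plus_libraries_validated(
        self, bundle, pipeline_result
    ):
        """Every planted single-site interaction whose gating locus is
        expressed in >= 3 degradome libraries is validated."""
        truth = bundle.truth
        validated = {
            (ix.srna_sequence, ix.transcript_id, ix.slice_position)
            for ix in pipeline_result.interactions
            if ix.validated
        }
        transcripts = [ix.transcript_id for ix in truth.interactions]
        checked = 0
        for ix in truth.interactions:
            if transcripts.count(ix.transcript_id) > 1:
                continue  # competing peaks handled by the oracle-equality test
            if sum(f[ix.gate_locus] for f in truth.degradome_expression) < 3:
                continue
            if ix.srna_kind == "phasiRNA" and not truth.expressed_in(
                ix.srna_source.split(":")[0]
            ):
                continue
            checked += 1
            assert (ix.srna_sequence, ix.transcript_id, ix.slice_t) in validated
        assert checked >= 10

    def test_validated_set_equals_truth_oracle(self, bundle, pipeline_result):
        """The pipeline's validated interactions equal the set derived from
        the truth manifest and raw tag counts alone."""
        from phasinet.simulate import expected_interaction_scores

        exp = expected_interaction_scores(
            bundle.truth, bundle.genome, bundle.annotation, bundle.degradome_libraries
        )
        expected = {k for k, s in exp.items() if s >= 15.0}
        got = {
            (ix.srna_sequence, ix.transcript_id, ix.slice_position)
            for ix in pipeline_result.interactions
            if ix.validated
        }
        assert got == expected


class TestMapTargetSite:
    def ann(self):
        a = GenomeAnnotation()
        gene = Feature("G1", "Chr1", 101, 400, "+", "gene")
        a.features.extend(
            [
                gene,
                Feature("G1.e1", "Chr1", 101, 200, "+", "exon", parent="G1"),
                Feature("G1.e2", "Chr1", 281, 400, "+", "exon", parent="G1"),
                Feature("G1.c1", "Chr1", 141, 200, "+", "CDS", parent="G1"),
                Feature("G1.c2", "Chr1", 281, 340, "+", "CDS", parent="G1"),
            ]
        )
        return a

    def ix(self, pos, tid="G1"):
        return Interaction("s", "A" * 21, "phasiRNA", "L", tid, pos, 15.0, 0.0, True)

    def test_single_exon_cds_site(self):
        chrom, gpos, label = map_target_site(self.ix(60), self.ann())
        assert (chrom, gpos, label) == ("Chr1", 160, "CDS")

    def test_site_past_first_exon_gets_intron_offset(self):
        chrom, gpos, label = map_target_site(self.ix(110), self.ann())
        assert gpos == 290 and label == "CDS"

    def test_minus_strand_positions_decrease(self):
        a = GenomeAnnotation()
        a.features.append(Feature("G2", "Chr1", 101, 400, "-", "gene"))
        g1 = map_target_site(self.ix(10, "G2"), a)[1]
        g2 = map_target_site(self.ix(11, "G2"), a)[1]
        assert g2 == g1 - 1

    def test_beyond_transcript_is_an_error(self):
        with pytest.raises(ValueError):
            map_target_site(self.ix(500), self.ann())


class TestBuildNetwork:
    def test_single_mirna_chain(self):
        c = cand("miR1", "A" * 21, "miRNA", "MIR1", 100)
        ix = Interaction("miR1", "A" * 21, "miRNA", "MIR1", "T1", 50, 15.0, 0.0, True)
        g = build_network([c], [ix])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        assert g.edges["MIR1", "miR1"]["edge_type"] == "biogenesis"
        assert g.edges["miR1", "T1"]["edge_type"] == "cleavage"

    def test_cascade_edge_counts(self):
        """A miRNA triggering a PHAS locus that yields two active phasiRNAs
        with one target each: 3 biogenesis + 3 cleavage edges."""
        cands = [
            cand("miR1", "A" * 21, "miRNA", "MIR1", 100),
            cand("p1", "C" * 21, "phasiRNA", "PHASL_000", 100),
            cand("p2", "G" * 21, "phasiRNA", "PHASL_000", 100),
        ]
        ixs = [
            Interaction("miR1", "A" * 21, "miRNA", "MIR1", "PHAS_host", 1, 15, 0, True),
            Interaction("p1", "C" * 21, "phasiRNA", "PHASL_000", "T1", 1, 15, 0, True),
            Interaction("p2", "G" * 21, "phasiRNA", "PHASL_000", "T2", 1, 15, 0, True),
        ]
        g = build_network(cands, ixs)
        by_type = {"biogenesis": 0, "cleavage": 0}
        for *_, d in g.edges(data=True):
            by_type[d["edge_type"]] += 1
        assert by_type == {"biogenesis": 3, "cleavage": 3}

    def test_empty_interactions_empty_network(self):
        assert build_network([cand()], []).number_of_nodes() == 0

    def test_unknown_srna_reference_is_error(self):
        ix = Interaction("ghost", "A" * 21, "miRNA", "", "T1", 1, 15, 0, True)
        with pytest.raises(ValueError):
            build_network([], [ix])

    def test_pipeline_network_is_bipartite_with_unit_indegree(self, pipeline_result):
        g = pipeline_result.network
        for u, v, d in g.edges(data=True):
            tu = g.nodes[u]["node_type"]
            tv = g.nodes[v]["node_type"]
            assert {tu, tv} == {"sRNA", "transcript"}
            if d["edge_type"] == "biogenesis":
                assert (tu, tv) == ("transcript", "sRNA")
            else:
                assert (tu, tv) == ("sRNA", "transcript")
        for n, d in g.nodes(data=True):
            if d["node_type"] == "sRNA":
                assert g.in_degree(n) == 1  # exactly one precursor

    def test_co_regulation_matches_truth_derived_value(self, bundle, pipeline_result):
        from phasinet.simulate import expected_interaction_scores

        exp = expected_interaction_scores(
            bundle.truth, bundle.genome, bundle.annotation, bundle.degradome_libraries
        )
        kinds_by_transcript = {}
        kind_of = {
            (ix.srna_sequence, ix.transcript_id, ix.slice_t): ix.srna_kind
            for ix in bundle.truth.interactions
        }
        for key, score in exp.items():
            if score >= 15.0:
                kinds_by_transcript.setdefault(key[1], set()).add(kind_of[key])
        expected_targets = len(kinds_by_transcript)
        expected_co = sum(
            1 for kinds in kinds_by_transcript.values() if kinds == {"miRNA", "phasiRNA"}
        )
        got = co_regulated_fraction(pipeline_result.network)
        assert got == pytest.approx(
            expected_co / expected_targets if expected_targets else 0.0
        )


class TestMetrics:
    def typed(self, edges):
        g = nx.DiGraph()
        for u, v in edges:
            g.add_node(u, node_type="sRNA", node_class="miRNA")
            g.add_node(v, node_type="transcript", node_class="target")
            g.add_edge(u, v, edge_type="cleavage")
        return g

    def test_two_disjoint_chains_are_two_components(self):
        m = network_metrics(self.typed([("a", "b"), ("c", "d")]))
        assert m.n_components == 2
        assert sum(m.component_sizes) == m.n_nodes

    def test_directed_cycle_density(self):
        g = nx.DiGraph()
        for u, v in (("a", "b"), ("b", "c"), ("c", "a")):
            g.add_node(u, node_type="sRNA")
            g.add_edge(u, v, edge_type="cleavage")
        assert network_metrics(g).density == pytest.approx(0.5)

    def test_triangle_has_unit_clustering(self):
        g = nx.DiGraph()
        for u, v in (("a", "b"), ("b", "c"), ("a", "c")):
            g.add_edge(u, v)
        assert network_metrics(g).avg_clustering == pytest.approx(1.0)

    def test_tiny_network_density_error(self):
        with pytest.raises(ValueError):
            network_metrics(nx.DiGraph([("a", "a")]))


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = list(range(10))
        y = [2 * v + 1 for v in x]
        r = correlate(x, y)
        assert r.r == pytest.approx(1.0) and r.r_squared == pytest.approx(1.0)

    def test_df_is_n_minus_2(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=57)
        y = rng.normal(size=57)
        assert correlate(x, y).df == 55

    def test_t_statistic_self_consistency_on_correlated_draws(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=57)
        y = 0.6 * x + rng.normal(scale=math.sqrt(1 - 0.36), size=57)
        res = correlate(x, y)
        assert abs(res.r - 0.6) < 0.2
        assert res.t == pytest.approx(res.r * math.sqrt(res.df / (1 - res.r**2)))

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            correlate([1.0] * 5, [1, 2, 3, 4, 5])


class TestEnrichment:
    def test_fully_enriched_term_has_tiny_exact_pvalue(self):
        universe = [f"g{i}" for i in range(1000)]
        term_genes = universe[:10]
        res = go_enrichment(term_genes, universe, {"GO:1": term_genes})
        over = next(r for r in res if r.direction == "over")
        # exact hypergeometric tail: P(X >= 10) = 1 / C(1000, 10) * C(10,10)*C(990,0) / ...
        exact = (
            math.comb(10, 10) * math.comb(990, 0) / math.comb(1000, 10)
        )
        assert over.raw_p == pytest.approx(exact, rel=1e-6)
        assert over.raw_p < 1e-10 and over.significant

    def test_term_covering_universe_not_significant(self):
        universe = [f"g{i}" for i in range(100)]
        res = go_enrichment(universe[:10], universe, {"GO:1": universe})
        over = next(r for r in res if r.direction == "over")
        assert over.raw_p == pytest.approx(1.0) and not over.significant

    def test_bh_correction_monotone_after_sorting(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(500)]
        net = list(rng.choice(universe, 60, replace=False))
        term_map = {
            f"GO:{t}": list(rng.choice(universe, int(rng.integers(10, 80)), replace=False))
            for t in range(12)
        }
        res = go_enrichment(net, universe, term_map)
        for direction in ("over", "under"):
            rows = sorted(
                [r for r in res if r.direction == direction], key=lambda r: r.raw_p
            )
            for a, b in zip(rows, rows[1:]):
                assert a.corrected_p <= b.corrected_p + 1e-12
            for r in rows:
                assert r.corrected_p >= r.raw_p - 1e-12

    def test_network_gene_missing_from_universe_is_error(self):
        with pytest.raises(ValueError):
            go_enrichment(["gX"], ["g1"], {"GO:1": ["g1"]})
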