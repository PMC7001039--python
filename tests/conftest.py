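import pytest

import phasinet as pn


@pytest.fixture(scope="session")
def bundle():
    """The standing synthetic study: 20 loci, 6 sRNA + 4 degradome
    libraries, expression rate 0.8, noise 0.3, one trans edge, one 22-nt
    shift locus."""
    return pn.simulate_bundle(pn.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    return pn.run_pipeline(pn.PipelineInputs.from_bundle(bundle))


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Noise-free, jitter-free, fully expressed simulation without a
    register shift: the cleanest round-trip instance."""
    cfg = pn.SimulationConfig(
        seed=7,
        n_phas_loci=6,
        n_target_genes=6,
        n_srna_libraries=3,
        n_degradome_libraries=3,
        chrom_length=12_000,
        locus_expression_rate=1.0,
        noise_fraction=0.0,
        poisson_jitter=False,
        shift_loci=(),
        trans_edges=(),
        n_co_regulated=0,
    )
    return pn.simulate_bundle(cfg)


@pytest.fixture(scope="session")
def small_bundle():
    """A light bundle for pipeline/CLI smoke tests."""
    cfg = pn.SimulationConfig(
        seed=3,
        n_phas_loci=6,
        n_target_genes=6,
        n_srna_libraries=4,
        n_degradome_libraries=3,
        chrom_length=15_000,
        trans_edges=((0, 1),),
        shift_loci=(0,),
        n_co_regulated=2,
    )
    return pn.simulate_bundle(cfg)


def locus_state_for(result, truth_locus):
    """Consensus-locus state overlapping a planted locus, or None."""
    for locus in result.consensus_loci:
        if (
            locus.chrom == truth_locus.chrom
            and locus.start <= truth_locus.end
            and locus.end >= truth_locus.start
        ):
            return result.annotation_result.states[locus.locus_id]
    return None
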