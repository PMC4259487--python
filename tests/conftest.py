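import pytest
from hypothesis import settings

from tolmap.config import Parameters

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from tolmap.seqio import build_amended_reference
from tolmap.synthetic import (
    SimulatedLocus,
    concatemer_span,
    insert_concatemer,
    simulate_capture_pairs,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_insertion():
    """A 60 kb genome carrying a 3-copy concatemer with an 8 bp TSD, plus
    error-free capture reads from two samples; shared by mapping tests."""
    genome = simulate_reference(1, [60_000], 0.4, seed=101)
    construct = simulate_reference(1, [1500], 0.45, seed=102, prefix="construct")[0]
    construct.id = "construct"
    locus = SimulatedLocus(genome[0].id, insertion_pos=30_450, copy_number=3, tsd_len=8)
    modified, _ = insert_concatemer(genome, construct.sequence, locus)
    span = concatemer_span(locus, len(construct))
    samples = {}
    for i, seed in enumerate((201, 202)):
        pairs, truth = simulate_capture_pairs(
            modified,
            (locus.scaffold_id, *span),
            1500,
            enrichment=50.0,
            seed=seed,
            pair_prefix=f"s{i + 1}",
        )
        samples[f"s{i + 1}"] = (pairs, truth)
    reference = build_amended_reference(genome, construct)
    return {
        "genome": genome,
        "construct": construct,
        "locus": locus,
        "modified": modified,
        "span": span,
        "samples": samples,
        "reference": reference,
    }


@pytest.fixture()
def tiny_params():
    return Parameters(
        genome_length=30_000,
        construct_length=1000,
        copy_number=3,
        n_pairs=900,
        n_samples=3,
        n_genes=300,
        library_size=100_000,
        seed=17,
    )
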