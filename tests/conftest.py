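import numpy as np
import pytest

from gcrtools import (
    CutModel,
    GenomeSpec,
    RejoinModel,
    alu_like_spec,
    embed_repeats,
    find_guide_matches,
    generate_genome,
    rejoin,
    select_cut_sites,
)

GUIDE = "TGTAATCCCAGCACTTTGGG"


@pytest.fixture(scope="session")
def small_genome():
    """Two plain random chromosomes, 60 kb total."""
    return generate_genome(GenomeSpec(2, (40_000, 20_000), 0.45, seed=7))


@pytest.fixture(scope="session")
def repeat_genome():
    """Three 300 kb chromosomes with 40 short repeat copies carrying the
    guide (half exact, some 1/2-mismatch variants)."""
    genome0 = generate_genome(GenomeSpec(3, (300_000,) * 3, 0.41, seed=11))
    genome, annotation = embed_repeats(
        genome0,
        [alu_like_spec(copy_number=40, guide_exact_fraction=0.5,
                       mismatch_profile=(0.2, 0.1), divergence_rate=0.1)],
        GUIDE, seed=12)
    return genome, annotation


@pytest.fixture(scope="session")
def rearranged_scene(repeat_genome):
    """A rearranged derivative of the repeat genome with full truth."""
    genome, annotation = repeat_genome
    matches = find_guide_matches(genome, GUIDE, max_mismatch=2)
    cuts = select_cut_sites(matches, CutModel(cut_probability=0.6, seed=13))
    derivative, junctions, truth = rejoin(
        genome, cuts, RejoinModel(seed=14), bin_size=20_000)
    return {
        "genome": genome,
        "annotation": annotation,
        "matches": matches,
        "cuts": cuts,
        "derivative": derivative,
        "junctions": junctions,
        "truth": truth,
        "bin_size": 20_000,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
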