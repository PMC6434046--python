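import pytest

from breaktrace.align import ToyAligner
from breaktrace.junctions import BaitConfig
from breaktrace.simulate import SimSpec, simulate_library

GUIDE = "GCGGTGAACGCTCAAGTCCA"

DEFAULT_MIXTURE = {
    "germline": 0.60,
    "small_insertion": 0.11,
    "small_deletion": 0.22,
    "large_deletion": 0.03,
    "inversion": 0.012,
    "background_translocation": 0.028,
}


def make_spec(**overrides) -> SimSpec:
    kwargs = dict(
        genome_sizes={"chr1": 3_000_000, "chr2": 2_000_000},
        seed=7,
        guide_seq=GUIDE,
        bait_chrom="chr1",
        bait_cut_pos=1_500_000,
        mixture=dict(DEFAULT_MIXTURE),
        n_molecules=300,
        duplication_mean=1.0,
        error_rate=0.002,
    )
    kwargs.update(overrides)
    return SimSpec(**kwargs)


@pytest.fixture(scope="session")
def small_library():
    """A 300-molecule mixed library shared across read-level tests."""
    return simulate_library(make_spec())


@pytest.fixture(scope="session")
def small_aligner(small_library):
    return ToyAligner(small_library.genome)


@pytest.fixture
def bait():
    return BaitConfig(
        chrom="chr1",
        strand="+",
        primer_start=9_920,
        primer_end=9_940,
        cut_pos=10_000,
        guide_seq=GUIDE,
    )
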