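import pytest

from backsplice import make_genome, plant_circles, simulate_reads


@pytest.fixture(scope="session")
def default_fixture():
    """Standard planted fixture: 2 x 100 kb genome, 10 circles (spans 60-5000,
    support 5-20, mixed strands), 1000 linear reads."""
    genome = make_genome(seed=101, n_chroms=2, chrom_len=100_000)
    genome, truth = plant_circles(
        genome, 10, span_range=(60, 5_000), strand_mix=0.5,
        support_range=(5, 20), seed=102,
    )
    reads = simulate_reads(genome, truth, read_len=50, linear_n=1_000, seed=103)
    return genome, truth, reads


@pytest.fixture(scope="session")
def small_fixture():
    """Cheap fixture for CLI tests: 1 x 20 kb genome, 4 circles."""
    genome = make_genome(seed=201, n_chroms=1, chrom_len=20_000)
    genome, truth = plant_circles(
        genome, 4, span_range=(60, 1_000), strand_mix=0.5,
        support_range=(5, 9), seed=202,
    )
    reads = simulate_reads(genome, truth, read_len=50, linear_n=100, seed=203)
    return genome, truth, reads
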