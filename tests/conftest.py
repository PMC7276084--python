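import numpy as np
import pytest

from h1contrast import Genome, GenomicInterval, IntervalSet


@pytest.fixture
def toy_genome() -> Genome:
    return Genome({"chrA": 10_000, "chrB": 20_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


def random_intervals(rng, genome, n, max_len=500):
    """n random intervals across the genome, lengths in [1, max_len]."""
    names = genome.chrom_names
    out = []
    for _ in range(n):
        chrom = names[rng.integers(len(names))]
        size = genome.chrom_sizes[chrom]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, size - length + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(out, genome=genome)
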