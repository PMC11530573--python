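import numpy as np
import pytest

from regland.intervals import GenomicInterval, Peak, TSSRecord


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20240901))


@pytest.fixture
def small_tss():
    """A handful of TSSs on two chromosomes."""
    return [
        TSSRecord("geneA", "chr1", 900),
        TSSRecord("geneB", "chr1", 1300),
        TSSRecord("geneC", "chr1", 50_000),
        TSSRecord("geneD", "chr2", 10_000, "-"),
    ]


def make_peak(chrom, start, end, ip=5.0, inp=1.0, rep="rep1", condition="A"):
    return Peak(GenomicInterval(chrom, start, end), ip, inp, rep, condition)


@pytest.fixture
def peak_factory():
    return make_peak


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=2_000):
    """n random possibly-overlapping intervals."""
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_disjoint_intervals(rng, n, chrom="chr1", spacing=5_000, max_len=2_000):
    """n sorted non-overlapping intervals on one chromosome."""
    out = []
    pos = 0
    for _ in range(n):
        pos += int(rng.integers(1, spacing))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, pos, pos + length))
        pos += length
    return out
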