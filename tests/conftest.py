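import numpy as np
import pytest

from kmersweep.fastx import ReadRecord

BASES = "ACGT"


def random_dna(rng, length):
    return "".join(rng.choice(list(BASES), size=length))


def random_kmers(rng, n, k):
    """n distinct random k-mers (not canonicalized)."""
    out = set()
    while len(out) < n:
        out.add(random_dna(rng, k))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_fixture_factory():
    """Factory for small randomized corpora with a trusted k-mer set.

    Reads are a mix of fragments drawn from a 'source' genome (whose
    k-mers seed the trusted set) and fully random fragments, with a
    sprinkling of N's so invalid windows are exercised.
    """

    def make(seed, n_reads=40, read_length=50, k=7, genome_length=400,
             n_fraction=0.05):
        from kmersweep.kmers import KmerConfig, canonical_kmers

        rng = np.random.default_rng(seed)
        genome = random_dna(rng, genome_length)
        trusted = {km for _, km in canonical_kmers(genome, KmerConfig(k=k))}
        reads = []
        for i in range(n_reads):
            if rng.random() < 0.5:
                start = int(rng.integers(0, genome_length - read_length + 1))
                seq = genome[start : start + read_length]
            else:
                seq = random_dna(rng, read_length)
            if rng.random() < n_fraction:
                chars = list(seq)
                chars[int(rng.integers(len(chars)))] = "N"
                seq = "".join(chars)
            reads.append(ReadRecord(seq_id=f"x{i}", sequence=seq))
        return reads, trusted, k

    return make
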