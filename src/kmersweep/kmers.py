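"""Canonical k-mer primitives.

All set membership in this package operates on *canonical* k-mers: a k-mer
is identified with its reverse complement and represented by the
lexicographically smaller of the two spellings. This collapses strand, so
a read sequenced from either strand of the same locus yields the same
k-mer multiset. Windows containing any non-ACGT character (N, ambiguity
codes) are skipped, but window start positions are preserved so that
"two consecutive matches" (adjacent start positions) remains well defined
across gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "KmerConfig",
    "reverse_complement",
    "canonicalize",
    "canonical_kmers",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IUPAC_OK = frozenset("ACGTN")
_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class KmerConfig:
    """Word-length configuration for k-mer extraction.

    Parameters
    ----------
    k : int
        K-mer length, default 31. Must be >= 2: the anchor criterion needs
        at least two k-mer windows per read to ever fire. Odd k guarantees
        no k-mer is its own reverse complement; even k is allowed and
        palindromes canonicalize to themselves deterministically.
    """

    k: int = 31

    def __post_init__(self) -> None:
        if not isinstance(self.k, int) or self.k < 2:
            raise ValueError(f"k must be an integer >= 2, got {self.k!r}")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N; output uppercase.

    Raises ``ValueError`` naming the 0-based position of the first
    character outside {A, C, G, T, N} (case-insensitive).
    """
    s = seq.upper()
    if not _IUPAC_OK.issuperset(s):
        for i, c in enumerate(s):
            if c not in _IUPAC_OK:
                raise ValueError(
                    f"non-IUPAC character {c!r} at position {i} in sequence"
                )
    return s.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Return the canonical spelling: min(kmer, reverse_complement(kmer))."""
    k = kmer.upper()
    rc = k.translate(_COMPLEMENT)[::-1]
    return k if k <= rc else rc


def canonical_kmers(seq: str, cfg: KmerConfig) -> list[tuple[int, str]]:
    """Extract ``(start, canonical k-mer)`` pairs from a sequence.

    One entry per window ``[i, i+k)`` whose characters are all in ACGT;
    windows touching any other character are skipped while positions are
    preserved. A clean sequence of length L yields exactly
    ``max(0, L - k + 1)`` entries. Degenerate input yields an empty list.
    """
    return list(iter_canonical_kmers(seq, cfg))


def iter_canonical_kmers(seq: str, cfg: KmerConfig) -> Iterator[tuple[int, str]]:
    """Lazy version of :func:`canonical_kmers`."""
    k = cfg.k
    s = seq.upper()
    n = len(s)
    if n < k:
        return
    # bad[i] == 1 when s[i] is not a plain base; prefix sums give O(1)
    # window validity checks.
    bad = [0] * (n + 1)
    acc = 0
    for i, c in enumerate(s):
        if c not in _ACGT:
            acc += 1
        bad[i + 1] = acc
    for i in range(n - k + 1):
        if bad[i + k] - bad[i] == 0:
            yield i, canonicalize(s[i : i + k])
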