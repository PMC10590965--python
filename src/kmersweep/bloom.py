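"""Bloom filter over canonical k-mers.

The filter stores the trusted oral k-mer set approximately: querying any
inserted k-mer always returns True (no false negatives), and a k-mer never
inserted returns True with probability at most the configured error rate
as long as no more than ``capacity`` distinct elements have been inserted.

Sizing uses the standard formulas

    m = ceil(-n * ln(p) / (ln 2)^2)        bits
    h = max(1, round((m / n) * ln 2))      hash functions

and positions are derived by double hashing: two 64-bit values ``g1, g2``
are taken from a single blake2b digest of the k-mer, and position ``j`` is
``(g1 + j * g2) mod m``. ``g2`` is forced odd so the probe sequence never
degenerates.

An :class:`ExactKmerSet` with the same query interface is provided as an
exact stand-in, used as the oracle side of filter-vs-exact comparisons.
"""

from __future__ import annotations

import hashlib
import logging
import math
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = ["BloomConfig", "BloomFilter", "ExactKmerSet", "bf_save", "bf_load"]

logger = logging.getLogger(__name__)

_MAGIC = b"KSBF"
_VERSION = 1
_HEADER = struct.Struct("<4sHHQdQIQ")  # magic, version, k, capacity, p, m, h, inserted
_PERSON = b"kmersweep-bloom!"  # blake2b person, 16 bytes max
# Refuse to allocate filters beyond 2^43 bits (1 TiB of bit array): almost
# certainly a mis-typed capacity rather than a real request.
_MAX_BITS = 1 << 43


@dataclass(frozen=True)
class BloomConfig:
    """Capacity / error-rate contract.

    capacity: maximum number of distinct elements for which the error-rate
        guarantee holds (default 2e9, sized for a full trusted oral set;
        use small values at test scale).
    error_rate: tolerated false-positive probability at capacity
        (default 0.001).
    """

    capacity: int = 2_000_000_000
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError(f"capacity must be >= 1, got {self.capacity}")
        if not (0.0 < self.error_rate < 1.0):
            raise ValueError(
                f"error_rate must be in (0, 1), got {self.error_rate}"
            )


def _sizing(n: int, p: float) -> tuple[int, int]:
    m = math.ceil(-n * math.log(p) / (math.log(2) ** 2))
    h = max(1, round((m / n) * math.log(2)))
    return m, h


def _hash_pair(kmer: str) -> tuple[int, int]:
    d = hashlib.blake2b(kmer.encode("ascii"), digest_size=16, person=_PERSON).digest()
    g1 = int.from_bytes(d[:8], "little")
    g2 = int.from_bytes(d[8:], "little") | 1
    return g1, g2


class BloomFilter:
    """Approximate membership store for fixed-length canonical k-mers."""

    def __init__(self, config: BloomConfig, k: int):
        if k < 2:
            raise ValueError(f"k must be >= 2, got {k}")
        m, h = _sizing(config.capacity, config.error_rate)
        if m > _MAX_BITS:
            raise ValueError(
                f"requested filter needs {m} bits ({m // 8 / 2**30:.1f} GiB); "
                f"exceeds the {_MAX_BITS} bit limit — lower capacity or raise "
                f"error_rate"
            )
        self.config = config
        self.k = k
        self.num_bits = m
        self.num_hashes = h
        self.inserted_count = 0  # counts insert calls, not distinct elements
        self.bits = np.zeros((m + 7) // 8, dtype=np.uint8)
        self._warned_over_capacity = False

    def _positions(self, kmer: str) -> list[int]:
        g1, g2 = _hash_pair(kmer)
        m = self.num_bits
        return [(g1 + j * g2) % m for j in range(self.num_hashes)]

    def insert(self, kmer: str) -> None:
        if len(kmer) != self.k:
            raise ValueError(
                f"k-mer length {len(kmer)} does not match filter k={self.k}"
            )
        bits = self.bits
        for pos in self._positions(kmer):
            bits[pos >> 3] |= 1 << (pos & 7)
        self.inserted_count += 1
        if self.inserted_count > self.config.capacity and not self._warned_over_capacity:
            logger.warning(
                "Bloom filter exceeded capacity %d; false-positive rate is no "
                "longer bounded by %g",
                self.config.capacity,
                self.config.error_rate,
            )
            self._warned_over_capacity = True

    def insert_many(self, kmers: Iterable[str]) -> None:
        for km in kmers:
            self.insert(km)

    def query(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            raise ValueError(
                f"k-mer length {len(kmer)} does not match filter k={self.k}"
            )
        bits = self.bits
        for pos in self._positions(kmer):
            if not (bits[pos >> 3] >> (pos & 7)) & 1:
                return False
        return True

    def __contains__(self, kmer: str) -> bool:
        return self.query(kmer)

    def save(self, path: str | Path) -> None:
        header = _HEADER.pack(
            _MAGIC,
            _VERSION,
            self.k,
            self.config.capacity,
            self.config.error_rate,
            self.num_bits,
            self.num_hashes,
            self.inserted_count,
        )
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(self.bits.tobytes())

    @classmethod
    def load(cls, path: str | Path, expect_k: int | None = None) -> "BloomFilter":
        with open(path, "rb") as fh:
            raw = fh.read(_HEADER.size)
            if len(raw) < _HEADER.size:
                raise ValueError(f"{path}: truncated header ({len(raw)} bytes)")
            magic, version, k, capacity, p, m, h, inserted = _HEADER.unpack(raw)
            if magic != _MAGIC:
                raise ValueError(
                    f"{path}: bad magic {magic!r}, expected {_MAGIC!r}"
                )
            if version != _VERSION:
                raise ValueError(
                    f"{path}: format version {version}, this build reads {_VERSION}"
                )
            if expect_k is not None and k != expect_k:
                raise ValueError(
                    f"{path}: filter was built with k={k}, caller expects k={expect_k}"
                )
            payload = fh.read()
        n_bytes = (m + 7) // 8
        if len(payload) != n_bytes:
            raise ValueError(
                f"{path}: bit payload is {len(payload)} bytes, header promises {n_bytes}"
            )
        bf = cls.__new__(cls)
        bf.config = BloomConfig(capacity=capacity, error_rate=p)
        bf.k = k
        bf.num_bits = m
        bf.num_hashes = h
        bf.inserted_count = inserted
        bf.bits = np.frombuffer(payload, dtype=np.uint8).copy()
        bf._warned_over_capacity = inserted > capacity
        return bf


class ExactKmerSet:
    """Exact membership stand-in with the BloomFilter query interface."""

    def __init__(self, kmers: Iterable[str], k: int):
        self.k = k
        self.kmers = frozenset(kmers)
        for km in self.kmers:
            if len(km) != k:
                raise ValueError(f"k-mer {km!r} has length != k={k}")

    def query(self, kmer: str) -> bool:
        return kmer in self.kmers

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers

    def __len__(self) -> int:
        return len(self.kmers)


def bf_save(bf: BloomFilter, path: str | Path) -> None:
    bf.save(path)


def bf_load(path: str | Path, expect_k: int | None = None) -> BloomFilter:
    return BloomFilter.load(path, expect_k=expect_k)
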