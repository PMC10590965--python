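"""Synthetic genomes, read mixtures, and labelled k-mer matrices.

Emulates the controlled evaluation setting: toy source "genomes" for an
ancient-oral community and two contaminant environments (skin,
sediment/soil), balanced read mixtures drawn from them in a
1/3 : 1/3 : 1/3 proportion with Illumina-like substitution errors, and a
labelled k-mer x sample presence matrix playing the role of the large
metagenomic reference collection.

Three overlap scenarios are supported, mirroring increasing realism:

- ``seen``: the genomes generating the reads are exactly the genomes
  behind the trusted-set matrix (best case);
- ``partially_seen``: the oral read source is a diverged variant of a
  matrix genome, contaminants are shared;
- ``unseen``: every read-source genome is a diverged variant or a fresh
  genome never used to build the matrix.

Divergence is modelled as uniform substitutions (default 3% for variant
genomes): strain-level distance at which a substantial fraction of
31-mers no longer survives intact (0.97^31 ~ 0.39), which is what makes
the anchor-harvest second pass earn its keep.

Truth labels travel in a sidecar table keyed by read id, never encoded
in the ids themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fastx import ReadRecord, write_reads
from .kmers import KmerConfig, canonical_kmers, reverse_complement
from .matrix import ENVIRONMENT_LABELS, KmerSampleMatrix

__all__ = [
    "MixtureDesign",
    "make_genomes",
    "mutate_genome",
    "make_reads",
    "make_matrix",
    "make_scenario",
    "write_mixture",
]

_BASES = np.array(list("ACGT"))
DEFAULT_SOURCES = ("aOral", "Skin", "SedimentSoil")


@dataclass(frozen=True)
class MixtureDesign:
    """Balanced three-source read mixture.

    Defaults are the package's standard evaluation conditions: 2,000 reads
    per source (6,000 total), 100 bp reads, 0.5% per-base substitution
    error, random strand. ``overlap_mode`` records which scenario the
    mixture belongs to; the genomes passed to :func:`make_reads` must
    have been prepared accordingly.
    """

    n_reads_per_source: int = 2000
    sources: tuple[str, ...] = DEFAULT_SOURCES
    read_length: int = 100
    error_rate: float = 0.005
    overlap_mode: str = "seen"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads_per_source < 1:
            raise ValueError("n_reads_per_source must be >= 1")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError(f"error_rate must be in [0, 0.1], got {self.error_rate}")
        if self.overlap_mode not in ("seen", "partially_seen", "unseen"):
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")
        for s in self.sources:
            if s not in ENVIRONMENT_LABELS:
                raise ValueError(f"unknown source label {s!r}")


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_genomes(
    seed: int,
    n_sources: int = 3,
    genome_length: int = 20_000,
    shared_fraction: float = 0.0,
    k: int = 31,
    labels: Sequence[str] = DEFAULT_SOURCES,
) -> list[tuple[str, str]]:
    """Generate labelled random source genomes.

    The first genome is the oral source; each contaminant genome shares a
    contiguous block with it sized so the pairwise k-mer Jaccard with the
    oral genome is approximately ``shared_fraction`` (a hard-case dial;
    0 gives near-disjoint k-mer sets — exactly disjoint in expectation
    since random 31-mer collisions are vanishingly rare).
    """
    if genome_length < k:
        raise ValueError(f"genome_length {genome_length} < k {k}")
    if not (0.0 <= shared_fraction < 1.0):
        raise ValueError(f"shared_fraction must be in [0, 1), got {shared_fraction}")
    rng = np.random.default_rng(seed)
    labels = list(labels)[:n_sources]
    while len(labels) < n_sources:
        labels.append(DEFAULT_SOURCES[len(labels) % len(DEFAULT_SOURCES)])
    oral = _random_genome(rng, genome_length)
    genomes = [(labels[0], oral)]
    n_kmers = genome_length - k + 1
    # Jaccard J between two equal-size k-mer sets sharing c k-mers is
    # c / (2 n - c), so c = 2 n J / (1 + J).
    shared_kmers = round(2 * n_kmers * shared_fraction / (1 + shared_fraction))
    for label in labels[1:]:
        if shared_kmers > 0:
            block = oral[: shared_kmers + k - 1]
            rest = _random_genome(rng, genome_length - len(block))
            genomes.append((label, block + rest))
        else:
            genomes.append((label, _random_genome(rng, genome_length)))
    return genomes


def mutate_genome(genome: str, rate: float, seed: int) -> str:
    """Apply uniform substitutions at ``rate`` per base (always to a
    different base); models strain-level divergence for the unseen and
    partially-seen scenarios."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    arr = np.array(list(genome))
    hit = rng.random(arr.size) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _add_substitution_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    if rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def make_reads(
    genomes: Sequence[tuple[str, str]],
    design: MixtureDesign,
    fixed_strand: bool = False,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw the balanced read mixture and its ground-truth table.

    Reads start at uniform random positions, come from a random strand
    (unless ``fixed_strand``), and carry per-base substitution errors at
    the design rate. Returns the reads in interleaved source order and a
    truth DataFrame with columns ``read_id`` and ``label``.
    """
    rng = np.random.default_rng(design.rng_seed)
    by_label = {}
    for label, genome in genomes:
        by_label.setdefault(label, genome)
    reads: list[ReadRecord] = []
    truth_rows: list[tuple[str, str]] = []
    counter = 0
    for label in design.sources:
        if label not in by_label:
            raise ValueError(f"no genome supplied for source {label!r}")
        genome = by_label[label]
        if design.read_length > len(genome):
            raise ValueError(
                f"read_length {design.read_length} > genome length {len(genome)}"
            )
        max_start = len(genome) - design.read_length
        for _ in range(design.n_reads_per_source):
            start = int(rng.integers(0, max_start + 1))
            frag = genome[start : start + design.read_length]
            if not fixed_strand and rng.random() < 0.5:
                frag = reverse_complement(frag)
            frag = _add_substitution_errors(frag, design.error_rate, rng)
            read_id = f"r{counter:06d}"
            counter += 1
            reads.append(
                ReadRecord(
                    seq_id=read_id,
                    sequence=frag,
                    qualities="I" * len(frag),
                )
            )
            truth_rows.append((read_id, label))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "label"])
    return reads, truth


def make_matrix(
    genomes: Sequence[tuple[str, str]],
    n_samples_per_env: int = 2,
    seed: int = 0,
    k: int = 31,
    subset_fraction: float = 0.9,
    noise_rate: float = 0.0,
    with_counts: bool = True,
) -> KmerSampleMatrix:
    """Build a labelled k-mer x sample matrix from source genomes.

    Each synthetic sample of an environment carries a random subset
    (``subset_fraction``) of its genome's canonical k-mers, plus — at
    ``noise_rate`` per k-mer — spurious presence of k-mers from the other
    genomes. With ``subset_fraction=1`` and ``noise_rate=0`` sample
    columns equal genome k-mer sets exactly. Per-sample counts, when
    requested, are 1 + Poisson(3), so roughly 5% of entries are
    within-sample singletons. Scenario control (seen / unseen) happens by
    choosing which genomes are passed in.
    """
    if n_samples_per_env < 1:
        raise ValueError("n_samples_per_env must be >= 1")
    rng = np.random.default_rng(seed)
    kcfg = KmerConfig(k=k)
    genome_kmers = [
        sorted({km for _, km in canonical_kmers(genome, kcfg)})
        for _, genome in genomes
    ]
    all_kmers = sorted(set().union(*genome_kmers)) if genome_kmers else []
    index = {km: i for i, km in enumerate(all_kmers)}
    sample_ids: list[str] = []
    labels: list[str] = []
    presence = np.zeros((len(all_kmers), len(genomes) * n_samples_per_env), dtype=bool)
    col = 0
    for (label, _), kmers in zip(genomes, genome_kmers):
        rows = np.array([index[km] for km in kmers], dtype=int)
        for s in range(n_samples_per_env):
            sample_ids.append(f"{label}_{s}")
            labels.append(label)
            keep = rng.random(rows.size) < subset_fraction
            presence[rows[keep], col] = True
            if noise_rate > 0:
                noise = rng.random(len(all_kmers)) < noise_rate
                presence[noise, col] = True
            col += 1
    counts = None
    if with_counts:
        counts = np.zeros_like(presence, dtype=np.int64)
        counts[presence] = 1 + rng.poisson(3, size=int(presence.sum()))
    return KmerSampleMatrix(
        kmers=all_kmers,
        sample_ids=sample_ids,
        labels=labels,
        presence=presence,
        counts=counts,
    )


def make_scenario(
    overlap_mode: str,
    seed: int,
    k: int = 31,
    genome_length: int = 20_000,
    design: MixtureDesign | None = None,
    divergence: float = 0.03,
) -> tuple[list[ReadRecord], pd.DataFrame, frozenset[str]]:
    """Assemble a full evaluation scenario: reads, truth, trusted k-mers.

    ``seen``: reads come from the same disjoint genomes whose oral member
    defines the trusted set — the best case. ``unseen``: the oral read
    source is a variant of the trusted-set genome at ``divergence``
    substitutions per base, and the contaminant read sources are fresh
    genomes never used for the trusted set. ``partially_seen``: oral
    variant as in unseen, contaminants shared with the trusted-set side.
    Returns ``(reads, truth, trusted_oral_kmers)``.
    """
    design = design or MixtureDesign(rng_seed=seed + 1, overlap_mode=overlap_mode)
    kcfg = KmerConfig(k=k)
    base = make_genomes(seed=seed, genome_length=genome_length, k=k)
    trusted = frozenset(km for _, km in canonical_kmers(base[0][1], kcfg))
    if overlap_mode == "seen":
        read_genomes = base
    else:
        oral_variant = (base[0][0], mutate_genome(base[0][1], divergence, seed + 7))
        if overlap_mode == "partially_seen":
            read_genomes = [oral_variant] + base[1:]
        else:  # unseen: fresh contaminant genomes too
            fresh = make_genomes(seed=seed + 1000, genome_length=genome_length, k=k)
            read_genomes = [oral_variant] + fresh[1:]
    reads, truth = make_reads(read_genomes, design)
    return reads, truth, trusted


def write_mixture(
    reads: Sequence[ReadRecord],
    truth: pd.DataFrame,
    fastq_path: str | Path,
    truth_path: str | Path,
) -> None:
    """Emit the mixture FASTQ and its truth sidecar TSV."""
    write_reads(((r, None) for r in reads), fastq_path, fmt="fastq")
    truth.to_csv(truth_path, sep="\t", index=False)
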