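"""Trusted oral k-mer selection from a labelled k-mer x sample matrix.

The trusted set is derived from a boolean presence matrix whose columns
carry environment labels in {aOral, mOral, Skin, SedimentSoil}. A k-mer is
trusted iff

    (present in any aOral sample OR any mOral sample)
    AND absent from ALL Skin samples
    AND absent from ALL SedimentSoil samples.

Before this boolean selection the pipeline applies, in order:

1. uniform row subsampling (default 10%, for memory reduction),
2. within-sample singleton removal (count == 1 entries cleared — likely
   sequencing errors; requires per-sample counts),
3. a sample-prevalence filter (k-mer must remain present in at least
   ``min_sample_prevalence`` samples, default 3).

All samples, oral and contaminant alike, count toward prevalence.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .kmers import KmerConfig, canonicalize

__all__ = [
    "ENVIRONMENT_LABELS",
    "ORAL_LABELS",
    "CONTAMINANT_LABELS",
    "KmerSampleMatrix",
    "TrustedSetFilters",
    "TrustedKmerSet",
    "apply_abundance_filters",
    "subsample_rows",
    "select_trusted",
    "build_trusted_set",
    "read_matrix",
    "write_matrix",
    "read_kmer_list",
    "write_kmer_list",
]

ORAL_LABELS = ("aOral", "mOral")
CONTAMINANT_LABELS = ("Skin", "SedimentSoil")
ENVIRONMENT_LABELS = ORAL_LABELS + CONTAMINANT_LABELS

_LABEL_ALIASES = {
    "aoral": "aOral",
    "moral": "mOral",
    "skin": "Skin",
    "sedimentsoil": "SedimentSoil",
    "sediment/soil": "SedimentSoil",
    "soil/sediment": "SedimentSoil",
    "soilsediment": "SedimentSoil",
}


def normalize_label(label: str) -> str:
    """Map a label spelling onto the closed vocabulary; reject unknowns."""
    key = label.strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(
            f"unknown environment label {label!r}; expected one of {ENVIRONMENT_LABELS}"
        )
    return _LABEL_ALIASES[key]


@dataclass
class KmerSampleMatrix:
    """Boolean k-mer x sample presence matrix with environment labels.

    ``presence`` is (n_kmers, n_samples) bool; optional ``counts`` has the
    same shape and satisfies presence == (counts >= 1).
    """

    kmers: list[str]
    sample_ids: list[str]
    labels: list[str]
    presence: np.ndarray
    counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n, s = len(self.kmers), len(self.sample_ids)
        self.labels = [normalize_label(lb) for lb in self.labels]
        if len(self.labels) != s:
            raise ValueError("one label per sample required")
        if len(set(self.kmers)) != n:
            raise ValueError("duplicate k-mer row keys")
        if len(set(self.sample_ids)) != s:
            raise ValueError("duplicate sample ids")
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (n, s):
            raise ValueError(
                f"presence shape {self.presence.shape} != ({n}, {s})"
            )
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != (n, s):
                raise ValueError("counts shape mismatch")
            if (self.counts < 0).any():
                raise ValueError("counts must be nonnegative")
            if not np.array_equal(self.presence, self.counts >= 1):
                raise ValueError("presence must equal counts >= 1")

    @property
    def n_kmers(self) -> int:
        return len(self.kmers)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def take_rows(self, idx: np.ndarray) -> "KmerSampleMatrix":
        return KmerSampleMatrix(
            kmers=[self.kmers[i] for i in idx],
            sample_ids=list(self.sample_ids),
            labels=list(self.labels),
            presence=self.presence[idx],
            counts=None if self.counts is None else self.counts[idx],
        )


@dataclass(frozen=True)
class TrustedSetFilters:
    """Filter configuration for trusted-set construction."""

    min_sample_prevalence: int = 3
    drop_within_sample_singletons: bool = True
    subsample_fraction: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError(
                f"subsample_fraction must be in (0, 1], got {self.subsample_fraction}"
            )
        if self.min_sample_prevalence < 0:
            raise ValueError("min_sample_prevalence must be >= 0")


@dataclass
class TrustedKmerSet:
    """The trusted oral k-mer set plus the provenance of its construction."""

    kmers: frozenset[str]
    k: int
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers


def apply_abundance_filters(
    matrix: KmerSampleMatrix, filters: TrustedSetFilters
) -> KmerSampleMatrix:
    """Clear within-sample singletons, then drop low-prevalence rows.

    Order is fixed: singleton entries (count == 1) become absent first;
    prevalence is then measured on the cleaned presence.
    """
    presence = matrix.presence
    counts = matrix.counts
    if filters.drop_within_sample_singletons:
        if counts is None:
            raise ValueError(
                "within-sample singleton removal requires per-sample counts; "
                "supply counts or disable drop_within_sample_singletons"
            )
        presence = presence & (counts != 1)
        counts = np.where(counts == 1, 0, counts)
    keep = presence.sum(axis=1) >= filters.min_sample_prevalence
    idx = np.flatnonzero(keep)
    return KmerSampleMatrix(
        kmers=[matrix.kmers[i] for i in idx],
        sample_ids=list(matrix.sample_ids),
        labels=list(matrix.labels),
        presence=presence[idx],
        counts=None if counts is None else counts[idx],
    )


def subsample_rows(
    matrix: KmerSampleMatrix, fraction: float, seed: int
) -> KmerSampleMatrix:
    """Uniformly keep ``floor(fraction * n_rows)`` rows, without replacement.

    Reproducible for a fixed seed; fraction = 1 is the identity. Selected
    rows retain their original order.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return matrix
    n_keep = int(fraction * matrix.n_kmers)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(matrix.n_kmers, size=n_keep, replace=False))
    return matrix.take_rows(idx)


def select_trusted(matrix: KmerSampleMatrix) -> TrustedKmerSet:
    """Evaluate the oral/contaminant boolean formula per row."""
    labels = np.asarray(matrix.labels)
    oral = np.isin(labels, ORAL_LABELS)
    contaminant = np.isin(labels, CONTAMINANT_LABELS)
    if not oral.any():
        raise ValueError(
            "matrix has no aOral or mOral columns; trusted-set formula is degenerate"
        )
    in_oral = matrix.presence[:, oral].any(axis=1)
    in_contaminant = matrix.presence[:, contaminant].any(axis=1)
    keep = in_oral & ~in_contaminant
    kmers = frozenset(km for km, flag in zip(matrix.kmers, keep) if flag)
    k = len(matrix.kmers[0]) if matrix.kmers else 0
    return TrustedKmerSet(
        kmers=kmers,
        k=k,
        provenance={
            "n_input_kmers": matrix.n_kmers,
            "n_trusted": len(kmers),
            "selection": "(aOral|mOral) & ~(Skin|SedimentSoil)",
        },
    )


def build_trusted_set(
    matrix: KmerSampleMatrix, filters: TrustedSetFilters | None = None
) -> TrustedKmerSet:
    """Full pipeline: subsample -> abundance filters -> boolean selection."""
    filters = filters or TrustedSetFilters()
    sub = subsample_rows(matrix, filters.subsample_fraction, filters.rng_seed)
    filtered = apply_abundance_filters(sub, filters)
    trusted = select_trusted(filtered)
    trusted.provenance.update(
        {
            "subsample_fraction": filters.subsample_fraction,
            "rng_seed": filters.rng_seed,
            "min_sample_prevalence": filters.min_sample_prevalence,
            "drop_within_sample_singletons": filters.drop_within_sample_singletons,
            "n_after_subsample": sub.n_kmers,
            "n_after_abundance_filters": filtered.n_kmers,
        }
    )
    return trusted


# ---------------------------------------------------------------------------
# File dialects: headered TSV matrix (first column "kmer", one column per
# sample, values 0/1 or counts) plus a two-column sample_id/label sidecar;
# trusted k-mer lists are one k-mer per line. All optionally gzipped.
# ---------------------------------------------------------------------------


def write_matrix(
    matrix: KmerSampleMatrix, matrix_path: str | Path, labels_path: str | Path
) -> None:
    values = matrix.counts if matrix.counts is not None else matrix.presence.astype(int)
    df = pd.DataFrame(values, index=matrix.kmers, columns=matrix.sample_ids)
    df.index.name = "kmer"
    df.to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {"sample_id": matrix.sample_ids, "label": matrix.labels}
    ).to_csv(labels_path, sep="\t", index=False)


def read_matrix(
    matrix_path: str | Path,
    labels_path: str | Path,
    has_counts: bool = True,
) -> KmerSampleMatrix:
    df = pd.read_csv(matrix_path, sep="\t", index_col="kmer")
    labels_df = pd.read_csv(labels_path, sep="\t")
    label_map = dict(zip(labels_df["sample_id"], labels_df["label"]))
    missing = [s for s in df.columns if s not in label_map]
    if missing:
        raise ValueError(f"samples missing from label sidecar: {missing}")
    values = df.to_numpy()
    counts = values.astype(np.int64) if has_counts else None
    return KmerSampleMatrix(
        kmers=[str(km) for km in df.index],
        sample_ids=list(df.columns),
        labels=[label_map[s] for s in df.columns],
        presence=values >= 1,
        counts=counts,
    )


def _text_opener(path: Path, mode: str):
    return gzip.open(path, mode + "t") if path.suffix == ".gz" else open(path, mode)


def write_kmer_list(trusted: TrustedKmerSet, path: str | Path) -> int:
    path = Path(path)
    kmers = sorted(trusted.kmers)
    with _text_opener(path, "w") as fh:
        for km in kmers:
            fh.write(km + "\n")
    return len(kmers)


def read_kmer_list(path: str | Path, cfg: KmerConfig) -> TrustedKmerSet:
    """Read one k-mer per line; canonicalize and deduplicate.

    Rejects lines of the wrong length or alphabet, naming the line number;
    warns when input contained non-canonical spellings.
    """
    path = Path(path)
    kmers: set[str] = set()
    non_canonical = 0
    with _text_opener(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            word = line.strip().upper()
            if not word:
                continue
            if len(word) != cfg.k:
                raise ValueError(
                    f"{path}, line {lineno}: k-mer length {len(word)} != k={cfg.k}"
                )
            if any(c not in "ACGT" for c in word):
                raise ValueError(
                    f"{path}, line {lineno}: k-mer contains characters outside ACGT"
                )
            canon = canonicalize(word)
            if canon != word:
                non_canonical += 1
            kmers.add(canon)
    if non_canonical:
        warnings.warn(
            f"{path}: {non_canonical} k-mer(s) were not in canonical form; "
            "canonicalized on read",
            stacklevel=2,
        )
    return TrustedKmerSet(
        kmers=frozenset(kmers),
        k=cfg.k,
        provenance={"source": str(path), "n_lines_canonicalized": non_canonical},
    )
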