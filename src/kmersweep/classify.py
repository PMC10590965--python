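"""Two-pass anchor-read classification of metagenomic reads.

Pass 1 scans every read against the trusted-k-mer membership structure
(normally a Bloom filter); a read with two consecutive matches — matches
at adjacent window start positions, overlapping by k-1 bases — is an
*anchor* read. Requiring two consecutive matches is permissive while
protecting against a single Bloom-filter false positive pulling in a
contaminant read.

Pass 2 k-merizes all anchor reads into an exact *anchor k-mer set* (this
is how the method picks up putative ancient k-mers absent from the
trusted set), rescans the input, and retains every read whose proportion
of k-mers found in the anchor set is at least the threshold tau (default
0.5, inclusive). Non-anchor reads can be retained; that is the point of
the second pass.

The one-pass baseline retains exactly the Pass-1 anchors.

:class:`TwoPassReadClassifier` packages the procedure as a scikit-learn
style estimator: ``fit`` ingests trusted k-mers (building a Bloom filter
or an exact set), ``predict`` labels reads retained/discarded. The
module-level ``run_two_pass`` / ``run_one_pass`` functions are thin
wrappers. Prediction is transductive: the anchor k-mer set is rebuilt
from each corpus passed to ``predict``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator

from .bloom import BloomConfig, BloomFilter, ExactKmerSet
from .fastx import ReadRecord, format_annotation_fields
from .kmers import KmerConfig, iter_canonical_kmers

__all__ = [
    "ClassifierConfig",
    "ReadAnnotation",
    "TwoPassReadClassifier",
    "find_anchor",
    "collect_anchor_set",
    "classify_read",
    "run_two_pass",
    "run_one_pass",
    "decontaminate_fastx",
]

Membership = Union[BloomFilter, ExactKmerSet]


@dataclass(frozen=True)
class ClassifierConfig:
    """Retention parameters.

    tau: anchor-proportion threshold in [0, 1]; a read is retained when
        the fraction of its valid k-mer windows found in the anchor k-mer
        set is >= tau (inclusive). Default 0.5.
    consecutive_required: number of adjacent-start matches that promote a
        read to anchor status; fixed at 2 by the method.
    mode: "two_pass" (anchor harvest + proportion threshold) or
        "one_pass" (retain anchors directly).
    """

    tau: float = 0.5
    consecutive_required: int = 2
    mode: str = "two_pass"

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError(f"tau must be in [0, 1], got {self.tau}")
        if self.consecutive_required != 2:
            raise ValueError("the anchor criterion is fixed at 2 consecutive matches")
        if self.mode not in ("two_pass", "one_pass"):
            raise ValueError(f"mode must be 'two_pass' or 'one_pass', got {self.mode!r}")


@dataclass
class ReadAnnotation:
    """Per-read outcome: anchor status, anchor proportion, retention."""

    seq_id: str
    read_len: int
    is_consecutive_match_found: bool
    anchor_proportion: float
    retained: bool

    def header_fields(self) -> str:
        return format_annotation_fields(
            self.read_len, self.is_consecutive_match_found, self.anchor_proportion
        )


def find_anchor(read: ReadRecord | str, membership: Membership, kcfg: KmerConfig) -> bool:
    """True iff the read has trusted-k-mer matches at two adjacent starts.

    Both windows must be valid (ACGT-only): a window broken by N cannot
    pair with its neighbour. Reads with fewer than two valid windows are
    never anchors.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    prev_pos = -2
    for pos, kmer in iter_canonical_kmers(seq, kcfg):
        if membership.query(kmer):
            if pos == prev_pos + 1:
                return True
            prev_pos = pos
    return False


def collect_anchor_set(
    reads: Sequence[ReadRecord | str], membership: Membership, kcfg: KmerConfig
) -> tuple[frozenset[str], list[bool]]:
    """Pass 1: anchor flags per read and the union of anchor-read k-mers."""
    flags: list[bool] = []
    anchor_kmers: set[str] = set()
    for read in reads:
        seq = read.sequence if isinstance(read, ReadRecord) else read
        is_anchor = find_anchor(seq, membership, kcfg)
        flags.append(is_anchor)
        if is_anchor:
            anchor_kmers.update(km for _, km in iter_canonical_kmers(seq, kcfg))
    return frozenset(anchor_kmers), flags


def anchor_proportion(seq: str, anchors: frozenset[str], kcfg: KmerConfig) -> float:
    """Fraction of valid k-mer windows whose k-mer is in the anchor set.

    Defined as 0 for reads with zero valid windows.
    """
    total = 0
    hits = 0
    for _, kmer in iter_canonical_kmers(seq, kcfg):
        total += 1
        if kmer in anchors:
            hits += 1
    return hits / total if total else 0.0


def classify_read(
    read: ReadRecord | str,
    anchors: frozenset[str],
    cfg: ClassifierConfig,
    kcfg: KmerConfig,
    is_anchor: bool = False,
) -> ReadAnnotation:
    """Pass 2 decision for one read: retained iff proportion >= tau."""
    if isinstance(read, ReadRecord):
        seq, seq_id = read.sequence, read.seq_id
    else:
        seq, seq_id = read, ""
    prop = anchor_proportion(seq, anchors, kcfg)
    return ReadAnnotation(
        seq_id=seq_id,
        read_len=len(seq),
        is_consecutive_match_found=is_anchor,
        anchor_proportion=prop,
        retained=prop >= cfg.tau,
    )


class TwoPassReadClassifier(BaseEstimator):
    """Anchor-read decontamination classifier, scikit-learn flavoured.

    Parameters
    ----------
    k : int
        K-mer length (default 31).
    tau : float
        Anchor-proportion retention threshold (default 0.5).
    mode : {"two_pass", "one_pass"}
        Full algorithm or the Pass-1-only baseline.
    use_bloom : bool
        Store trusted k-mers in a Bloom filter (default) or an exact set.
    bloom_capacity, bloom_error_rate : int, float
        Bloom filter contract; capacity defaults to the number of k-mers
        given to ``fit`` when None.

    Attributes
    ----------
    membership_ : BloomFilter or ExactKmerSet
        Trusted-k-mer store built by ``fit``.
    n_trusted_kmers_ : int
        Number of distinct trusted k-mers ingested.
    """

    def __init__(
        self,
        k: int = 31,
        tau: float = 0.5,
        mode: str = "two_pass",
        use_bloom: bool = True,
        bloom_capacity: int | None = None,
        bloom_error_rate: float = 0.001,
    ):
        self.k = k
        self.tau = tau
        self.mode = mode
        self.use_bloom = use_bloom
        self.bloom_capacity = bloom_capacity
        self.bloom_error_rate = bloom_error_rate

    def _configs(self) -> tuple[ClassifierConfig, KmerConfig]:
        return (
            ClassifierConfig(tau=self.tau, mode=self.mode),
            KmerConfig(k=self.k),
        )

    def fit(self, X: Iterable[str] | Membership, y=None) -> "TwoPassReadClassifier":
        """Ingest trusted k-mers (iterable of strings) or adopt a prebuilt
        membership structure (BloomFilter / ExactKmerSet)."""
        _, kcfg = self._configs()
        if isinstance(X, (BloomFilter, ExactKmerSet)):
            if X.k != self.k:
                raise ValueError(
                    f"membership structure has k={X.k}, estimator has k={self.k}"
                )
            self.membership_ = X
            self.n_trusted_kmers_ = (
                len(X) if isinstance(X, ExactKmerSet) else X.inserted_count
            )
            return self
        kmers = list(X)
        if self.use_bloom:
            capacity = self.bloom_capacity or max(1, len(kmers))
            bf = BloomFilter(
                BloomConfig(capacity=capacity, error_rate=self.bloom_error_rate),
                k=kcfg.k,
            )
            bf.insert_many(kmers)
            self.membership_ = bf
        else:
            self.membership_ = ExactKmerSet(kmers, k=kcfg.k)
        self.n_trusted_kmers_ = len(set(kmers))
        return self

    def annotate(self, X: Sequence[ReadRecord | str]) -> list[ReadAnnotation]:
        """Run the configured algorithm over a read corpus.

        ``X`` must be re-iterable (a sequence); generators are spooled.
        Returns one annotation per input read, in input order.
        """
        if not hasattr(self, "membership_"):
            raise RuntimeError("classifier is not fitted; call fit() first")
        if not isinstance(X, Sequence):
            X = list(X)
        cfg, kcfg = self._configs()
        anchors, flags = collect_anchor_set(X, self.membership_, kcfg)
        annotations: list[ReadAnnotation] = []
        for i, read in enumerate(X):
            if cfg.mode == "one_pass":
                if isinstance(read, ReadRecord):
                    seq, seq_id = read.sequence, read.seq_id
                else:
                    seq, seq_id = read, f"read{i}"
                ann = ReadAnnotation(
                    seq_id=seq_id,
                    read_len=len(seq),
                    is_consecutive_match_found=flags[i],
                    anchor_proportion=0.0,
                    retained=flags[i],
                )
            else:
                ann = classify_read(read, anchors, cfg, kcfg, is_anchor=flags[i])
                if not ann.seq_id:
                    ann.seq_id = f"read{i}"
            annotations.append(ann)
        return annotations

    def predict(self, X: Sequence[ReadRecord | str]) -> np.ndarray:
        """Boolean retention decision per read."""
        return np.array([a.retained for a in self.annotate(X)], dtype=bool)


def run_two_pass(
    reads: Sequence[ReadRecord],
    membership: Membership,
    cfg: ClassifierConfig | None = None,
    kcfg: KmerConfig | None = None,
) -> tuple[list[ReadRecord], list[ReadAnnotation]]:
    """Full two-pass run against a prebuilt membership structure."""
    cfg = cfg or ClassifierConfig()
    kcfg = kcfg or KmerConfig(k=membership.k)
    est = TwoPassReadClassifier(k=kcfg.k, tau=cfg.tau, mode="two_pass").fit(membership)
    annotations = est.annotate(reads)
    retained = [r for r, a in zip(reads, annotations) if a.retained]
    return retained, annotations


def decontaminate_fastx(
    in_path,
    membership: Membership,
    out_path,
    annotations_path=None,
    cfg: ClassifierConfig | None = None,
    kcfg: KmerConfig | None = None,
) -> tuple[int, int]:
    """Stream a FASTA/FASTQ file through the classifier, twice.

    The input is re-opened for the second pass, so read storage stays
    constant-memory; only the anchor k-mer set is held in RAM. Retained
    reads go to ``out_path`` (FASTA in, FASTA out) with the annotated
    header; an optional TSV sidecar records every read's annotation.
    Returns ``(n_input, n_retained)``.
    """
    from . import fastx

    cfg = cfg or ClassifierConfig()
    kcfg = kcfg or KmerConfig(k=membership.k)
    fmt = fastx.sniff_format(in_path)

    one_pass = cfg.mode == "one_pass"
    anchor_kmers: set[str] = set()
    flags: list[bool] = []
    for read in fastx.open_reads(in_path):
        is_anchor = find_anchor(read.sequence, membership, kcfg)
        flags.append(is_anchor)
        if is_anchor and not one_pass:
            anchor_kmers.update(
                km for _, km in iter_canonical_kmers(read.sequence, kcfg)
            )
    anchors = frozenset(anchor_kmers)

    n_in = 0
    n_out = 0
    ann_rows = []

    def retained_stream():
        nonlocal n_in, n_out
        for i, read in enumerate(fastx.open_reads(in_path)):
            n_in += 1
            if one_pass:
                ann = ReadAnnotation(
                    seq_id=read.seq_id,
                    read_len=len(read.sequence),
                    is_consecutive_match_found=flags[i],
                    anchor_proportion=0.0,
                    retained=flags[i],
                )
            else:
                ann = classify_read(read, anchors, cfg, kcfg, is_anchor=flags[i])
            ann_rows.append(
                (
                    ann.seq_id,
                    ann.read_len,
                    int(ann.is_consecutive_match_found),
                    round(ann.anchor_proportion, 4),
                    int(ann.retained),
                )
            )
            if ann.retained:
                n_out += 1
                yield read, ann.header_fields()

    count = fastx.write_reads(retained_stream(), out_path, fmt=fmt)
    assert count == n_out
    if annotations_path is not None:
        import pandas as pd

        pd.DataFrame(
            ann_rows,
            columns=[
                "SeqId",
                "ReadLen",
                "isConsecutiveMatchFound",
                "AnchorProportion",
                "retained",
            ],
        ).to_csv(annotations_path, sep="\t", index=False)
    return n_in, n_out


def run_one_pass(
    reads: Sequence[ReadRecord],
    membership: Membership,
    cfg: ClassifierConfig | None = None,
    kcfg: KmerConfig | None = None,
) -> tuple[list[ReadRecord], list[ReadAnnotation]]:
    """Pass-1-only baseline: retained iff the anchor criterion fires."""
    cfg = cfg or ClassifierConfig(mode="one_pass")
    kcfg = kcfg or KmerConfig(k=membership.k)
    est = TwoPassReadClassifier(k=kcfg.k, tau=cfg.tau, mode="one_pass").fit(membership)
    annotations = est.annotate(reads)
    retained = [r for r, a in zip(reads, annotations) if a.retained]
    return retained, annotations
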