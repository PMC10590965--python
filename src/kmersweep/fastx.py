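"""Streaming FASTA/FASTQ input and annotated output.

Parsing delegates to Biopython's tuple iterators (SimpleFastaParser,
FastqGeneralIterator); this module adds gzip handling, format sniffing
from the first non-blank byte, 1-based record-index error reporting, and
the annotated output header dialect used for retained reads:

    @<SeqId> ReadLen=<int> isConsecutiveMatchFound=<0|1> AnchorProportion=<0.xxxx>

CRLF is tolerated on input; LF is emitted on output.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadRecord",
    "FastxParseError",
    "open_reads",
    "sniff_format",
    "write_reads",
    "format_annotation_fields",
    "parse_annotation_fields",
]


@dataclass
class ReadRecord:
    """One sequencing read. ``qualities`` is present iff the source was FASTQ."""

    seq_id: str
    sequence: str
    description: str = ""
    qualities: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.seq_id!r}: quality string length "
                f"{len(self.qualities)} != sequence length {len(self.sequence)}"
            )


class FastxParseError(ValueError):
    """Malformed FASTA/FASTQ record, reported with its 1-based index."""

    def __init__(self, record_index: int, reason: str):
        self.record_index = record_index
        super().__init__(f"record {record_index}: {reason}")


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    raw = open(path, "rb")
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), newline=None)
    return io.TextIOWrapper(raw, newline=None)


def sniff_format(path: str | Path) -> str:
    """Return ``"fasta"`` or ``"fastq"`` from the first non-blank byte."""
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line[0] == ">":
                return "fasta"
            if line[0] == "@":
                return "fastq"
            raise FastxParseError(1, f"unrecognized leading character {line[0]!r}")
    raise FastxParseError(1, "empty file")


def _split_title(title: str) -> tuple[str, str]:
    parts = title.split(None, 1)
    if not parts:
        return "", ""
    return parts[0], (parts[1] if len(parts) > 1 else "")


def open_reads(path: str | Path) -> Iterator[ReadRecord]:
    """Lazily stream records from a FASTA/FASTQ file, plain or gzipped."""
    fmt = sniff_format(path)
    fh = _open_text(path)
    index = 0
    try:
        if fmt == "fasta":
            parser: Iterable = SimpleFastaParser(fh)
            for title, seq in parser:
                index += 1
                seq_id, desc = _split_title(title)
                yield ReadRecord(seq_id=seq_id, sequence=seq.strip(), description=desc)
        else:
            try:
                for title, seq, qual in FastqGeneralIterator(fh):
                    index += 1
                    seq_id, desc = _split_title(title)
                    if len(qual) != len(seq):
                        raise FastxParseError(
                            index, f"quality length {len(qual)} != sequence length {len(seq)}"
                        )
                    yield ReadRecord(
                        seq_id=seq_id, sequence=seq, description=desc, qualities=qual
                    )
            except ValueError as exc:
                if isinstance(exc, FastxParseError):
                    raise
                raise FastxParseError(index + 1, str(exc)) from exc
    finally:
        fh.close()


def format_annotation_fields(
    read_len: int, is_consecutive_match_found: bool, anchor_proportion: float
) -> str:
    return (
        f"ReadLen={read_len} "
        f"isConsecutiveMatchFound={1 if is_consecutive_match_found else 0} "
        f"AnchorProportion={anchor_proportion:.4f}"
    )


def parse_annotation_fields(description: str) -> dict:
    """Parse the key=value annotation dialect back into typed values."""
    out: dict = {}
    for token in description.split():
        if "=" not in token:
            continue
        key, value = token.split("=", 1)
        if key == "ReadLen":
            out["read_len"] = int(value)
        elif key == "isConsecutiveMatchFound":
            out["is_consecutive_match_found"] = bool(int(value))
        elif key == "AnchorProportion":
            out["anchor_proportion"] = float(value)
    return out


def write_reads(
    records: Iterable[tuple[ReadRecord, Optional[str]]],
    path: str | Path,
    fmt: str,
) -> int:
    """Write ``(record, annotation_string_or_None)`` pairs; return the count.

    ``fmt`` is ``"fasta"`` or ``"fastq"``; FASTA output drops qualities.
    The annotation string, when given, replaces the record description.
    """
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {fmt!r}")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    count = 0
    with opener(path, "wt") as fh:
        for record, annotation in records:
            desc = annotation if annotation is not None else record.description
            header = f"{record.seq_id} {desc}".rstrip()
            if fmt == "fasta":
                fh.write(f">{header}\n{record.sequence}\n")
            else:
                qual = record.qualities
                if qual is None:
                    qual = "I" * len(record.sequence)
                fh.write(f"@{header}\n{record.sequence}\n+\n{qual}\n")
            count += 1
    return count
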