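"""FASTA/FASTQ input and output and the sequence record model.

Every downstream stage (primer matching, filtering, clustering) consumes
:class:`SequenceRecord` objects produced here.  Sequences are normalised to
uppercase on ingest and restricted to the nucleotide alphabet {A, C, G, T, N};
qualities are Phred scores decoded from ASCII at a configurable offset
(33 by default, matching modern Illumina output).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

ALPHABET = frozenset("ACGTN")

__all__ = [
    "SequenceRecord",
    "ParseError",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
]


class ParseError(ValueError):
    """Malformed FASTA/FASTQ input; the message names the offending line."""


@dataclass
class SequenceRecord:
    """One read or reference sequence with optional per-base qualities.

    Parameters
    ----------
    id : str
        Record label (FASTA/FASTQ header without the marker character).
    seq : str
        Nucleotide string over {A, C, G, T, N}; lowercase input is accepted
        and uppercased.
    qual : list of int, optional
        Phred scores, one per base, all >= 0.
    sample : str, optional
        Sample label attached during demultiplexing.
    """

    id: str
    seq: str
    qual: list[int] | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: sequence contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}"
            )
        self.seq = seq
        if self.qual is not None:
            if len(self.qual) != len(seq):
                raise ValueError(
                    f"record {self.id!r}: quality length {len(self.qual)} != "
                    f"sequence length {len(seq)}"
                )
            if any(q < 0 for q in self.qual):
                raise ValueError(f"record {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.seq)

    def mean_quality(self) -> float:
        """Mean Phred score; raises if the record carries no qualities."""
        if self.qual is None:
            raise ValueError(f"record {self.id!r} has no qualities")
        return sum(self.qual) / len(self.qual)


def _open_text(path: str | Path, mode: str = "rt"):
    # decompress-on-open convenience for .gz inputs
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of records, order preserved.

    Multi-line sequences are concatenated.  Raises :class:`ParseError` for a
    sequence line appearing before any header or a header with an empty
    sequence, naming the line number.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        if not chunks:
            raise ParseError(f"line {header_line}: header {header!r} has an empty sequence")
        records.append(SequenceRecord(id=header, seq="".join(chunks)))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                header_line = lineno
                chunks = []
                if not header.strip():
                    raise ParseError(f"line {lineno}: empty FASTA header")
            else:
                if header is None:
                    raise ParseError(f"line {lineno}: sequence data before any '>' header")
                chunks.append(line.strip())
        flush()
    return records


def read_fastq(path: str | Path, phred_offset: int = 33) -> list[SequenceRecord]:
    """Read 4-line FASTQ records, decoding qualities as ``ord(char) - offset``.

    Raises :class:`ParseError` on a truncated record, a seq/qual length
    mismatch, or a decoded quality below zero (which suggests a wrong
    ``phred_offset``).
    """
    if phred_offset not in (33, 64):
        raise ValueError(f"phred_offset must be 33 or 64, got {phred_offset}")
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    # drop trailing blank lines only
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise ParseError(
            f"line {len(lines)}: truncated FASTQ record (file has {len(lines)} "
            "lines, not a multiple of 4)"
        )
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise ParseError(f"line {lineno}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise ParseError(f"line {lineno + 2}: expected '+' separator")
        if len(qual) != len(seq):
            raise ParseError(
                f"line {lineno + 3}: quality length {len(qual)} != sequence "
                f"length {len(seq)} for record {head[1:]!r}"
            )
        scores = [ord(c) - phred_offset for c in qual]
        if any(q < 0 for q in scores):
            raise ParseError(
                f"line {lineno + 3}: negative Phred score after decoding — "
                f"wrong phred_offset ({phred_offset})?"
            )
        records.append(SequenceRecord(id=head[1:], seq=seq, qual=scores))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, line_width: int = 80
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``line_width`` columns."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width] + "\n")


def write_fastq(
    records: Iterable[SequenceRecord], path: str | Path, phred_offset: int = 33
) -> None:
    """Write records as 4-line FASTQ; every record must carry qualities."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            qual = "".join(chr(q + phred_offset) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
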