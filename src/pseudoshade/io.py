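"""Sequence file input.

FASTA/FASTQ is auto-detected from the first non-blank character ('>' vs '@');
gzip compression is detected from the magic bytes, so ``.gz`` extensions are
honoured but not required.  Parsing is delegated to Biopython's SeqIO.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path: str | Path) -> _io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def sniff_format(path: str | Path) -> str:
    """Return ``"fasta"`` or ``"fastq"`` based on the first non-blank character."""
    with _open_text(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped[0] == ">":
                return "fasta"
            if stripped[0] == "@":
                return "fastq"
            raise ValueError(
                f"{path}: not FASTA or FASTQ (first record starts with {stripped[0]!r})"
            )
    raise ValueError(f"{path}: file is empty")


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(record_id, uppercased_sequence)`` from a FASTA/FASTQ file."""
    fmt = sniff_format(path)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_fastq(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
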