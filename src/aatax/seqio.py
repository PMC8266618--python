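"""Thin FASTA/FASTQ reading helpers (Biopython SeqIO underneath)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

from Bio import SeqIO

__all__ = ["sniff_format", "read_records"]


def sniff_format(path) -> str:
    """Return 'fasta' or 'fastq' from the first non-blank character."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            break
    raise ValueError(f"{path}: neither FASTA nor FASTQ")


def read_records(path) -> Iterator[tuple[str, str, str]]:
    """Yield (record_id, full_header, uppercased_sequence) per record.

    Quality lines of FASTQ are ignored.
    """
    path = Path(path)
    fmt = sniff_format(path)
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, rec.description, str(rec.seq).upper()
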