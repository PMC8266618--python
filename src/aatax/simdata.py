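"""Synthetic references, mutated reads, and read-level evaluation.

A desk-scale robustness benchmark: i.i.d. uniform-ACGT genomes (one per
taxon, so references are disjoint with overwhelming probability), reads of
a fixed length sampled uniformly from them, and independent per-base
substitution at a chosen rate — emulating sequencing error or divergence
from the reference.  Classification quality is scored per read: the
top-ranked taxon of each read is compared with the truth, giving
sensitivity, precision and F1.

Defaults mirror the study conditions the benchmark stands in for: reads of
length 100 and substitution rates up to 20%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .content import TaxonomyMap, resolve_level

__all__ = [
    "TruthRow",
    "sample_genomes",
    "sample_reads",
    "mutate_reads",
    "write_fasta",
    "write_fastq",
    "write_truth",
    "read_truth",
    "evaluate",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_ROOT_TAX_ID = 1
_FIRST_TAX_ID = 101
DEFAULT_READ_LENGTH = 100


@dataclass
class TruthRow:
    read_id: str
    tax_id: int
    mutation_rate: float
    accession: str
    position: int


def sample_genomes(n_taxa: int, genome_len: int, seed: int
                   ) -> tuple[list[tuple[str, str]], TaxonomyMap]:
    """Uniform random genomes, one per taxon, plus a flat toy taxonomy.

    Returns ``[(accession, sequence), ...]`` and a TaxonomyMap in which
    taxon i has tax_id 101+i (rank "species") under a single root.
    """
    if n_taxa < 1:
        raise ValueError("need at least one taxon")
    if genome_len < 300:
        raise ValueError("genome_len must be >= 300")
    rng = np.random.default_rng(seed)
    genomes: list[tuple[str, str]] = []
    acc2tax: dict[str, int] = {}
    names = {_ROOT_TAX_ID: "root"}
    parents = {_ROOT_TAX_ID: (_ROOT_TAX_ID, "root")}
    for i in range(n_taxa):
        seq = rng.choice(_BASES, size=genome_len).tobytes().decode("ascii")
        acc = f"SYN{i:04d}.1"
        tax_id = _FIRST_TAX_ID + i
        genomes.append((acc, seq))
        acc2tax[acc] = tax_id
        names[tax_id] = f"synthetic_taxon_{i}"
        parents[tax_id] = (_ROOT_TAX_ID, "species")
    return genomes, TaxonomyMap(acc2tax=acc2tax, names=names, parents=parents)


def sample_reads(genomes: list[tuple[str, str]], taxonomy: TaxonomyMap,
                 n_reads: int, read_len: int = DEFAULT_READ_LENGTH,
                 seed: int = 0, reverse_strand: bool = False
                 ) -> tuple[list[tuple[str, str]], list[TruthRow]]:
    """Sample forward-strand reads uniformly over genomes and positions.

    With ``reverse_strand`` half the reads (chosen at random) are reverse
    complemented.  Returns ``[(read_id, seq), ...]`` and one truth row per
    read.
    """
    from .encoding import reverse_complement

    if any(read_len > len(seq) for _a, seq in genomes):
        raise ValueError("read_len exceeds a genome length")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(genomes), size=n_reads)
    reads: list[tuple[str, str]] = []
    truth: list[TruthRow] = []
    for i, g in enumerate(picks):
        acc, seq = genomes[g]
        pos = int(rng.integers(0, len(seq) - read_len + 1))
        fragment = seq[pos:pos + read_len]
        if reverse_strand and rng.random() < 0.5:
            fragment = reverse_complement(fragment)
        read_id = f"read{i:06d}"
        reads.append((read_id, fragment))
        truth.append(TruthRow(read_id=read_id, tax_id=taxonomy.acc2tax[acc],
                              mutation_rate=0.0, accession=acc, position=pos))
    return reads, truth


def mutate_reads(reads: list[tuple[str, str]], p: float, seed: int = 0
                 ) -> list[tuple[str, str]]:
    """Substitute each base independently with probability p.

    A mutated base is drawn uniformly from the three *other* bases, so at
    p=1 no position keeps its original base.  Non-ACGT letters are left
    untouched.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mutation rate must be in [0, 1], got {p}")
    if p == 0.0:
        return list(reads)
    rng = np.random.default_rng(seed)
    base_index = {b: i for i, b in enumerate("ACGT")}
    out: list[tuple[str, str]] = []
    for read_id, seq in reads:
        hit = rng.random(len(seq)) < p
        if not hit.any():
            out.append((read_id, seq))
            continue
        chars = list(seq)
        # uniform over the 3 alternatives: shift the base index by 1..3 mod 4
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        j = 0
        for i in np.flatnonzero(hit):
            b = chars[i]
            if b in base_index:
                chars[i] = "ACGT"[(base_index[b] + int(shifts[j])) % 4]
            j += 1
        out.append((read_id, "".join(chars)))
    return out


def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(reads: list[tuple[str, str]], path, quality_char: str = "I") -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_truth(truth: list[TruthRow], path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write("read_id\ttax_id\tmutation_rate\taccession\tposition\n")
        for row in truth:
            fh.write(f"{row.read_id}\t{row.tax_id}\t{row.mutation_rate}"
                     f"\t{row.accession}\t{row.position}\n")


def read_truth(path) -> list[TruthRow]:
    out: list[TruthRow] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        assert header.startswith("read_id")
        for line in fh:
            read_id, tax_id, rate, acc, pos = line.rstrip("\n").split("\t")
            out.append(TruthRow(read_id=read_id, tax_id=int(tax_id),
                                mutation_rate=float(rate), accession=acc,
                                position=int(pos)))
    return out


def evaluate(predictions: dict[str, int | None], truth: list[TruthRow],
             level: str = "lowest", taxonomy: TaxonomyMap | None = None
             ) -> tuple[float, float, float]:
    """Per-read sensitivity, precision and F1 of top-ranked predictions.

    ``predictions`` maps read_id to the top-ranked tax_id (or None for an
    unclassified read).  A correct prediction at the requested level is a
    true positive; a wrong one counts as both a false positive and a false
    negative; an unclassified read is a false negative only.  Undefined
    ratios are reported as 0.
    """
    truth_by_read = {row.read_id: row.tax_id for row in truth}
    unknown = set(predictions) - set(truth_by_read)
    if unknown:
        raise ValueError(f"predictions for reads absent from truth: {sorted(unknown)[:5]}")

    def at_level(tax_id: int) -> int:
        if level == "lowest" or taxonomy is None:
            return tax_id
        return resolve_level(tax_id, level, taxonomy)

    tp = fp = fn = 0
    for read_id, true_tax in truth_by_read.items():
        pred = predictions.get(read_id)
        if pred is None:
            fn += 1
        elif at_level(pred) == at_level(true_tax):
            tp += 1
        else:
            fp += 1
            fn += 1
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * sensitivity * precision / (sensitivity + precision)
          if sensitivity + precision else 0.0)
    return sensitivity, precision, f1


def top_predictions(scored: dict) -> dict[str, int | None]:
    """Top-ranked tax_id per read from an identification result."""
    return {read_id: (rows[0].tax_id if rows else None)
            for read_id, rows in scored.items()}
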