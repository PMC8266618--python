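"""Read identification: variable-k matching against the index, two scores.

Reads are converted to sorted (k-mer, read) pairs exactly like references
during the build — except that each k-mer carries a read ID instead of a
taxon and duplicates are kept, since repeated k-mers may mark motifs.  The
matcher then compares input k-mers with index entries for every k in the
requested range: a k-match means the first k letters agree, so the set of
taxa matched at k can only shrink as k grows, and recording matches per k
independently is equivalent to extending a match upward from the lowest k.

Two scores summarise the evidence per (read, taxon):

* the k-mer score, a weighted sum over matches with weights w(k) = k²/625
  (k² normalised to (0, 1] over k = 1..25) — longer matches count more but
  short ones still contribute; each k-mer's contribution is split evenly
  among the taxa it matched at that k;
* the relative score, the k-mer score divided by
  1 + log2(read length · taxon frequency), which discounts taxa that are
  simply big (many index entries) and reads that are simply long.

For a read of length 100, a relative score below about 0.4 is empirically
insignificant; an optional cutoff drops such rows.
"""

from __future__ import annotations

import json
import logging
import math
from bisect import bisect_left
from dataclasses import dataclass, field
from itertools import groupby
from pathlib import Path

from . import encoding, seqio
from .encoding import PackedKmer, TranslationTable, standard_table
from .index import Index, TRIE_DEPTH, trie_lookup

__all__ = [
    "WeightScheme",
    "MatchTable",
    "ScoredMatch",
    "reads_to_pairs",
    "match",
    "kmer_score",
    "relative_score",
    "score_table",
    "identify_reads",
    "write_identification",
    "DEFAULT_SIGNIFICANCE_CUTOFF",
]

logger = logging.getLogger(__name__)

_BITS = 5
#: Relative scores below this are empirically insignificant for 100 nt
#: reads; applied only when the caller asks for filtering.
DEFAULT_SIGNIFICANCE_CUTOFF = 0.4
_WEIGHT_NORM = 25 * 25  # k² normalised to (0,1] over k = 1..25


@dataclass(frozen=True)
class WeightScheme:
    """The k range and the weight w(k) = k²/625 of a match at length k."""

    k_lower: int = 7
    k_upper: int = 12

    def __post_init__(self) -> None:
        if not 1 <= self.k_lower <= self.k_upper:
            raise ValueError(f"need 1 <= k_lower <= k_upper, got "
                             f"[{self.k_lower}, {self.k_upper}]")

    def weight(self, k: int) -> float:
        return k * k / _WEIGHT_NORM

    @property
    def ks(self) -> range:
        return range(self.k_lower, self.k_upper + 1)


@dataclass
class MatchTable:
    """Match evidence accumulated over (possibly chunked) input.

    ``match_counts[(r, t, k)]`` — input k-mer occurrences of read r whose
    k-prefix matches an index entry of taxon t (duplicates counted).
    ``weighted[(r, t, k)]`` — the same occurrences, each divided by the
    number of taxa that k-mer matched at k (the k-mer score summand).
    ``prefix_taxa[k][v]`` — (matched taxa, input occurrence count) per
    matched k-prefix v; feeds the taxonomic profile.
    ``input_occurrences[k]`` — all input k-mer occurrences participating at
    k, matched or not (padded k-mers participate only up to their length).
    """

    k_lower: int
    k_upper: int
    match_counts: dict = field(default_factory=dict)
    weighted: dict = field(default_factory=dict)
    prefix_taxa: dict = field(default_factory=dict)
    input_occurrences: dict = field(default_factory=dict)

    def merge(self, other: "MatchTable") -> None:
        """Fold in the table of another input chunk (same index)."""
        if (self.k_lower, self.k_upper) != (other.k_lower, other.k_upper):
            raise ValueError("cannot merge tables with different k ranges")
        for key, n in other.match_counts.items():
            self.match_counts[key] = self.match_counts.get(key, 0) + n
        for key, w in other.weighted.items():
            self.weighted[key] = self.weighted.get(key, 0.0) + w
        for k, per_v in other.prefix_taxa.items():
            mine = self.prefix_taxa.setdefault(k, {})
            for v, (taxa, c) in per_v.items():
                if v in mine:
                    mine[v] = (taxa, mine[v][1] + c)
                else:
                    mine[v] = (taxa, c)
        for k, n in other.input_occurrences.items():
            self.input_occurrences[k] = self.input_occurrences.get(k, 0) + n

    def matched_read_taxon_pairs(self) -> set:
        return {(r, t) for (r, t, _k) in self.match_counts}

    def match_count(self, read, taxon, k) -> int:
        return self.match_counts.get((read, taxon, k), 0)


@dataclass
class ScoredMatch:
    read_id: str
    taxon_line: int
    tax_id: int
    name: str
    kmer_score: float
    relative_score: float
    read_length: int


def reads_to_pairs(reads, frames: int = 3, k_max: int = 12, k_lower: int = 7,
                   table: TranslationTable | None = None,
                   protein: bool = False) -> list[tuple[PackedKmer, str]]:
    """Convert reads to the sorted (k-mer, read ID) pair list.

    ``reads`` is an iterable of (read_id, sequence).  Each read is
    translated in ``frames`` reading frames (protein input skips
    translation) and every full-length window — plus one padded window when
    a whole frame is shorter than k_max — becomes a pair.  Pairs are sorted
    by (k-mer value, read ID); duplicates are kept.
    """
    table = table or standard_table()
    pairs: list[tuple[PackedKmer, str]] = []
    for read_id, seq in reads:
        produced = False
        if protein:
            frame_strings = [seq.upper()]
        else:
            frame_strings = encoding.frames_of(seq, frames, table)
        for letters in frame_strings:
            for _pos, kmer in encoding.kmers_of(letters, k_max, k_lower, table):
                pairs.append((kmer, read_id))
                produced = True
        if not produced:
            logger.info("read %s too short to produce any k-mer; unclassified", read_id)
    pairs.sort(key=lambda p: (p[0].value, p[1]))
    return pairs


def match(pairs, index: Index, scheme: WeightScheme) -> MatchTable:
    """Match sorted input pairs against the index for every k in the range.

    For each k, input k-prefixes are swept in sorted order; the trie
    restricts each comparison to the slice of entries sharing the 6-letter
    prefix, and a prefix match at k records the occurrence for every
    matched taxon.  Padded input k-mers participate only at k up to their
    valid length.
    """
    if scheme.k_upper > index.k_max:
        raise ValueError(f"k_upper {scheme.k_upper} exceeds index k_max {index.k_max}")
    if index.meta.shrunken_lossless and scheme.k_lower < 7:
        raise ValueError("losslessly shrunken index requires k_lower >= 7")
    table = MatchTable(k_lower=scheme.k_lower, k_upper=scheme.k_upper)
    values = index.values
    taxa = index.taxa
    k_max = index.k_max
    n = len(values)
    for k in scheme.ks:
        shift = _BITS * (k_max - k)
        eligible = [(p[0].value >> shift, p[1]) for p in pairs if p[0].valid_len >= k]
        table.input_occurrences[k] = len(eligible)
        per_v = table.prefix_taxa.setdefault(k, {})
        for v, group in groupby(eligible, key=lambda e: e[0]):
            read_counts: dict[str, int] = {}
            for _v, read_id in group:
                read_counts[read_id] = read_counts.get(read_id, 0) + 1
            if k >= TRIE_DEPTH:
                probe = PackedKmer(value=v << shift, k_max=k_max, valid_len=k)
                lo, hi = trie_lookup(index.trie, probe)
            else:
                lo, hi = 0, n
            if lo == hi:
                continue
            lo2 = bisect_left(values, v << shift, lo, hi)
            hi2 = bisect_left(values, (v + 1) << shift, lo2, hi)
            if lo2 == hi2:
                continue
            matched = tuple(sorted(set(taxa[lo2:hi2])))
            c = sum(read_counts.values())
            per_v[v] = (matched, c)
            split = 1.0 / len(matched)
            for read_id, cnt in read_counts.items():
                for t in matched:
                    key = (read_id, t, k)
                    table.match_counts[key] = table.match_counts.get(key, 0) + cnt
                    table.weighted[key] = table.weighted.get(key, 0.0) + cnt * split
    return table


def kmer_score(table: MatchTable, read_id, taxon_line: int,
               scheme: WeightScheme) -> float:
    """Weighted sum over the k range: w(k) · matches / |matched taxa|."""
    return sum(
        scheme.weight(k) * table.weighted.get((read_id, taxon_line, k), 0.0)
        for k in scheme.ks
    )


def relative_score(score: float, read_len_nt: int, frequency: int) -> float:
    """k-mer score in relation to read length and taxon index frequency."""
    if read_len_nt < 1 or frequency < 1:
        raise ValueError("read length and taxon frequency must be >= 1")
    return score / (1.0 + math.log2(read_len_nt * frequency))


def score_table(table: MatchTable, index: Index, read_lengths: dict,
                scheme: WeightScheme) -> dict[str, list[ScoredMatch]]:
    """Score every matched (read, taxon) pair and rank taxa per read.

    Rows per read are sorted by relative score descending, ties broken by
    ascending tax_id.  Reads that produced pairs but matched nothing map to
    an empty list.
    """
    per_read: dict[str, list[ScoredMatch]] = {r: [] for r in read_lengths}
    for read_id, t in sorted(table.matched_read_taxon_pairs(),
                             key=lambda rt: (str(rt[0]), rt[1])):
        s = kmer_score(table, read_id, t, scheme)
        if s <= 0:
            continue
        entry = index.content.entry_at(t)
        rs = relative_score(s, read_lengths[read_id],
                            max(1, index.frequency_of_line(t)))
        per_read.setdefault(read_id, []).append(
            ScoredMatch(read_id=read_id, taxon_line=t, tax_id=entry.tax_id,
                        name=entry.name, kmer_score=s, relative_score=rs,
                        read_length=read_lengths[read_id]))
    for rows in per_read.values():
        rows.sort(key=lambda m: (-m.relative_score, m.tax_id))
    return per_read


def identify_reads(index: Index, reads, frames: int = 3, k_lower: int = 7,
                   k_upper: int | None = None,
                   mem_budget_bytes: int = 256 * 1024 * 1024,
                   table: TranslationTable | None = None,
                   protein: bool = False,
                   ) -> tuple[dict[str, list[ScoredMatch]], MatchTable]:
    """End-to-end identification of an iterable of (read_id, seq) reads.

    Reads are processed in memory-budget-sized slices; because every score
    is a sum over matches, partitioning the input does not change the
    result.  Returns the ranked per-read matches and the merged match
    table (for profiling).
    """
    k_upper = index.k_max if k_upper is None else k_upper
    scheme = WeightScheme(k_lower=k_lower, k_upper=k_upper)
    # ~96 bytes per buffered pair, ~70 pairs per 100 nt read at 3 frames
    chunk_reads = max(1, mem_budget_bytes // (96 * 70))
    merged: MatchTable | None = None
    read_lengths: dict[str, int] = {}
    chunk: list[tuple[str, str]] = []

    def flush(chunk):
        nonlocal merged
        pairs = reads_to_pairs(chunk, frames=frames, k_max=index.k_max,
                               k_lower=k_lower, table=table, protein=protein)
        part = match(pairs, index, scheme)
        if merged is None:
            merged = part
        else:
            merged.merge(part)

    for read_id, seq in reads:
        read_lengths[read_id] = len(seq)
        chunk.append((read_id, seq))
        if len(chunk) >= chunk_reads:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    if merged is None:
        merged = MatchTable(k_lower=scheme.k_lower, k_upper=scheme.k_upper)
    scored = score_table(merged, index, read_lengths, scheme)
    return scored, merged


def read_file_records(path):
    """(read_id, sequence) pairs from a FASTA or FASTQ file."""
    for rec_id, _header, seq in seqio.read_records(path):
        yield rec_id, seq


def write_identification(scored: dict[str, list[ScoredMatch]], out_path,
                         fmt: str = "tsv", cutoff: float | None = None) -> None:
    """Write ranked identifications, one record per read.

    TSV columns: read_id, tax_id, name, relative_score, kmer_score; reads
    with no match appear with empty taxon fields.  ``cutoff`` drops rows
    below that relative score (never applied silently).
    """
    out_path = Path(out_path)
    if fmt == "tsv":
        with open(out_path, "w", encoding="utf-8") as fh:
            fh.write("read_id\ttax_id\tname\trelative_score\tkmer_score\n")
            for read_id in scored:
                rows = scored[read_id]
                if cutoff is not None:
                    rows = [m for m in rows if m.relative_score >= cutoff]
                if not rows:
                    fh.write(f"{read_id}\t\t\t\t\n")
                    continue
                for m in rows:
                    fh.write(f"{read_id}\t{m.tax_id}\t{m.name}"
                             f"\t{m.relative_score:.6g}\t{m.kmer_score:.6g}\n")
    elif fmt == "json":
        payload = []
        for read_id in scored:
            rows = scored[read_id]
            if cutoff is not None:
                rows = [m for m in rows if m.relative_score >= cutoff]
            payload.append({
                "read_id": read_id,
                "matches": [{"tax_id": m.tax_id, "name": m.name,
                             "relative_score": m.relative_score,
                             "kmer_score": m.kmer_score} for m in rows],
            })
        with open(out_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown output format {fmt!r}")


def read_identification(path) -> dict[str, list[tuple[int, float]]]:
    """Parse a TSV identification file back to read → [(tax_id, rel score)]."""
    out: dict[str, list[tuple[int, float]]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        assert header.startswith("read_id")
        for line in fh:
            read_id, tax_id, _name, rel, _s = line.rstrip("\n").split("\t")
            out.setdefault(read_id, [])
            if tax_id:
                out[read_id].append((int(tax_id), float(rel)))
    return out
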