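"""Sorted (k-mer, taxon) index with a depth-6 prefix trie.

The index is a flat, ascending-sorted array of pairs: a packed full-length
k-mer value and the content-file line number of its source taxon.  The
same k-mer may appear under several taxa (one entry each); exact duplicate
pairs are collapsed.  A prefix trie over the first six letters maps each
30-bit prefix to the half-open range of index positions sharing it, so a
lookup only ever scans a small slice of the array.

Construction honours a caller-supplied memory budget: reference sequences
are translated and packed into an in-memory buffer of pairs until the
budget is reached, the buffer is sorted, deduplicated and spilled to a
temporary sorted chunk on disk, and at the end all chunks are k-way merged
(deduplicating across chunks).  The final index is byte-identical whatever
the budget.

On disk the index is a small magic + JSON header followed by little-endian
fixed-width records, with the trie in a JSON sidecar (``<path>.trie.json``).
A losslessly shrunken index halves each record by dropping the six prefix
letters (recoverable from the trie) and narrowing the taxon handle to 16
bits; such an index can no longer be updated.
"""

from __future__ import annotations

import heapq
import json
import logging
import struct
import tempfile
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import encoding
from .content import ContentFile, LOSSLESS_MAX_ENTRIES, parse_accession
from .encoding import PackedKmer, TranslationTable, standard_table
from . import seqio

__all__ = [
    "PrefixTrie",
    "IndexMeta",
    "Index",
    "build_index",
    "trie_lookup",
    "update_index",
    "shrink_lossless",
    "shrink_lossy",
    "load_index",
    "MIN_MEM_BUDGET",
]

logger = logging.getLogger(__name__)

TRIE_DEPTH = 6
_BITS = 5
_MAGIC = b"AATAX01\n"

#: Documented floor for the build memory budget (bytes).
MIN_MEM_BUDGET = 64 * 1024
#: Rough in-memory footprint of one buffered (kmer, taxon) pair; the buffer
#: capacity is ``mem_budget // PAIR_MEM_BYTES``.
PAIR_MEM_BYTES = 96


@dataclass
class PrefixTrie:
    """Depth-6 trie stored flat: sorted 30-bit prefixes with entry ranges.

    ``leaves[p] == (lo, hi)`` means index positions [lo, hi) hold exactly
    the entries whose first six letters pack to ``p``.  Ranges are
    disjoint, ordered, and partition [0, N).
    """

    depth: int = TRIE_DEPTH
    prefixes: list[int] = field(default_factory=list)  # sorted
    lowers: list[int] = field(default_factory=list)
    uppers: list[int] = field(default_factory=list)

    @property
    def leaves(self) -> dict[int, tuple[int, int]]:
        return {p: (lo, hi) for p, lo, hi in zip(self.prefixes, self.lowers, self.uppers)}

    def lookup(self, prefix: int) -> tuple[int, int]:
        i = bisect_left(self.prefixes, prefix)
        if i < len(self.prefixes) and self.prefixes[i] == prefix:
            return self.lowers[i], self.uppers[i]
        return (0, 0)

    def owner_prefix(self, position: int) -> int:
        """Prefix of the leaf whose range contains an entry position."""
        i = bisect_right(self.lowers, position) - 1
        if i < 0 or position >= self.uppers[i]:
            raise IndexError(f"position {position} not covered by trie")
        return self.prefixes[i]

    @classmethod
    def from_values(cls, values, k_max: int) -> "PrefixTrie":
        shift = _BITS * (k_max - TRIE_DEPTH)
        prefixes: list[int] = []
        lowers: list[int] = []
        uppers: list[int] = []
        prev = None
        for pos, v in enumerate(values):
            p = v >> shift
            if p != prev:
                if prev is not None:
                    uppers.append(pos)
                prefixes.append(p)
                lowers.append(pos)
                prev = p
        if prev is not None:
            uppers.append(len(values))
        return cls(prefixes=prefixes, lowers=lowers, uppers=uppers)

    def to_json(self) -> str:
        return json.dumps(
            {"depth": self.depth,
             "leaves": [[p, lo, hi] for p, lo, hi in
                        zip(self.prefixes, self.lowers, self.uppers)]}
        )

    @classmethod
    def from_json(cls, text: str) -> "PrefixTrie":
        obj = json.loads(text)
        leaves = obj["leaves"]
        return cls(depth=obj["depth"],
                   prefixes=[l[0] for l in leaves],
                   lowers=[l[1] for l in leaves],
                   uppers=[l[2] for l in leaves])


def trie_lookup(trie: PrefixTrie, kmer: PackedKmer) -> tuple[int, int]:
    """Half-open index range of entries sharing the k-mer's 6-letter prefix."""
    if kmer.valid_len < TRIE_DEPTH:
        raise ValueError(f"k-mer has only {kmer.valid_len} letters; trie depth is {TRIE_DEPTH}")
    return trie.lookup(kmer.prefix(TRIE_DEPTH))


@dataclass
class IndexMeta:
    k_max: int
    width: int  # 64 or 128
    frames: int
    level: str
    frequencies: dict[int, int]  # content line number -> entry count
    shrunken_lossless: bool = False
    content_checksum: str = ""
    lossy_seed: int | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["frequencies"] = {str(k): v for k, v in self.frequencies.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "IndexMeta":
        d = dict(d)
        d["frequencies"] = {int(k): v for k, v in d["frequencies"].items()}
        return cls(**d)


class Index:
    """In-memory view of the index: parallel sorted value/taxon arrays.

    ``values`` are full packed k-mer integers (reconstructed from the trie
    when loading a losslessly shrunken index); ``taxa`` are content-file
    line numbers.
    """

    def __init__(self, values: list[int], taxa: list[int], meta: IndexMeta,
                 content: ContentFile, trie: PrefixTrie | None = None):
        self.values = values
        self.taxa = taxa
        self.meta = meta
        self.content = content
        self.trie = trie if trie is not None else PrefixTrie.from_values(values, meta.k_max)
        if meta.content_checksum and meta.content_checksum != content.checksum():
            raise ValueError("content file does not match the checksum bound to this index")
        self.meta.content_checksum = content.checksum()

    def __len__(self) -> int:
        return len(self.values)

    @property
    def k_max(self) -> int:
        return self.meta.k_max

    def distinct_kmer_count(self) -> int:
        return sum(1 for i, v in enumerate(self.values) if i == 0 or v != self.values[i - 1])

    def frequency_of_line(self, line: int) -> int:
        return self.meta.frequencies.get(line, 0)

    def tax_id_of_line(self, line: int) -> int:
        return self.content.entry_at(line).tax_id

    def entries_as_tax_ids(self) -> list[tuple[int, int]]:
        """(kmer value, tax_id) view for humans and tests."""
        return [(v, self.tax_id_of_line(t)) for v, t in zip(self.values, self.taxa)]

    # ---- persistence -----------------------------------------------------

    def payload_bytes(self) -> bytes:
        """The record block exactly as written to disk."""
        if self.meta.shrunken_lossless:
            suffix_mask = (1 << (_BITS * (self.meta.k_max - TRIE_DEPTH))) - 1
            return b"".join(
                struct.pack("<IH", v & suffix_mask, t)
                for v, t in zip(self.values, self.taxa)
            )
        kbytes = self.meta.width // 8
        return b"".join(
            v.to_bytes(kbytes, "little") + struct.pack("<I", t)
            for v, t in zip(self.values, self.taxa)
        )

    def save(self, path) -> None:
        path = Path(path)
        header = json.dumps({"meta": self.meta.to_dict(), "n_entries": len(self.values)}
                            ).encode("utf-8")
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<I", len(header)))
            fh.write(header)
            fh.write(self.payload_bytes())
        with open(str(path) + ".trie.json", "w", encoding="utf-8") as fh:
            fh.write(self.trie.to_json())


def load_index(path, content: ContentFile) -> Index:
    """Load an index and bind it to its content file (checksum-verified)."""
    path = Path(path)
    with open(path, "rb") as fh:
        if fh.read(len(_MAGIC)) != _MAGIC:
            raise ValueError(f"{path}: not an index file")
        (hlen,) = struct.unpack("<I", fh.read(4))
        header = json.loads(fh.read(hlen).decode("utf-8"))
        meta = IndexMeta.from_dict(header["meta"])
        n = header["n_entries"]
        payload = fh.read()
    with open(str(path) + ".trie.json", encoding="utf-8") as fh:
        trie = PrefixTrie.from_json(fh.read())
    values: list[int] = []
    taxa: list[int] = []
    if meta.shrunken_lossless:
        if meta.content_checksum != content.checksum():
            raise ValueError("content file does not match the checksum bound to this index")
        shift = _BITS * (meta.k_max - TRIE_DEPTH)
        # walk the trie leaves in order; each position's full value is the
        # owning leaf's prefix re-attached to the stored suffix
        for li in range(len(trie.prefixes)):
            hi_bits = trie.prefixes[li] << shift
            for pos in range(trie.lowers[li], trie.uppers[li]):
                suffix, line = struct.unpack_from("<IH", payload, pos * 6)
                values.append(hi_bits | suffix)
                taxa.append(line)
    else:
        kbytes = meta.width // 8
        rec = kbytes + 4
        for i in range(n):
            off = i * rec
            values.append(int.from_bytes(payload[off:off + kbytes], "little"))
            (line,) = struct.unpack_from("<I", payload, off + kbytes)
            taxa.append(line)
    return Index(values=values, taxa=taxa, meta=meta, content=content, trie=trie)


# ---- construction --------------------------------------------------------


def _width_for(k_max: int) -> int:
    if k_max == 12:
        return 64
    if k_max == 25:
        return 128
    raise ValueError(f"k_max must be 12 or 25, got {k_max}")


def _pairs_from_fastas(fasta_paths, acc2line: dict[str, int], k_max: int,
                       frames: int, table: TranslationTable):
    """Yield (kmer value, content line) pairs for every full-length window."""
    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    for path in fasta_paths:
        for rec_id, header, seq in seqio.read_records(path):
            acc = parse_accession(header) or rec_id
            if acc not in acc2line:
                raise ValueError(
                    f"accession {acc!r} is not in the content file; build content first")
            line = acc2line[acc]
            for letters in encoding.frames_of(seq, frames, table):
                # index side: full-length windows only
                for _pos, kmer in encoding.kmers_of(letters, k_max, k_max, table,
                                                    pad_short=False):
                    yield kmer.value, line


def _spill_chunk(buffer: list[tuple[int, int]], kbytes: int, tmpdir: str) -> Path:
    buffer.sort()
    fh = tempfile.NamedTemporaryFile(dir=tmpdir, suffix=".chunk", delete=False)
    prev = None
    with fh:
        for pair in buffer:
            if pair == prev:
                continue
            prev = pair
            fh.write(pair[0].to_bytes(kbytes, "little") + struct.pack("<I", pair[1]))
    return Path(fh.name)


def _read_chunk(path: Path, kbytes: int):
    rec = kbytes + 4
    data = path.read_bytes()
    for off in range(0, len(data), rec):
        yield (int.from_bytes(data[off:off + kbytes], "little"),
               struct.unpack_from("<I", data, off + kbytes)[0])


def _merge_chunks(chunks, kbytes: int) -> tuple[list[int], list[int]]:
    values: list[int] = []
    taxa: list[int] = []
    prev = None
    for pair in heapq.merge(*(_read_chunk(c, kbytes) for c in chunks)):
        if pair == prev:
            continue
        prev = pair
        values.append(pair[0])
        taxa.append(pair[1])
    return values, taxa


def _build_entries(pair_iter, mem_budget_bytes: int, kbytes: int
                   ) -> tuple[list[int], list[int]]:
    if mem_budget_bytes < MIN_MEM_BUDGET:
        raise ValueError(
            f"memory budget {mem_budget_bytes} below floor {MIN_MEM_BUDGET} bytes")
    capacity = max(1, mem_budget_bytes // PAIR_MEM_BYTES)
    chunks: list[Path] = []
    buffer: list[tuple[int, int]] = []
    with tempfile.TemporaryDirectory(prefix="aatax-build-") as tmpdir:
        for pair in pair_iter:
            buffer.append(pair)
            if len(buffer) >= capacity:
                chunks.append(_spill_chunk(buffer, kbytes, tmpdir))
                buffer = []
        if buffer:
            chunks.append(_spill_chunk(buffer, kbytes, tmpdir))
        values, taxa = _merge_chunks(chunks, kbytes)
    return values, taxa


def build_index(fasta_paths, content: ContentFile, k_max: int = 12,
                frames: int = 6, mem_budget_bytes: int = 256 * 1024 * 1024,
                level: str = "lowest",
                table: TranslationTable | None = None) -> Index:
    """Build the sorted index from reference FASTA files.

    Pairs are buffered up to the memory budget, sorted, deduplicated and
    spilled as sorted chunks, then k-way merged with cross-chunk dedup.
    The result is independent of the budget.
    """
    if frames not in (1, 3, 6):
        raise ValueError(f"frames must be 1, 3 or 6, got {frames}")
    table = table or standard_table()
    width = _width_for(k_max)
    acc2line = content.acc_to_line()
    values, taxa = _build_entries(
        _pairs_from_fastas(fasta_paths, acc2line, k_max, frames, table),
        mem_budget_bytes, width // 8)
    freqs: dict[int, int] = {}
    for t in taxa:
        freqs[t] = freqs.get(t, 0) + 1
    meta = IndexMeta(k_max=k_max, width=width, frames=frames, level=level,
                     frequencies=freqs)
    return Index(values=values, taxa=taxa, meta=meta, content=content)


def update_index(index: Index, new_fasta_paths, new_content: ContentFile,
                 mem_budget_bytes: int = 256 * 1024 * 1024,
                 table: TranslationTable | None = None) -> Index:
    """Merge new reference sequences into an existing index.

    ``new_content`` must extend the index's content file by appended lines
    only, so existing line numbers stay valid.  A losslessly shrunken index
    is static and cannot be updated.
    """
    if index.meta.shrunken_lossless:
        raise ValueError("index is static: lossless shrinking disables updating")
    old = index.content.entries
    if new_content.entries[: len(old)] != old:
        raise ValueError("content additions must append lines; existing lines changed")
    table = table or standard_table()
    if isinstance(new_fasta_paths, (str, Path)):
        new_fasta_paths = [new_fasta_paths]
    if not new_fasta_paths:
        return Index(values=list(index.values), taxa=list(index.taxa),
                     meta=IndexMeta(**{**index.meta.__dict__,
                                       "frequencies": dict(index.meta.frequencies),
                                       "content_checksum": new_content.checksum()}),
                     content=new_content)
    kbytes = index.meta.width // 8
    new_values, new_taxa = _build_entries(
        _pairs_from_fastas(new_fasta_paths, new_content.acc_to_line(),
                           index.k_max, index.meta.frames, table),
        mem_budget_bytes, kbytes)
    # merge two sorted runs with dedup
    values: list[int] = []
    taxa: list[int] = []
    prev = None
    for pair in heapq.merge(zip(index.values, index.taxa), zip(new_values, new_taxa)):
        if pair == prev:
            continue
        prev = pair
        values.append(pair[0])
        taxa.append(pair[1])
    freqs: dict[int, int] = {}
    for t in taxa:
        freqs[t] = freqs.get(t, 0) + 1
    meta = IndexMeta(k_max=index.k_max, width=index.meta.width,
                     frames=index.meta.frames, level=index.meta.level,
                     frequencies=freqs)
    return Index(values=values, taxa=taxa, meta=meta, content=new_content)


# ---- shrinking -----------------------------------------------------------


def shrink_lossless(index: Index) -> Index:
    """Halve the on-disk entry width without information loss.

    The six prefix letters move into the trie (each entry keeps only its
    30-bit suffix) and the taxon handle narrows to a 16-bit content line
    number.  Requires a 64-bit index and at most 65535 content entries;
    the result is static (no updates).
    """
    if index.meta.width != 64:
        raise ValueError("lossless shrink requires a 64-bit (k_max=12) index")
    if len(index.content) > LOSSLESS_MAX_ENTRIES:
        raise ValueError(
            f"content file has {len(index.content)} entries; lossless shrink "
            f"allows at most {LOSSLESS_MAX_ENTRIES}")
    meta = IndexMeta(k_max=index.k_max, width=index.meta.width,
                     frames=index.meta.frames, level=index.meta.level,
                     frequencies=dict(index.meta.frequencies),
                     shrunken_lossless=True)
    return Index(values=list(index.values), taxa=list(index.taxa), meta=meta,
                 content=index.content, trie=index.trie)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def shrink_lossy(index: Index, percent: float | None = None,
                 target_bytes: int | None = None, seed: int = 0) -> Index:
    """Randomly delete k-mers, a fair share per taxon.

    Each taxon with n entries loses round(percent*n/100) of them uniformly
    at random, so taxa with more k-mers lose more in absolute terms.  A
    target size is first converted to the equivalent percentage.  Taxa with
    a single entry are protected unless percent is 100.
    """
    record = 6 if index.meta.shrunken_lossless else index.meta.width // 8 + 4
    current = len(index) * record
    if percent is None:
        if target_bytes is None:
            raise ValueError("give either a percentage or a target size")
        if target_bytes >= current:
            logger.warning("target size %d >= current %d bytes; nothing deleted",
                           target_bytes, current)
            return index
        percent = (1 - target_bytes / current) * 100.0
    if not 0 <= percent <= 100:
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    if percent == 0:
        return index
    rng = np.random.default_rng(seed)
    positions_by_taxon: dict[int, list[int]] = {}
    for pos, t in enumerate(index.taxa):
        positions_by_taxon.setdefault(t, []).append(pos)
    drop: set[int] = set()
    for t in sorted(positions_by_taxon):
        positions = positions_by_taxon[t]
        n_del = _round_half_up(percent * len(positions) / 100.0)
        if len(positions) == 1 and percent < 100:
            n_del = 0
        n_del = min(n_del, len(positions))
        if n_del:
            chosen = rng.choice(len(positions), size=n_del, replace=False)
            drop.update(positions[i] for i in chosen)
    values = [v for i, v in enumerate(index.values) if i not in drop]
    taxa = [t for i, t in enumerate(index.taxa) if i not in drop]
    freqs: dict[int, int] = {}
    for t in taxa:
        freqs[t] = freqs.get(t, 0) + 1
    meta = IndexMeta(k_max=index.k_max, width=index.meta.width,
                     frames=index.meta.frames, level=index.meta.level,
                     frequencies=freqs,
                     shrunken_lossless=index.meta.shrunken_lossless,
                     lossy_seed=seed)
    return Index(values=values, taxa=taxa, meta=meta, content=index.content)
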