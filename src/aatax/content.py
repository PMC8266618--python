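"""The content file: a line-numbered registry of taxa behind an index.

The index never stores taxonomic IDs directly; each entry carries the
1-based line number of a content-file entry, so the content file binds
internal handles to (name, tax_id, accessions).  The file is a plain TSV —
``name<TAB>tax_id<TAB>acc1;acc2;...`` — deliberately human-readable and
hand-editable.  Taxonomy inputs are two small TSVs (accession → tax_id,
and tax_id → parent/rank/name), so toy taxonomies need no external dumps.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import seqio

__all__ = [
    "ContentEntry",
    "ContentFile",
    "TaxonomyMap",
    "parse_accession",
    "resolve_level",
    "build_content",
    "DUMMY_TAX_ID",
    "DUMMY_NAME",
    "LOSSLESS_MAX_ENTRIES",
]

logger = logging.getLogger(__name__)

DUMMY_TAX_ID = 0
DUMMY_NAME = "unnamed"
#: Lossless index shrinking stores content line numbers in 16 bits.
LOSSLESS_MAX_ENTRIES = 2**16 - 1

_PIPE_TAGS = ("ref", "gb", "emb")


@dataclass
class ContentEntry:
    name: str
    tax_id: int
    accessions: list[str]


@dataclass
class ContentFile:
    """Ordered taxon registry; an entry's 1-based position is its handle."""

    entries: list[ContentEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        tax_ids = [e.tax_id for e in self.entries]
        if len(set(tax_ids)) != len(tax_ids):
            raise ValueError("tax_ids must be unique across content entries")
        accs = [a for e in self.entries for a in e.accessions]
        if len(set(accs)) != len(accs):
            raise ValueError("every accession must appear in exactly one entry")

    def __len__(self) -> int:
        return len(self.entries)

    def line_of_tax(self, tax_id: int) -> int:
        """1-based line number of the entry with this tax_id."""
        for i, e in enumerate(self.entries, start=1):
            if e.tax_id == tax_id:
                return i
        raise KeyError(tax_id)

    def entry_at(self, line: int) -> ContentEntry:
        return self.entries[line - 1]

    def acc_to_line(self) -> dict[str, int]:
        return {a: i for i, e in enumerate(self.entries, start=1) for a in e.accessions}

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_text())

    def to_text(self) -> str:
        lines = [
            f"{e.name}\t{e.tax_id}\t{';'.join(e.accessions)}" for e in self.entries
        ]
        return "\n".join(lines) + "\n"

    def checksum(self) -> str:
        """Digest binding an index to this exact content file."""
        return hashlib.sha256(self.to_text().encode("utf-8")).hexdigest()

    @classmethod
    def read(cls, path) -> "ContentFile":
        entries = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                name, tax_id, accs = line.split("\t")
                entries.append(
                    ContentEntry(name=name, tax_id=int(tax_id),
                                 accessions=accs.split(";") if accs else [])
                )
        if not entries:
            raise ValueError(f"{path}: content file has no entries")
        return cls(entries=entries)


@dataclass
class TaxonomyMap:
    """Accession → tax_id plus a rank-labelled parent tree.

    ``parents`` maps tax_id → (parent tax_id, rank-of-this-node); the root
    points to itself.  Lookups are total: unknown accessions fall back to
    the dummy taxon at content-building time.
    """

    acc2tax: dict[str, int]
    names: dict[int, str]
    parents: dict[int, tuple[int, str]]

    @classmethod
    def read(cls, acc2tax_path, nodes_path) -> "TaxonomyMap":
        """Load from ``accession<TAB>tax_id`` and
        ``tax_id<TAB>parent_id<TAB>rank<TAB>name`` TSVs."""
        acc2tax: dict[str, int] = {}
        with open(acc2tax_path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                acc, tid = line.split("\t")
                acc2tax[acc] = int(tid)
        names: dict[int, str] = {}
        parents: dict[int, tuple[int, str]] = {}
        with open(nodes_path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                tid, parent, rank, name = line.split("\t")
                names[int(tid)] = name
                parents[int(tid)] = (int(parent), rank)
        return cls(acc2tax=acc2tax, names=names, parents=parents)

    def write(self, acc2tax_path, nodes_path) -> None:
        with open(acc2tax_path, "w", encoding="utf-8") as fh:
            for acc, tid in self.acc2tax.items():
                fh.write(f"{acc}\t{tid}\n")
        with open(nodes_path, "w", encoding="utf-8") as fh:
            for tid, (parent, rank) in self.parents.items():
                fh.write(f"{tid}\t{parent}\t{rank}\t{self.names.get(tid, DUMMY_NAME)}\n")

    def name_of(self, tax_id: int) -> str:
        return self.names.get(tax_id, DUMMY_NAME)


def parse_accession(fasta_header: str) -> str | None:
    """Extract an accession from a FASTA header (text after '>').

    Plain headers give the first whitespace-delimited token.  Classic
    pipe-delimited headers prefer the field following a ``ref``/``gb``/
    ``emb`` tag, else the second pipe field.
    """
    fasta_header = fasta_header.strip()
    if not fasta_header:
        return None
    token = fasta_header.split()[0]
    if "|" not in token:
        return token
    fields = token.split("|")
    for tag in _PIPE_TAGS:
        if tag in fields:
            idx = fields.index(tag)
            if idx + 1 < len(fields) and fields[idx + 1]:
                return fields[idx + 1]
    return fields[1] if len(fields) > 1 and fields[1] else None


def resolve_level(tax_id: int, level: str, taxonomy: TaxonomyMap) -> int:
    """Map a tax_id to its ancestor at ``level``.

    "lowest" (strain/sequence level) returns the input unchanged, as does a
    lineage with no ancestor of the requested rank — a reference is never
    silently dropped.
    """
    if level == "lowest":
        return tax_id
    seen = set()
    current = tax_id
    while current in taxonomy.parents and current not in seen:
        seen.add(current)
        parent, rank = taxonomy.parents[current]
        if rank == level:
            return current
        if parent == current:
            break
        current = parent
    return tax_id


def build_content(fasta_paths, taxonomy: TaxonomyMap, level: str = "lowest") -> ContentFile:
    """Group FASTA records into content entries at the requested level.

    One entry per distinct resolved tax_id, in first-appearance order;
    records whose accession is unknown to the taxonomy get the dummy taxon
    (tax_id 0, name "unnamed") with a warning.
    """
    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    order: list[int] = []
    by_tax: dict[int, ContentEntry] = {}
    n_records = 0
    for path in fasta_paths:
        try:
            records = list(seqio.read_records(path))
        except OSError as exc:
            raise OSError(f"cannot read reference file {path}: {exc}") from exc
        for rec_id, header, _seq in records:
            n_records += 1
            acc = parse_accession(header) or rec_id
            if acc in taxonomy.acc2tax:
                tax_id = resolve_level(taxonomy.acc2tax[acc], level, taxonomy)
                name = taxonomy.name_of(tax_id)
            else:
                logger.warning("accession %r not in taxonomy; assigning dummy taxon", acc)
                tax_id, name = DUMMY_TAX_ID, DUMMY_NAME
            if tax_id not in by_tax:
                entry = ContentEntry(name=name, tax_id=tax_id, accessions=[])
                by_tax[tax_id] = entry
                order.append(tax_id)
            if acc not in by_tax[tax_id].accessions:
                by_tax[tax_id].accessions.append(acc)
    if n_records == 0:
        raise ValueError("no FASTA records found in the given reference files")
    return ContentFile(entries=[by_tax[t] for t in order])
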