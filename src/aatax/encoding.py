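"""Amino-acid-like encoding of DNA and order-preserving packed k-mers.

Every nucleotide triplet — coding or not — is translated through a codon
table (the standard genetic code by default) into a letter alphabet of at
most 31 symbols, each stored in 5 bits.  A k-mer of up to ``k_max`` letters
is packed most-significant-letter-first into a single unsigned integer, so
integer order on packed values equals lexicographic order on the letter
strings.  Code 0 is a padding sentinel that sorts before every letter,
which keeps short (padded) k-mers adjacent to their full-length extensions
in a sorted index.

Translating in three forward frames is lossless except for the first and
last base of the sequence: every interior base lands in exactly one codon
of at least one frame.  Six frames add the reverse complement, which makes
the index strand-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable as _CodonTable

__all__ = [
    "TranslationTable",
    "PackedKmer",
    "AMBIGUOUS_LETTER",
    "STOP_LETTER",
    "reverse_complement",
    "translate",
    "frames_of",
    "pack",
    "unpack",
    "kmers_of",
]

#: Letter a codon containing any non-ACGT base translates to.
AMBIGUOUS_LETTER = "X"
#: Letter stop codons translate to; translation continues through stops
#: because non-coding DNA is indexed like coding DNA.
STOP_LETTER = "*"

_BITS_PER_LETTER = 5
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _standard_codon_map() -> dict[str, str]:
    table = _CodonTable.standard_dna_table
    codon_map = dict(table.forward_table)
    for stop in table.stop_codons:
        codon_map[stop] = STOP_LETTER
    return codon_map


@dataclass(frozen=True)
class TranslationTable:
    """Codon → letter map plus the 5-bit code of each letter.

    Letter codes start at 1 (0 is the padding sentinel) and are assigned in
    ascending lexicographic order of the letters, so code order equals
    letter order and packed integers sort like letter strings.
    """

    codon_map: dict[str, str]
    letter_codes: dict[str, int] = field(default=None)  # type: ignore[assignment]
    name: str = "standard"

    def __post_init__(self) -> None:
        if len(self.codon_map) != 64:
            raise ValueError(
                f"codon table must cover all 64 ACGT triplets, got {len(self.codon_map)}"
            )
        alphabet = sorted(set(self.codon_map.values()) | {AMBIGUOUS_LETTER})
        if len(alphabet) > 31:
            raise ValueError(f"alphabet of {len(alphabet)} letters exceeds 31 (5-bit limit)")
        if self.letter_codes is None:
            codes = {letter: i + 1 for i, letter in enumerate(alphabet)}
            object.__setattr__(self, "letter_codes", codes)
        self._check()

    def _check(self) -> None:
        codes = self.letter_codes
        if 0 in codes.values():
            raise ValueError("code 0 is reserved for the padding sentinel")
        if len(set(codes.values())) != len(codes):
            raise ValueError("letter codes must be distinct")
        if any(not 1 <= c <= 31 for c in codes.values()):
            raise ValueError("letter codes must lie in [1, 31]")
        in_order = sorted(codes, key=codes.__getitem__)
        if in_order != sorted(in_order):
            raise ValueError("letter codes must ascend with lexicographic letter order")

    @classmethod
    def standard(cls) -> "TranslationTable":
        return cls(codon_map=_standard_codon_map(), name="standard")

    @classmethod
    def from_tsv(cls, path) -> "TranslationTable":
        """Load a custom table from a TSV of 64 rows ``codon<TAB>letter``."""
        codon_map: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                codon, letter = line.split("\t")
                codon_map[codon.upper()] = letter
        return cls(codon_map=codon_map, name=str(path))

    @property
    def letters(self) -> str:
        return "".join(sorted(self.letter_codes))

    def decode(self, code: int) -> str:
        for letter, c in self.letter_codes.items():
            if c == code:
                return letter
        raise KeyError(code)


_STANDARD: TranslationTable | None = None


def standard_table() -> TranslationTable:
    global _STANDARD
    if _STANDARD is None:
        _STANDARD = TranslationTable.standard()
    return _STANDARD


@dataclass(frozen=True, order=True)
class PackedKmer:
    """A k-mer of up to ``k_max`` letters packed into one unsigned integer.

    Letter *i* (0-based from the start) occupies bits
    ``[5*(k_max-1-i), 5*(k_max-i))`` — first letter most significant.
    Positions ``>= valid_len`` hold the sentinel 0, so a padded k-mer sorts
    immediately before every full k-mer that extends it.  A k_max of 12
    consumes 60 bits (64-bit storage); 25 consumes 125 bits (128-bit).
    """

    value: int
    k_max: int
    valid_len: int

    def prefix(self, k: int) -> int:
        """Integer holding the first ``k`` letters (right-aligned)."""
        return self.value >> (_BITS_PER_LETTER * (self.k_max - k))


def reverse_complement(seq: str) -> str:
    """Reverse complement; A<->T, C<->G, every other IUPAC letter maps to
    itself (ambiguity is resolved at translation, not complementation)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int, table: TranslationTable | None = None) -> str:
    """Translate one reading frame into amino-acid-like letters.

    Drops the first ``frame`` bases and any trailing partial triplet.
    Codons containing a non-ACGT base become :data:`AMBIGUOUS_LETTER`.
    """
    if not 0 <= frame <= 2:
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    table = table or standard_table()
    seq = seq.upper()
    codon_map = table.codon_map
    out = []
    for i in range(frame, len(seq) - 2, 3):
        out.append(codon_map.get(seq[i : i + 3], AMBIGUOUS_LETTER))
    return "".join(out)


def frames_of(seq: str, n_frames: int, table: TranslationTable | None = None) -> list[str]:
    """Translate ``seq`` in 1, 3 or 6 reading frames.

    Order is fixed: forward frames 0,1,2, then (for 6) frames 0,1,2 of the
    reverse complement.
    """
    if n_frames not in (1, 3, 6):
        raise ValueError(f"n_frames must be 1, 3 or 6, got {n_frames}")
    frames = [translate(seq, f, table) for f in range(min(n_frames, 3))]
    if n_frames == 6:
        rc = reverse_complement(seq)
        frames += [translate(rc, f, table) for f in range(3)]
    return frames


def pack(letters: str, k_max: int, table: TranslationTable | None = None) -> PackedKmer:
    """Pack a letter string of length <= k_max, sentinel-padding the tail."""
    if len(letters) > k_max:
        raise ValueError(f"kmer overflow: {len(letters)} letters > k_max={k_max}")
    table = table or standard_table()
    value = 0
    codes = table.letter_codes
    for letter in letters:
        value = (value << _BITS_PER_LETTER) | codes[letter]
    value <<= _BITS_PER_LETTER * (k_max - len(letters))
    return PackedKmer(value=value, k_max=k_max, valid_len=len(letters))


def unpack(kmer: PackedKmer, table: TranslationTable | None = None) -> str:
    """Inverse of :func:`pack` (sentinel positions are omitted)."""
    table = table or standard_table()
    by_code = {c: letter for letter, c in table.letter_codes.items()}
    letters = []
    for i in range(kmer.valid_len):
        shift = _BITS_PER_LETTER * (kmer.k_max - 1 - i)
        letters.append(by_code[(kmer.value >> shift) & 0x1F])
    return "".join(letters)


def kmers_of(
    letters: str,
    k_max: int,
    k_lower: int,
    table: TranslationTable | None = None,
    pad_short: bool = True,
) -> list[tuple[int, PackedKmer]]:
    """All overlapping full-length k-mer windows of a letter string.

    Returns ``(start_position, PackedKmer)`` pairs.  A string shorter than
    ``k_max`` but at least ``k_lower`` long yields one sentinel-padded
    window (so short reads stay classifiable) unless ``pad_short`` is
    False, which is the index-side behaviour: the index holds only
    maximum-length k-mers.  Strings shorter than ``k_lower`` yield nothing.
    """
    table = table or standard_table()
    n = len(letters)
    if n < k_max:
        if pad_short and k_lower <= n:
            return [(0, pack(letters, k_max, table))]
        return []
    codes = table.letter_codes
    mask = (1 << (_BITS_PER_LETTER * k_max)) - 1
    out: list[tuple[int, PackedKmer]] = []
    value = 0
    for i, letter in enumerate(letters):
        value = ((value << _BITS_PER_LETTER) | codes[letter]) & mask
        if i >= k_max - 1:
            out.append((i - k_max + 1, PackedKmer(value=value, k_max=k_max, valid_len=k_max)))
    return out
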