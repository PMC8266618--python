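# Methods

## Encoding model

DNA is translated triplet-wise into an amino-acid-like alphabet through a
codon table, regardless of whether the sequence codes for protein. The
default table is the standard genetic code extended with two extra letters:
`*` for the three stop codons (translation continues through stops, since
non-coding DNA is indexed like coding DNA) and `X` for any codon containing
a non-ACGT base. `X` matches `X` like any other letter; no attempt is made
to expand IUPAC ambiguity codes into alternative codons. Custom tables are
accepted as a 64-row `codon<TAB>letter` TSV, with the constraint that the
alphabet (plus `X`) stays within 31 letters.

Each letter gets a 5-bit code in `[1, 31]`, assigned in ascending
lexicographic order of the letters; code 0 is a padding sentinel. A k-mer
of up to `k_max` letters packs most-significant-letter-first into one
unsigned integer (60 bits used for `k_max=12`, 125 for `k_max=25`), so

* integer order on packed values equals lexicographic order on strings;
* two k-mers share their first k letters iff their values agree after a
  right shift by `5·(k_max−k)` — this is what makes one sorted array serve
  every k;
* a sentinel-padded short k-mer sorts immediately before its extensions.

Properties relied on elsewhere and covered by tests: three forward frames
cover every base except the first and last; replacing a codon by a synonym
leaves the aligned frame's translation (hence all its k-mers) unchanged.

Window emission is deliberately asymmetric. The index stores only
full-length (`k_max`) windows of each translated frame. The query side also
emits one sentinel-padded window when an entire translated frame is shorter
than `k_max` (but at least `k_lower`), so short reads remain classifiable;
trailing sub-`k_max` suffixes of long frames are not emitted, keeping query
and index windows aligned. A padded k-mer participates in matching only up
to its valid length.

## Index

The index is a sorted array of `(packed k-mer, taxon)` pairs, ascending by
value then taxon. The same k-mer may appear under several taxa; exact
duplicates are collapsed. Taxa are stored as 1-based line numbers of the
*content file*, a human-readable TSV registry
(`name<TAB>tax_id<TAB>acc1;acc2;...`) built by grouping FASTA accessions
through a toy-scale taxonomy (two TSVs: accession→tax_id and
tax_id→parent/rank/name) at a chosen rank. Records with accessions unknown
to the taxonomy go to a dummy taxon (tax_id 0, "unnamed") with a warning
rather than being dropped; likewise a lineage with no ancestor at the
requested rank keeps its own id.

Construction respects a memory budget as a soft contract: pairs are
buffered (capacity = budget / 96 bytes, an estimate of the per-pair Python
footprint; floor 64 KiB), each full buffer is sorted, deduplicated and
spilled as a sorted binary chunk, and the chunks are heap-merged with
cross-chunk dedup. The final array — and the saved file — is byte-identical
for any budget. Updating merges chunks built from the new sequences only;
the content file may only gain appended lines, so existing handles stay
valid.

A depth-6 prefix trie (stored flat: sorted 30-bit prefixes with half-open
entry ranges that partition `[0, N)`) restricts every lookup to the entries
sharing the query's first six letters. This motivates the default
`k_lower = 7`: the trie then fully resolves the search space before suffix
comparison.

On disk: magic + JSON header (k_max, width, frames, level, per-taxon
frequencies, flags, content checksum) + little-endian fixed-width records,
with the trie in a JSON sidecar. The format is this package's own; it
replaces an external-memory vector with a portable contract of uniform
record width.

**Lossless shrink** requires a 64-bit index and ≤65535 content lines: each
record drops its 6 prefix letters (recoverable from the trie leaf owning
its position) and stores the 30-bit suffix plus a 16-bit content line —
6 bytes instead of 12. The index becomes static, and a checksum binds it to
its exact content file. Identification output is unchanged, which the tests
assert byte-for-byte. **Lossy shrink** deletes `round(p·n_t/100)` entries
of each taxon t uniformly at random (seeded, seed recorded in the header);
a target size is first converted to the equivalent percentage. Rounding is
half-up; a taxon with a single entry is never deleted unless p = 100 — a
guard for rare taxa that the deletion rule itself does not force.

## Matching and scores

Reads are converted exactly like references — per translated frame, all
full windows plus the padded-short-frame window — but each k-mer carries a
read ID and duplicates are kept (de-duplicate reads beforehand if
abundances matter). The identification default is 3 frames: the index is
built six-frame by default, so reverse-strand reads are covered by the
index rather than the query (tested: a reverse-complemented read attains
the same full-length match counts).

Because a match at k is a shared k-prefix, the matched-taxa set at k+1 is a
subset of that at k; recording matches independently per k is therefore
exactly equivalent to the extend-upward loop over a sorted intersection,
and is how the matcher is implemented: for each k, input prefixes are swept
in sorted order, the trie bounds the candidate slice, and binary search
within the slice yields the matching entries. The matcher is validated
against a brute-force translated-substring oracle on randomized instances.

The k-mer score of taxon t for read r sums `w_k · c / |T(x,k)|` over the
read's k-mer occurrences x and all k in range, where `w_k = k²/625`
(k² normalised to (0,1] over k = 1..25 — so `w_25 = 1`), c counts
occurrences, and `T(x,k)` is the set of taxa x matched at k. Two readings
of the `|T|` denominator are defensible (global vs per-k-mer); the
per-k-mer set is used here because it is the one consistent with the
profile's evenly-split hit counts. The same weights are kept for
`k_max=12` indices rather than renormalising to `k²/144`; weights are a
ranking device and the choice only rescales scores within a run. The
relative score divides by `1 + log₂(read length · taxon frequency)`;
output rows per read are ordered by it, ties broken by ascending tax_id
for determinism. A significance cutoff (0.4 for 100 nt reads) is available
but never applied silently.

Scores are pure sums over matches, so processing the input reads in
budget-sized slices and merging the per-slice match tables changes nothing
(asserted exactly in tests).

## Profiles

At each k: `unique_count(t)` sums occurrences of prefixes matching t alone;
`h_U = unique_count / Σ_t unique_count`. The non-unique weight splits each
prefix's occurrence count evenly over its matched taxa (5 hits over 3 taxa
add 5/3 each); `h` divides by all matched occurrences, `overall` by all
input occurrences at that k. Hence `Σ h_U = Σ h = 1` wherever anything
matched and `Σ overall ≤ 1`; a k with no matches reports zeros, never NaN.
Totals count k-mer *occurrences*, not distinct values, consistent with the
hit-count semantics of the 5/3 split. Profiles cover every k in the range,
one column group per k. The cutoff (0.01 is a sensible starting point)
drops low-frequency rows without renormalising, keeping surviving values
interpretable. The ambiguity value `(N − D)/N` (entries minus distinct
k-mer values, over entries) is this package's own formula for the index
redundancy diagnostic the profile choice relies on.

No genome-length or ploidy normalisation is applied to the frequencies.

## Synthetic data and the benchmark

The generator emulates the conditions the method is meant to face at desk
scale: several distinct reference genomes (i.i.d. uniform ACGT — disjoint
at any k of interest with overwhelming probability), reads of length 100
sampled uniformly over genomes and positions on the forward strand
(reverse-strand sampling behind a flag), and independent per-base
substitution at rates up to 20%, each substituted base drawn uniformly
from the other three. Bernoulli-per-base is the simplest seedable model
consistent with a stated "mutation percentage"; a fixed-count-per-read
scheme would differ only in variance. Everything is seeded and
reproducible.

What this does *not* emulate: real genome composition and shared homology
(random genomes have essentially no cross-taxon k-mer sharing, so the
ambiguity value is ~0 and precision is easier than on real references),
indels, quality-dependent error models, long reads, and abundance skew.
Passing benchmarks therefore demonstrate the mechanics and the
multi-k robustness effect, not field accuracy on real communities.

Evaluation is per read: the top taxon by relative score against the truth;
a wrong prediction counts as both a false positive and a false negative
(the standard per-read multiclass convention), an unclassified read as a
false negative; undefined ratios report 0. The default study conditions —
3 genomes × 50 kb, 3000 reads of length 100, six-frame index, three-frame
identification, k ∈ [7, 12], rates {0, 5, 10, 15}% — run in well under a
minute and give: perfect F1 on clean reads, F1 non-increasing in the
mutation rate, and multi-k F1 dominating fixed k = 12 at every nonzero
rate (see `scripts/acceptance.py`).

## Numerical and design choices

* Reverse complement maps A↔T/C↔G and leaves other IUPAC letters in place;
  ambiguity is resolved at translation (to `X`), not at complementation.
* Lowercase input is uppercased before any processing.
* Pipe-delimited FASTA headers prefer the token after a `ref`/`gb`/`emb`
  tag, else the second pipe field; plain headers use the first token.
* Merge tie-break: equal (k-mer, taxon) pairs collapse to one; equal k-mer
  with different taxa are all kept, taxon ascending.
* The 128-bit k-mer path uses Python's arbitrary-precision integers with
  the same code path as 64-bit; width only matters at (de)serialisation.
* A losslessly shrunken index enforces `k_lower ≥ 7` at identification
  time (the trie must fully resolve the dropped prefix).
* Reads too short to yield any k-mer (all translated frames shorter than
  `k_lower`) are logged and counted as unclassified, not errored.

## Limitations

* Pure-Python matching is comfortable at the tested scales (hundreds of
  thousands of index entries, thousands of reads) but is not engineered
  for multi-GB references.
* No paired-end awareness, no quality-score use, no lowest-common-ancestor
  reassignment of multi-matched reads.
* The taxonomy reader expects the package's own two-file TSV dialect, not
  full taxonomy database dumps.
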