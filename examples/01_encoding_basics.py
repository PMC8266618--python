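"""Amino-acid-like encoding: reading frames and order-preserving packing.

Translates a short DNA sequence in all six frames, packs a k-mer into its
5-bits-per-letter integer, and shows that integer order equals
lexicographic order on the letter strings.
"""

from aatax import frames_of, pack, reverse_complement, translate

seq = "ATGAAACGCATTAGCACCACCATT"
print(f"sequence            : {seq}")
print(f"reverse complement  : {reverse_complement(seq)}")
print(f"frame 0 translation : {translate(seq, 0)}")
for i, letters in enumerate(frames_of(seq, 6)):
    strand = "fwd" if i < 3 else "rev"
    print(f"frame {i % 3} ({strand})       : {letters}")

a = pack("MKRIST", 12)
b = pack("MKRISV", 12)
print(f"\npack('MKRIST') = {a.value:#017x}  (k_max=12, 5 bits/letter)")
print(f"pack('MKRISV') = {b.value:#017x}")
print(f"integer order matches letter order: {(a.value < b.value) == ('MKRIST' < 'MKRISV')}")
# The packed value uses at most 60 of the 64 bits; padded positions hold a
# sentinel 0 that sorts before every letter.
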