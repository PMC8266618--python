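"""Build a sorted k-mer index over synthetic genomes and inspect it.

Creates three random 20 kb genomes with a toy taxonomy, builds the content
file and a six-frame index under a small memory budget (forcing chunked
construction), then shrinks it losslessly and verifies nothing is lost.
"""

import tempfile
from pathlib import Path

from aatax import build_content, build_index, load_index, shrink_lossless, shrink_lossy
from aatax import simdata
from aatax.profile import ambiguity_value

genomes, taxonomy = simdata.sample_genomes(n_taxa=3, genome_len=20_000, seed=7)

with tempfile.TemporaryDirectory() as d:
    fasta = Path(d) / "genomes.fasta"
    simdata.write_fasta(genomes, fasta)
    content = build_content([fasta], taxonomy, level="lowest")
    idx = build_index([fasta], content, k_max=12, frames=6,
                      mem_budget_bytes=1 << 20)  # 1 MiB budget -> many chunks
    print(f"index entries        : {len(idx)}")
    print(f"taxa (content lines) : {len(content)}")
    print(f"trie leaves (6-letter prefixes): {len(idx.trie.prefixes)}")
    print(f"ambiguity value      : {ambiguity_value(idx):.4f}  "
          "(0 = no k-mer shared between taxa)")

    # lossless shrink halves every record; reloading reconstructs the k-mers
    shrunk = shrink_lossless(idx)
    path = Path(d) / "small.idx"
    shrunk.save(path)
    back = load_index(path, content)
    print(f"payload bytes full/shrunk: {len(idx.payload_bytes())} / "
          f"{len(shrunk.payload_bytes())}")
    print(f"entries identical after reload: {back.values == idx.values}")

    # lossy shrink deletes a fair share per taxon
    lossy = shrink_lossy(idx, percent=25, seed=1)
    print(f"after deleting 25% per taxon: {len(lossy)} entries")
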