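"""Shared fixtures: toy genomes, taxonomy, content file and index."""

from __future__ import annotations

import pytest

from aatax import simdata
from aatax.content import build_content
from aatax.index import build_index


def make_reference(tmp_path, n_taxa=3, genome_len=2000, seed=11, k_max=12,
                   frames=6, name="genomes.fasta"):
    """Random disjoint genomes -> (index, genomes, taxonomy, fasta, content)."""
    genomes, taxonomy = simdata.sample_genomes(n_taxa, genome_len, seed)
    fasta = tmp_path / name
    simdata.write_fasta(genomes, fasta)
    content = build_content([fasta], taxonomy, level="lowest")
    idx = build_index([fasta], content, k_max=k_max, frames=frames)
    return idx, genomes, taxonomy, fasta, content


@pytest.fixture
def toy_reference(tmp_path):
    return make_reference(tmp_path)


@pytest.fixture
def toy_index(toy_reference):
    return toy_reference[0]
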