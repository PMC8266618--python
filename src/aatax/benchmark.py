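"""End-to-end robustness benchmark on synthetic data.

Builds an index over random disjoint genomes, samples fixed-length reads,
mutates them at a given per-base substitution rate, identifies them, and
scores the top-ranked taxon of every read against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import simdata
from .content import ContentFile, build_content
from .identify import identify_reads
from .index import Index, build_index
from .simdata import evaluate, top_predictions

__all__ = ["BenchmarkResult", "build_reference", "run_identification"]


@dataclass
class BenchmarkResult:
    mutation_rate: float
    k_lower: int
    k_upper: int
    n_reads: int
    sensitivity: float
    precision: float
    f1: float


def build_reference(n_taxa: int = 3, genome_len: int = 50_000, seed: int = 0,
                    k_max: int = 12, frames: int = 6, tmpdir=None
                    ) -> tuple[Index, list[tuple[str, str]], simdata.TaxonomyMap]:
    """Random genomes → content file → six-frame index (in memory)."""
    import tempfile
    from pathlib import Path

    genomes, taxonomy = simdata.sample_genomes(n_taxa, genome_len, seed)
    with tempfile.TemporaryDirectory(dir=tmpdir) as d:
        fasta = Path(d) / "genomes.fasta"
        simdata.write_fasta(genomes, fasta)
        content = build_content([fasta], taxonomy, level="lowest")
        idx = build_index([fasta], content, k_max=k_max, frames=frames)
    return idx, genomes, taxonomy


def run_identification(index: Index, genomes, taxonomy, mutation_rate: float,
                       n_reads: int = 1000, read_len: int = 100, seed: int = 0,
                       k_lower: int = 7, k_upper: int | None = None,
                       frames: int = 3) -> BenchmarkResult:
    """Sample, mutate and identify reads; score against the truth."""
    reads, truth = simdata.sample_reads(genomes, taxonomy, n_reads,
                                        read_len=read_len, seed=seed + 1)
    reads = simdata.mutate_reads(reads, mutation_rate, seed=seed + 2)
    for row in truth:
        row.mutation_rate = mutation_rate
    scored, _table = identify_reads(index, reads, frames=frames,
                                    k_lower=k_lower, k_upper=k_upper)
    sens, prec, f1 = evaluate(top_predictions(scored), truth)
    return BenchmarkResult(mutation_rate=mutation_rate, k_lower=k_lower,
                           k_upper=k_upper or index.k_max, n_reads=n_reads,
                           sensitivity=sens, precision=prec, f1=f1)
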