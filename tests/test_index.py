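"""Index construction, trie lookups, updates, shrinking, persistence."""

import random

import pytest

from aatax import encoding
from aatax.content import ContentEntry, ContentFile, TaxonomyMap, build_content
from aatax.encoding import pack, standard_table
from aatax.index import (Index, IndexMeta, MIN_MEM_BUDGET, PrefixTrie,
                         build_index, load_index, shrink_lossless,
                         shrink_lossy, trie_lookup, update_index)
from aatax.simdata import write_fasta
from conftest import make_reference

TABLE = standard_table()


def flat_taxonomy(accs_to_tax):
    names = {1: "root"}
    parents = {1: (1, "root")}
    for tax in set(accs_to_tax.values()):
        names[tax] = f"taxon {tax}"
        parents[tax] = (1, "species")
    return TaxonomyMap(acc2tax=dict(accs_to_tax), names=names, parents=parents)


def build_toy(tmp_path, records, frames=1, k_max=12, mem=2**20, name="toy.fasta"):
    fasta = tmp_path / name
    write_fasta(records, fasta)
    taxonomy = flat_taxonomy({acc: 100 + i for i, (acc, _s) in enumerate(records)})
    content = build_content([fasta], taxonomy)
    return build_index([fasta], content, k_max=k_max, frames=frames,
                       mem_budget_bytes=mem), fasta, taxonomy, content


class TestBuild:
    def test_entry_count_matches_hand_enumeration(self, tmp_path):
        """Distinct frame-0 windows of a homopolymer-codon genome."""
        seq = "ATG" * 20  # frame 0 translates to M * 20
        idx, *_ = build_toy(tmp_path, [("A1", seq)], frames=1)
        letters = encoding.translate(seq, 0, TABLE)
        expected = {letters[i:i + 12] for i in range(len(letters) - 11)}
        assert letters == "M" * 20
        assert len(idx) == len(expected) == 1

    def test_distinct_windows_counted_once_per_taxon(self, tmp_path):
        rng = random.Random(4)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        idx, *_ = build_toy(tmp_path, [("A1", seq)], frames=3)
        expected = set()
        for frame in encoding.frames_of(seq, 3, TABLE):
            for i in range(len(frame) - 11):
                expected.add(pack(frame[i:i + 12], 12, TABLE).value)
        assert sorted(expected) == idx.values

    def test_same_sequence_two_taxa_doubles_entries(self, tmp_path):
        rng = random.Random(8)
        seq = "".join(rng.choice("ACGT") for _ in range(400))
        idx, *_ = build_toy(tmp_path, [("A1", seq), ("A2", seq)], frames=6)
        assert len(idx) == 2 * idx.distinct_kmer_count()
        # equal k-mer, taxon ascending
        for i in range(1, len(idx)):
            assert (idx.values[i - 1], idx.taxa[i - 1]) < (idx.values[i], idx.taxa[i])

    def test_chunking_invariance(self, tmp_path):
        """The on-disk payload is identical whatever the memory budget."""
        rng = random.Random(15)
        records = [(f"A{i}", "".join(rng.choice("ACGT") for _ in range(1500)))
                   for i in range(3)]
        fasta = tmp_path / "refs.fasta"
        write_fasta(records, fasta)
        taxonomy = flat_taxonomy({a: 100 + i for i, (a, _s) in enumerate(records)})
        content = build_content([fasta], taxonomy)
        small = build_index([fasta], content, mem_budget_bytes=MIN_MEM_BUDGET)
        big = build_index([fasta], content, mem_budget_bytes=10 * MIN_MEM_BUDGET)
        assert small.payload_bytes() == big.payload_bytes()
        assert small.meta.frequencies == big.meta.frequencies

    def test_budget_below_floor_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="floor"):
            build_toy(tmp_path, [("A1", "ACGT" * 100)], mem=1024)

    def test_unknown_accession_rejected(self, tmp_path):
        fasta = tmp_path / "refs.fasta"
        write_fasta([("A1", "ACGT" * 100), ("A2", "TTGA" * 100)], fasta)
        taxonomy = flat_taxonomy({"A1": 100})
        content = ContentFile(entries=[ContentEntry("taxon 100", 100, ["A1"])])
        with pytest.raises(ValueError, match="content"):
            build_index([fasta], content)

    def test_frequencies_sum_to_entry_count(self, toy_index):
        assert sum(toy_index.meta.frequencies.values()) == len(toy_index)


class TestTrie:
    def test_lookup_equals_linear_scan(self, toy_index):
        rng = random.Random(2)
        values = toy_index.values
        probes = rng.sample(range(len(values)), 25)
        for pos in probes:
            kmer = encoding.PackedKmer(value=values[pos], k_max=12, valid_len=12)
            lo, hi = trie_lookup(toy_index.trie, kmer)
            p6 = kmer.prefix(6)
            scan = [i for i, v in enumerate(values) if v >> 30 == p6]
            assert list(range(lo, hi)) == scan

    def test_absent_prefix_gives_empty_range(self, toy_index):
        # craft a prefix absent from the index
        present = set(toy_index.trie.prefixes)
        missing = next(p for p in range(2 ** 30) if p not in present)
        kmer = encoding.PackedKmer(value=missing << 30, k_max=12, valid_len=6)
        assert trie_lookup(toy_index.trie, kmer) == (0, 0)

    def test_leaf_ranges_partition_the_index(self, toy_index):
        trie = toy_index.trie
        assert trie.lowers[0] == 0
        assert trie.uppers[-1] == len(toy_index)
        for i in range(1, len(trie.prefixes)):
            assert trie.lowers[i] == trie.uppers[i - 1]
            assert trie.prefixes[i] > trie.prefixes[i - 1]

    def test_short_kmer_rejected(self, toy_index):
        kmer = pack("ACDE", 12, TABLE)
        with pytest.raises(ValueError, match="trie depth"):
            trie_lookup(toy_index.trie, kmer)


class TestUpdate:
    def test_update_equals_rebuild(self, tmp_path):
        rng = random.Random(21)
        records = [(f"A{i}", "".join(rng.choice("ACGT") for _ in range(800)))
                   for i in range(4)]
        taxonomy = flat_taxonomy({a: 100 + i for i, (a, _s) in enumerate(records)})
        fa, fb, fab = tmp_path / "a.fasta", tmp_path / "b.fasta", tmp_path / "ab.fasta"
        write_fasta(records[:2], fa)
        write_fasta(records[2:], fb)
        write_fasta(records, fab)
        content_a = build_content([fa], taxonomy)
        content_ab = build_content([fab], taxonomy)
        idx_a = build_index([fa], content_a)
        updated = update_index(idx_a, [fb], content_ab)
        rebuilt = build_index([fab], content_ab)
        assert updated.values == rebuilt.values
        assert updated.taxa == rebuilt.taxa
        assert updated.meta.frequencies == rebuilt.meta.frequencies

    def test_empty_update_is_identity(self, toy_reference):
        idx, _genomes, _tax, _fasta, content = toy_reference
        same = update_index(idx, [], content)
        assert same.values == idx.values
        assert same.taxa == idx.taxa

    def test_update_after_lossless_shrink_errors(self, toy_reference):
        idx, _genomes, _tax, fasta, content = toy_reference
        static = shrink_lossless(idx)
        with pytest.raises(ValueError, match="static"):
            update_index(static, [fasta], content)


class TestShrinkLossless:
    def test_payload_halves_and_entries_survive(self, toy_index):
        shrunk = shrink_lossless(toy_index)
        full_record = toy_index.meta.width // 8 + 4
        assert len(shrunk) == len(toy_index)
        assert len(shrunk.payload_bytes()) == len(toy_index) * 6
        assert len(toy_index.payload_bytes()) == len(toy_index) * full_record
        assert full_record == 2 * 6

    def test_roundtrip_reconstructs_kmers(self, toy_reference, tmp_path):
        idx, *_rest, content = toy_reference
        shrunk = shrink_lossless(idx)
        path = tmp_path / "shrunk.idx"
        shrunk.save(path)
        back = load_index(path, content)
        assert back.values == idx.values
        assert back.taxa == idx.taxa
        assert back.meta.shrunken_lossless

    def test_checksum_binds_content(self, toy_reference, tmp_path):
        idx, *_rest, content = toy_reference
        shrunk = shrink_lossless(idx)
        path = tmp_path / "shrunk.idx"
        shrunk.save(path)
        tampered = ContentFile(entries=[ContentEntry("other", e.tax_id, e.accessions)
                                        for e in content.entries])
        with pytest.raises(ValueError, match="checksum"):
            load_index(path, tampered)

    def test_width_128_rejected(self, tmp_path):
        idx, *_ = build_toy(tmp_path, [("A1", "ACGT" * 100)], k_max=25)
        with pytest.raises(ValueError, match="64-bit"):
            shrink_lossless(idx)

    def test_content_entry_bound(self):
        entries = [ContentEntry(f"t{i}", i + 1, [f"A{i}"]) for i in range(65536)]
        content = ContentFile(entries=entries)
        kmer = pack("ACDEFGHIKLMN", 12, TABLE)
        meta = IndexMeta(k_max=12, width=64, frames=1, level="lowest",
                         frequencies={1: 1})
        idx = Index(values=[kmer.value], taxa=[1], meta=meta, content=content)
        with pytest.raises(ValueError, match="65535"):
            shrink_lossless(idx)


class TestShrinkLossy:
    def test_half_deletion_per_taxon(self, toy_index):
        shrunk = shrink_lossy(toy_index, percent=50, seed=3)
        for taxon, n in toy_index.meta.frequencies.items():
            kept = shrunk.meta.frequencies.get(taxon, 0)
            assert kept == n - round(n / 2 + 0.0001)

    def test_bigger_taxa_lose_more(self, tmp_path):
        rng = random.Random(30)
        records = [("A1", "".join(rng.choice("ACGT") for _ in range(3000))),
                   ("A2", "".join(rng.choice("ACGT") for _ in range(600)))]
        idx, *_ = build_toy(tmp_path, records, frames=6)
        shrunk = shrink_lossy(idx, percent=30, seed=1)
        lost = {t: idx.meta.frequencies[t] - shrunk.meta.frequencies.get(t, 0)
                for t in idx.meta.frequencies}
        assert lost[1] > lost[2]

    def test_zero_percent_is_identity(self, toy_index):
        assert shrink_lossy(toy_index, percent=0) is toy_index

    def test_target_above_current_is_noop(self, toy_index, caplog):
        with caplog.at_level("WARNING"):
            same = shrink_lossy(toy_index, target_bytes=10 ** 12)
        assert same is toy_index
        assert any("nothing deleted" in rec.message for rec in caplog.records)

    def test_target_size_converts_to_percent(self, toy_index):
        record = toy_index.meta.width // 8 + 4
        target = len(toy_index) * record // 2
        shrunk = shrink_lossy(toy_index, target_bytes=target, seed=5)
        assert len(shrunk) == pytest.approx(len(toy_index) / 2, rel=0.01)

    def test_single_entry_taxon_protected(self):
        content = ContentFile(entries=[ContentEntry("a", 1, ["A"]),
                                       ContentEntry("b", 2, ["B"])])
        v1 = pack("ACDEFGHIKLMN", 12, TABLE).value
        v2 = pack("CDEFGHIKLMNP", 12, TABLE).value
        meta = IndexMeta(k_max=12, width=64, frames=1, level="lowest",
                         frequencies={1: 1, 2: 1})
        idx = Index(values=sorted([v1, v2]), taxa=[1, 2], meta=meta, content=content)
        assert len(shrink_lossy(idx, percent=90, seed=0)) == 2
        assert len(shrink_lossy(idx, percent=100, seed=0)) == 0

    def test_seed_reproducible_and_recorded(self, toy_index):
        a = shrink_lossy(toy_index, percent=25, seed=42)
        b = shrink_lossy(toy_index, percent=25, seed=42)
        assert a.values == b.values and a.taxa == b.taxa
        assert a.meta.lossy_seed == 42

    def test_sortedness_after_every_operation(self, toy_index):
        for variant in (toy_index, shrink_lossy(toy_index, percent=40, seed=2),
                        shrink_lossless(toy_index)):
            pairs = list(zip(variant.values, variant.taxa))
            assert pairs == sorted(pairs)
            assert len(pairs) == len(set(pairs))


class TestPersistence:
    def test_save_load_roundtrip(self, toy_reference, tmp_path):
        idx, *_rest, content = toy_reference
        path = tmp_path / "full.idx"
        idx.save(path)
        back = load_index(path, content)
        assert back.values == idx.values
        assert back.taxa == idx.taxa
        assert back.meta.k_max == idx.meta.k_max
        assert back.meta.frequencies == idx.meta.frequencies
        assert back.trie.leaves == idx.trie.leaves

    def test_bad_magic_rejected(self, tmp_path, toy_reference):
        *_rest, content = toy_reference
        path = tmp_path / "junk.idx"
        path.write_bytes(b"not an index")
        with pytest.raises(ValueError, match="not an index"):
            load_index(path, content)
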