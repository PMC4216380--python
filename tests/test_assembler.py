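"""De Bruijn graph construction, simplification, contigs, N50, scaffolding."""

import numpy as np
import pytest

from seedfam.assembler import (
    Assembly,
    AssemblyParams,
    Contig,
    assemble,
    assembly_stats,
    build_graph,
    canonical,
    extract_contigs,
    multi_k_assemble,
    reverse_complement,
    scaffold,
    simplify_graph,
    union_contigs,
    write_fasta,
)
from tests.conftest import random_dna, tiling_reads


class TestBuildGraph:
    def test_single_read_enumerated_kmers(self):
        g = build_graph(["ACGTAC"], 4)
        assert set(g.counts) == {canonical(k) for k in ("ACGT", "CGTA", "GTAC")}
        assert len(g) == 3

    def test_reverse_complement_read_gives_identical_graph(self, rng):
        seq = random_dna(rng, 80)
        g1 = build_graph([seq], 21)
        g2 = build_graph([reverse_complement(seq)], 21)
        assert g1.counts == g2.counts

    def test_duplicate_reads_scale_coverage(self, rng):
        seq = random_dna(rng, 60)
        g1 = build_graph([seq], 21)
        g10 = build_graph([seq] * 10, 21)
        assert set(g1.counts) == set(g10.counts)
        assert all(g10.counts[k] == 10 * g1.counts[k] for k in g1.counts)

    def test_k_longer_than_reads_errors(self):
        with pytest.raises(ValueError):
            build_graph(["ACGT"], 11)

    def test_n_containing_kmers_skipped(self):
        g = build_graph(["ACGTNACGT"], 4)
        assert all("N" not in k for k in g.counts)


class TestSimplify:
    def test_linear_chain_is_fixpoint(self, rng):
        seq = random_dna(rng, 200)
        g = build_graph(tiling_reads(seq, 50, 10), 21)
        before = dict(g.counts)
        simplify_graph(g, bubble_size=50)
        assert g.counts == before

    def test_low_coverage_spur_removed(self, rng):
        seq = random_dna(rng, 200)
        k = 21
        reads = tiling_reads(seq, 50, 5) * 50
        # spur: one extra path hanging off position 100 with a different base
        spur = seq[80:100] + ("A" if seq[100] != "A" else "C")
        g = build_graph(reads + [spur], k)
        n_spur = canonical(spur[-k:])
        assert n_spur in g.counts
        simplify_graph(g, bubble_size=50)
        assert n_spur not in g.counts

    def test_snp_bubble_absorbed_keeping_high_coverage_path(self, rng):
        seq = random_dna(rng, 200)
        alt_base = "A" if seq[100] != "A" else "C"
        variant = seq[:100] + alt_base + seq[101:]
        k = 21
        reads = tiling_reads(seq, 50, 5) * 50 + tiling_reads(variant, 50, 5) * 2
        g = build_graph(reads, k)
        simplify_graph(g, bubble_size=50)
        contigs = extract_contigs(g, 100)
        assert len(contigs) == 1
        assert contigs[0].sequence in (seq, reverse_complement(seq))


class TestContigs:
    def test_single_transcript_reconstructed(self, rng):
        tx = random_dna(rng, 500)
        asm = assemble(tiling_reads(tx, 101, 20), AssemblyParams(word_size=60, min_contig_length=300))
        assert len(asm.contigs) == 1
        assert asm.contigs[0].sequence in (tx, reverse_complement(tx))

    def test_min_length_filter(self, rng):
        tx = random_dna(rng, 500)
        g = build_graph(tiling_reads(tx, 101, 20), 60)
        assert extract_contigs(g, 600) == []

    def test_two_disjoint_transcripts_separate(self, rng):
        t1, t2 = random_dna(rng, 400), random_dna(rng, 400)
        reads = tiling_reads(t1, 101, 15) + tiling_reads(t2, 101, 15)
        asm = assemble(reads, AssemblyParams(word_size=31, min_contig_length=300))
        got = {c.sequence for c in asm.contigs}
        want = {min(t, reverse_complement(t)) for t in (t1, t2)}
        assert {min(s, reverse_complement(s)) for s in got} == want

    def test_shared_block_at_least_k_creates_branch(self, rng):
        shared = random_dna(rng, 80)
        p1 = random_dna(rng, 150) + shared + random_dna(rng, 150)
        p2 = random_dna(rng, 150) + shared + random_dna(rng, 150)
        reads = tiling_reads(p1, 101, 10) + tiling_reads(p2, 101, 10)
        g = build_graph(reads, 60)
        assert any(
            len(g.successors(k)) > 1 or len(g.predecessors(k)) > 1 for k in g.counts
        )

    def test_deterministic_output(self, rng, tmp_path):
        tx = [random_dna(rng, 400) for _ in range(3)]
        reads = [r for t in tx for r in tiling_reads(t, 101, 10)]
        f1, f2 = tmp_path / "a.fa", tmp_path / "b.fa"
        for f in (f1, f2):
            asm = assemble(list(reads), AssemblyParams(word_size=31, min_contig_length=300))
            write_fasta(asm.contigs, f)
        assert f1.read_bytes() == f2.read_bytes()


def _brute_n50(lengths):
    total = sum(lengths)
    candidates = [L for L in lengths if sum(x for x in lengths if x >= L) * 2 >= total]
    return max(candidates)


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected", [([500, 300, 200], 500), ([400, 400, 200], 400), ([700], 700)]
    )
    def test_examples(self, lengths, expected):
        contigs = [Contig(f"c{i}", "A" * L, 1.0) for i, L in enumerate(lengths)]
        assert assembly_stats(contigs).n50 == expected

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 11))
            lengths = [int(rng.integers(1, 1000)) for _ in range(n)]
            contigs = [Contig(f"c{i}", "A" * L, 1.0) for i, L in enumerate(lengths)]
            assert assembly_stats(contigs).n50 == _brute_n50(lengths)

    def test_empty_assembly(self):
        stats = assembly_stats([])
        assert (stats.n50, stats.contig_count, stats.total_bases) == (0, 0, 0)


class TestScaffold:
    def _gapped_transcript(self, rng):
        tx = random_dna(rng, 800)
        reads = [tx[i : i + 101] for i in range(0, 250, 10)]
        reads += [tx[i : i + 101] for i in range(450, 699, 10)]
        return tx, reads

    def _pairs(self, tx, starts, insert=350):
        out = []
        for s in starts:
            frag = tx[s : s + insert]
            out.append((frag[:101], reverse_complement(frag[-101:])))
        return out

    def test_spanning_pairs_join_with_n_gap(self, rng):
        tx, reads = self._gapped_transcript(rng)
        asm = assemble(reads, AssemblyParams(word_size=31, min_contig_length=100))
        assert len(asm.contigs) == 2
        pairs = (
            self._pairs(tx, range(0, 101, 25))
            + self._pairs(tx, range(450, 551, 25))
            + self._pairs(tx, range(210, 251, 10))
        )
        joined = scaffold(asm.contigs, pairs)
        assert len(joined) == 1
        assert "N" in joined[0].sequence

    def test_no_pairs_is_identity(self, rng):
        tx, reads = self._gapped_transcript(rng)
        asm = assemble(reads, AssemblyParams(word_size=31, min_contig_length=100))
        assert scaffold(asm.contigs, []) == list(asm.contigs)

    def test_links_below_threshold_do_not_join(self, rng):
        tx, reads = self._gapped_transcript(rng)
        asm = assemble(reads, AssemblyParams(word_size=31, min_contig_length=100))
        pairs = (
            self._pairs(tx, range(0, 101, 25))
            + self._pairs(tx, range(450, 551, 25))
            + self._pairs(tx, [210])  # a single spanning pair < min_link_pairs
        )
        joined = scaffold(asm.contigs, pairs, min_link_pairs=3)
        assert len(joined) == 2
        assert not any("N" in c.sequence for c in joined)


class TestMultiK:
    def test_single_k_equals_plain_assembly(self, rng):
        tx = random_dna(rng, 500)
        reads = tiling_reads(tx, 101, 20)
        params = AssemblyParams(word_size=60, min_contig_length=300)
        single = assemble(reads, params)
        swept = multi_k_assemble(reads, [60], params)
        assert list(swept) == [60]
        assert [c.sequence for c in swept[60].contigs] == [
            c.sequence for c in single.contigs
        ]

    def test_duplicate_k_deduplicated(self, rng):
        tx = random_dna(rng, 500)
        reads = tiling_reads(tx, 101, 20)
        swept = multi_k_assemble(reads, [60, 60, 60], AssemblyParams(min_contig_length=300))
        assert list(swept) == [60]

    def test_union_deduplicates_identical_contigs(self, rng):
        tx = random_dna(rng, 500)
        reads = tiling_reads(tx, 101, 20)
        swept = multi_k_assemble(reads, [31, 60], AssemblyParams(min_contig_length=300))
        union = union_contigs(swept)
        assert len(union) == 1


def test_params_validation():
    with pytest.raises(ValueError):
        AssemblyParams(word_size=10)
    with pytest.raises(ValueError):
        AssemblyParams(word_size=23, min_contig_length=20)
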