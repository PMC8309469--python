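"""Promoter extraction, fragmentation and GC-content behaviour."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boxscan import (
    GeneModel,
    GenomeSequence,
    extract_promoter,
    filter_fragments_by_gc,
    fragment_genome,
    gc_content,
    read_annotation,
    read_genome,
)
from boxscan.sequence_io import reverse_complement

from conftest import random_sequence

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestReadGenome:
    def test_two_records_lengths_preserved(self, tmp_path):
        fa = tmp_path / "g.fasta"
        fa.write_text(">a\nACGTACGTAC\n>b\n" + "A" * 20 + "\n")
        recs = read_genome(fa)
        assert [r.contig_id for r in recs] == ["a", "b"]
        assert [r.length for r in recs] == [10, 20]

    def test_lowercase_uppercased(self, tmp_path):
        fa = tmp_path / "g.fasta"
        fa.write_text(">a\nacgtn\n")
        assert read_genome(fa)[0].sequence == "ACGTN"

    def test_empty_file_warns(self, tmp_path, caplog):
        fa = tmp_path / "g.fasta"
        fa.write_text("")
        with caplog.at_level("WARNING"):
            assert read_genome(fa) == []
        assert any("no FASTA records" in m for m in caplog.messages)

    def test_invalid_alphabet_rejected(self, tmp_path):
        fa = tmp_path / "g.fasta"
        fa.write_text(">a\nACGU\n")
        with pytest.raises(ValueError, match="a"):
            read_genome(fa)


GFF_PLUS = """##gff-version 3
chr1\tsrc\tgene\t51\t400\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t51\t400\t.\t+\t.\tID=g1.1;Parent=g1
chr1\tsrc\texon\t51\t400\t.\t+\t.\tID=g1.1.e1;Parent=g1.1
chr1\tsrc\tCDS\t101\t400\t.\t+\t0\tID=g1.1.c1;Parent=g1.1
"""

GFF_MINUS = """##gff-version 3
chr1\tsrc\tgene\t101\t400\t.\t-\t.\tID=g2
chr1\tsrc\tmRNA\t101\t400\t.\t-\t.\tID=g2.1;Parent=g2
chr1\tsrc\tCDS\t101\t400\t.\t-\t0\tID=g2.1.c1;Parent=g2.1
"""

GFF_TWO_TRANSCRIPTS = """##gff-version 3
chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=g3
chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=g3.1;Parent=g3
chr1\tsrc\tCDS\t101\t400\t.\t+\t0\tID=g3.1.c1;Parent=g3.1
chr1\tsrc\tmRNA\t151\t400\t.\t+\t.\tID=g3.2;Parent=g3
chr1\tsrc\tCDS\t151\t400\t.\t+\t0\tID=g3.2.c1;Parent=g3.2
"""

GFF_NO_CDS = """##gff-version 3
chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=g4
chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=g4.1;Parent=g4
"""


class TestReadAnnotation:
    def test_plus_strand_cds_start(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_PLUS)
        (gene,) = read_annotation(p)
        assert gene.cds_start == 101 and gene.strand == "+"

    def test_minus_strand_cds_start_is_right_end(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_MINUS)
        (gene,) = read_annotation(p)
        assert gene.cds_start == 400 and gene.strand == "-"

    def test_first_transcript_retained(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_TWO_TRANSCRIPTS)
        (gene,) = read_annotation(p)
        assert gene.cds_start == 101

    def test_gene_without_cds_skipped(self, tmp_path, caplog):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_NO_CDS)
        with caplog.at_level("WARNING"):
            assert read_annotation(p) == []


class TestExtractPromoter:
    def test_plus_strand_interval(self, rng):
        seq = random_sequence(rng, 6000)
        genome = GenomeSequence("chr1", seq)
        gene = GeneModel("g", "chr1", "+", cds_start=3001)
        p = extract_promoter(genome, gene, 2000)
        assert (p.start, p.end) == (1000, 3000)
        assert p.sequence == seq[1000:3000]
        assert p.actual_length == 2000 and not p.truncated

    def test_minus_strand_revcomp(self, rng):
        seq = random_sequence(rng, 6000)
        genome = GenomeSequence("chr1", seq)
        gene = GeneModel("g", "chr1", "-", cds_start=3000)
        p = extract_promoter(genome, gene, 2000)
        # bases 3001..5000 (1-based) reverse complemented
        assert p.sequence == reverse_complement(seq[3000:5000])
        assert (p.start, p.end) == (3000, 5000)

    def test_truncated_at_contig_start(self, rng):
        genome = GenomeSequence("chr1", random_sequence(rng, 3000))
        gene = GeneModel("g", "chr1", "+", cds_start=501)
        p = extract_promoter(genome, gene, 2000)
        assert p.actual_length == 500 and p.truncated
        assert p.sequence == genome.sequence[:500]

    def test_zero_upstream_gives_empty_truncated(self, rng):
        genome = GenomeSequence("chr1", random_sequence(rng, 100))
        gene = GeneModel("g", "chr1", "+", cds_start=1)
        p = extract_promoter(genome, gene, 2000)
        assert p.actual_length == 0 and p.truncated

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_round_trip_planted_upstream(self, rng, strand):
        """Planted upstream sequence is recovered exactly on both strands."""
        up = random_sequence(rng, 150)
        pad = random_sequence(rng, 50)
        if strand == "+":
            seq = pad + up + "ATG" + random_sequence(rng, 30)
            gene = GeneModel("g", "chr1", "+", cds_start=len(pad) + len(up) + 1)
            expected = up
        else:
            seq = random_sequence(rng, 30) + "CAT" + reverse_complement(up) + pad
            gene = GeneModel("g", "chr1", "-", cds_start=33)
            expected = up
        p = extract_promoter(GenomeSequence("chr1", seq), gene, 150)
        assert p.sequence == expected

    def test_wrong_contig_raises(self, rng):
        genome = GenomeSequence("chr1", random_sequence(rng, 100))
        gene = GeneModel("g", "chr2", "+", cds_start=50)
        with pytest.raises(ValueError):
            extract_promoter(genome, gene)


class TestFragmentGenome:
    @pytest.mark.parametrize("length,expected", [(6000, 3), (5000, 2), (1999, 0)])
    def test_fragment_counts(self, rng, length, expected):
        genome = GenomeSequence("chr1", random_sequence(rng, length))
        frags = fragment_genome(genome, 2000)
        assert len(frags) == expected
        assert all(f.end - f.start == 2000 for f in frags)

    @given(length=st.integers(1, 500), window=st.integers(1, 100))
    @settings(max_examples=50, deadline=None)
    def test_coverage_property(self, length, window):
        genome = GenomeSequence("c", "A" * length)
        frags = fragment_genome(genome, window)
        assert sum(f.end - f.start for f in frags) == window * (length // window)
        # adjacency from offset 0
        for i, f in enumerate(frags):
            assert f.start == i * window


class TestGC:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 0.5), ("GGCC", 1.0), ("AATT", 0.0), ("GCNN", 1.0)]
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_undefined(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")

    @given(dna)
    @settings(max_examples=100, deadline=None)
    def test_revcomp_invariant(self, seq):
        assert gc_content(seq) == pytest.approx(gc_content(reverse_complement(seq)))


class TestGCFilter:
    def test_range_boundaries_inclusive(self):
        from boxscan.sequence_io import GenomeFragment

        frags = [
            GenomeFragment("c", i * 10, (i + 1) * 10, gc)
            for i, gc in enumerate((0.263, 0.264, 0.284, 0.304, 0.305))
        ]
        kept = filter_fragments_by_gc(frags, 0.284, 0.02)
        assert sorted(f.gc for f in kept) == [0.264, 0.284, 0.304]

    def test_idempotent(self, rng):
        genome = GenomeSequence("chr1", random_sequence(rng, 50000, gc=0.36))
        frags = fragment_genome(genome, 500)
        once = filter_fragments_by_gc(frags, 0.36, 0.01)
        assert filter_fragments_by_gc(once, 0.36, 0.01) == once

    def test_zero_tolerance_exact_match_only(self):
        from boxscan.sequence_io import GenomeFragment

        frags = [GenomeFragment("c", 0, 10, 0.3), GenomeFragment("c", 10, 20, 0.31)]
        assert filter_fragments_by_gc(frags, 0.3, 0.0) == frags[:1]
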