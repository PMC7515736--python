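"""Interval algebra and format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqdap.genome_io import (
    CalledPeak,
    CoverageTrack,
    FormatError,
    GeneModel,
    GenomicInterval,
    overlap_fraction,
    read_bedgraph,
    read_fasta,
    read_gene_table,
    read_gff3_genes,
    read_narrowpeak,
    reciprocal_match,
    write_bedgraph,
    write_fasta,
    write_gene_table,
    write_narrowpeak,
)


class TestNarrowPeak:
    def test_field_mapping(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr1\t100\t501\tp1\t50\t.\t4.2\t6.0\t5.1\t200\n")
        (peak,) = read_narrowpeak(path)
        assert peak.interval == GenomicInterval("chr1", 100, 501)
        assert peak.summit_offset == 200
        assert peak.neg_log10_p == 6.0
        assert peak.summit == 300

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.narrowPeak"
        path.write_text("")
        assert read_narrowpeak(path) == []

    def test_round_trip(self, tmp_path):
        peaks = [
            CalledPeak(GenomicInterval("chr1", 0, 401), 200, 50.0, 6.0, "p1", 4.2, 5.1),
            CalledPeak(GenomicInterval("chr2", 10, 30), 5, 1.0, 0.5, "p2", 0.0, -1.0),
        ]
        path = tmp_path / "rt.narrowPeak"
        write_narrowpeak(peaks, path)
        again = read_narrowpeak(path)
        assert again == peaks
        # byte stability on a second write
        text1 = path.read_text()
        write_narrowpeak(again, path)
        assert path.read_text() == text1

    def test_malformed_column_count_names_line(self, tmp_path):
        path = tmp_path / "bad.narrowPeak"
        path.write_text("chr1\t1\t2\tok\t0\t.\t0\t0\t0\t0\nchr1\t5\t9\tshort\n")
        with pytest.raises(FormatError, match=":2"):
            read_narrowpeak(path)

    def test_start_ge_end_rejected(self, tmp_path):
        path = tmp_path / "bad2.narrowPeak"
        path.write_text("chr1\t10\t10\tp\t0\t.\t0\t0\t0\t0\n")
        with pytest.raises(FormatError):
            read_narrowpeak(path)

    def test_unset_summit_maps_to_midpoint_with_warning(self, tmp_path):
        path = tmp_path / "s.narrowPeak"
        path.write_text("chr1\t100\t200\tp\t0\t.\t0\t1\t0\t-1\n")
        with pytest.warns(UserWarning, match="midpoint"):
            (peak,) = read_narrowpeak(path)
        assert peak.summit_offset == 50


class TestFasta:
    def test_case_fold_and_n(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">c1\nacgT\n>c2\nACGN\n")
        genome = read_fasta(path)
        assert genome == {"c1": "ACGT", "c2": "ACGN"}

    def test_duplicate_header_rejected(self, tmp_path):
        path = tmp_path / "dup.fa"
        path.write_text(">c1\nACGT\n>c1\nTTTT\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(path)

    def test_empty_sequence_rejected(self, tmp_path):
        path = tmp_path / "e.fa"
        path.write_text(">c1\n>c2\nACGT\n")
        with pytest.raises(FormatError):
            read_fasta(path)

    def test_round_trip(self, tmp_path):
        genome = {"chr1": "ACGT" * 50, "chr2": "GGNNCC"}
        path = tmp_path / "rt.fa"
        write_fasta(genome, path)
        assert read_fasta(path) == genome


class TestOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 100), (50, 150), (0.5, 0.5)),
            ((0, 100), (10, 110), (0.9, 0.9)),
            ((0, 100), (200, 300), (0.0, 0.0)),
        ],
    )
    def test_examples(self, a, b, expected):
        ia = GenomicInterval("c", *a)
        ib = GenomicInterval("c", *b)
        assert overlap_fraction(ia, ib) == pytest.approx(expected)

    def test_different_chrom_is_zero_not_error(self):
        a = GenomicInterval("c1", 0, 10)
        b = GenomicInterval("c2", 0, 10)
        assert overlap_fraction(a, b) == (0.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        s1=st.integers(0, 500), l1=st.integers(1, 100),
        s2=st.integers(0, 500), l2=st.integers(1, 100),
    )
    def test_symmetry_under_swap(self, s1, l1, s2, l2):
        a = GenomicInterval("c", s1, s1 + l1)
        b = GenomicInterval("c", s2, s2 + l2)
        fa, fb = overlap_fraction(a, b)
        fb2, fa2 = overlap_fraction(b, a)
        assert fa == fa2 and fb == fb2


class TestReciprocalMatch:
    def test_either_semantics(self):
        a = [GenomicInterval("c", 0, 100)]
        b = [GenomicInterval("c", 10, 110)]
        assert reciprocal_match(a, b, 0.8, "either") == [(0, 0)]

    def test_either_matches_via_smaller_interval(self):
        a = [GenomicInterval("c", 0, 1000)]
        b = [GenomicInterval("c", 0, 100)]
        assert reciprocal_match(a, b, 0.8, "either") == [(0, 0)]
        assert reciprocal_match(a, b, 0.8, "both") == []

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            reciprocal_match([], [], 0.0)
        with pytest.raises(ValueError):
            reciprocal_match([], [], 1.5)

    def test_swap_equivalence(self):
        rng = np.random.default_rng(0)
        a = [GenomicInterval("c", int(s), int(s) + int(l))
             for s, l in zip(rng.integers(0, 2000, 30), rng.integers(50, 400, 30))]
        b = [GenomicInterval("c", int(s), int(s) + int(l))
             for s, l in zip(rng.integers(0, 2000, 30), rng.integers(50, 400, 30))]
        fwd = set(reciprocal_match(a, b, 0.5, "either"))
        rev = {(i, j) for j, i in reciprocal_match(b, a, 0.5, "either")}
        assert fwd == rev


class TestTracksAndGenes:
    def test_bedgraph_round_trip(self, tmp_path):
        cov = np.zeros(100)
        cov[10:20] = 3.0
        cov[50:51] = 1.5
        track = CoverageTrack({"c1": cov}, library_size=1e6)
        path = tmp_path / "t.bedGraph"
        write_bedgraph(track, path)
        again = read_bedgraph(path, {"c1": 100}, 1e6)
        np.testing.assert_array_equal(again.coverage["c1"], cov)

    def test_window_mean_rpm_is_rpm_per_bp(self):
        track = CoverageTrack({"c1": np.full(1000, 10.0)}, library_size=1e6)
        assert track.window_mean_rpm(GenomicInterval("c1", 100, 501)) == pytest.approx(10.0)

    def test_gene_table_round_trip(self, tmp_path):
        genes = [
            GeneModel("g1", "c1", "+", 100, 900, ((100, 300), (700, 900))),
            GeneModel("g2", "c1", "-", 2000, 1200),
        ]
        path = tmp_path / "genes.tsv"
        write_gene_table(genes, path)
        assert read_gene_table(path) == genes

    def test_gene_model_strand_invariants(self):
        with pytest.raises(ValueError):
            GeneModel("bad", "c", "+", 900, 100)
        with pytest.raises(ValueError):
            GeneModel("bad", "c", "-", 100, 900)

    def test_gff3_one_based_conversion(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "c1\tsrc\tgene\t101\t900\t.\t+\t.\tID=g1\n"
            "c1\tsrc\texon\t101\t300\t.\t+\t.\tParent=g1\n"
            "c1\tsrc\tgene\t1201\t2000\t.\t-\t.\tID=g2\n"
        )
        genes = {g.gene_id: g for g in read_gff3_genes(path)}
        assert genes["g1"].tss == 100 and genes["g1"].tts == 900
        assert genes["g1"].exons == ((100, 300),)
        assert genes["g2"].tss == 2000 and genes["g2"].tts == 1200
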