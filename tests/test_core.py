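"""Interval arithmetic, domain-type invariants, and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peaksyn.core import (
    GeneModel,
    Genome,
    GenomicInterval,
    Peak,
    RepeatFeature,
    merge_within,
    overlap_length,
    overlaps,
)
from peaksyn.io import read_gff3_genes, read_peaks, write_bed, write_narrowpeak

from conftest import brute_force_merge, random_intervals


class TestTypes:
    def test_genome_rejects_duplicate_chroms(self):
        with pytest.raises(ValueError):
            Genome("g", (("chr1", 100), ("chr1", 200)))

    def test_genome_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            Genome("g", (("chr1", 0),))

    def test_interval_rejects_inverted_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)

    def test_peak_summit_must_lie_inside(self):
        iv = GenomicInterval("chr1", 100, 300)
        assert Peak(iv, "p", 199).summit_pos == 299
        with pytest.raises(ValueError):
            Peak(iv, "p", 200)

    def test_gene_model_tss_is_strand_aware(self):
        iv = GenomicInterval("chr1", 1000, 2000)
        assert GeneModel("g+", iv, "+").tss == 1000
        assert GeneModel("g-", iv, "-").tss == 1999

    def test_gene_model_rejects_overlapping_exons(self):
        iv = GenomicInterval("chr1", 0, 1000)
        with pytest.raises(ValueError):
            GeneModel("g", iv, "+", (GenomicInterval("chr1", 0, 500),
                                     GenomicInterval("chr1", 400, 600)))

    def test_repeat_needs_family(self):
        with pytest.raises(ValueError):
            RepeatFeature(GenomicInterval("chr1", 0, 10), "")


class TestOverlap:
    def test_one_shared_base(self):
        assert overlaps(GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 199, 250))

    def test_half_open_abutment_is_disjoint(self):
        assert not overlaps(GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 200, 250))

    def test_different_chromosomes_never_overlap(self):
        assert not overlaps(GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 0, 100))

    def test_agrees_with_brute_force_on_random_pairs(self, rng):
        ivs = random_intervals(rng, 50)
        for a in ivs:
            for b in ivs:
                expected = (
                    a.chrom == b.chrom
                    and max(a.start, b.start) < min(a.end, b.end)
                )
                assert overlaps(a, b) == expected
                assert (overlap_length(a, b) > 0) == expected


class TestMergeWithin:
    def test_gap_below_threshold_merges(self):
        out = merge_within(
            [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 250, 400)], 100
        )
        assert out == [GenomicInterval("chr1", 100, 400)]

    def test_gap_above_threshold_survives(self):
        ivs = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 350, 400)]
        assert merge_within(ivs, 100) == ivs

    def test_gap_exactly_threshold_survives(self):
        ivs = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 300, 400)]
        assert merge_within(ivs, 100) == ivs

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(200):
            ivs = random_intervals(rng, int(rng.integers(1, 12)), max_pos=300, max_len=40)
            max_gap = int(rng.integers(0, 60))
            got = [(m.chrom, m.start, m.end) for m in merge_within(ivs, max_gap)]
            assert got == brute_force_merge(ivs, max_gap)

    def test_idempotent_and_coverage_preserving(self, rng):
        for _ in range(100):
            ivs = random_intervals(rng, 10, max_pos=500)
            merged = merge_within(ivs, 50)
            assert merge_within(merged, 50) == merged
            covered_in = set()
            for iv in ivs:
                covered_in.update((iv.chrom, p) for p in range(iv.start, iv.end))
            covered_out = set()
            for iv in merged:
                covered_out.update((iv.chrom, p) for p in range(iv.start, iv.end))
            assert covered_in <= covered_out

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 50)), min_size=1, max_size=10
        ),
        st.integers(0, 100),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_sorted_nonoverlapping(self, pairs, max_gap):
        ivs = [GenomicInterval("chr1", s, s + l) for s, l in pairs]
        merged = merge_within(ivs, max_gap)
        for a, b in zip(merged, merged[1:]):
            assert a.end <= b.start


class TestPeakIO:
    def test_narrowpeak_fields_map_directly(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr1\t100\t300\tp1\t0\t.\t5\t3\t2\t50\n")
        (peak,) = read_peaks(f)
        assert (peak.chrom, peak.start, peak.end) == ("chr1", 100, 300)
        assert peak.peak_id == "p1"
        assert peak.summit == 50

    def test_bed6_summit_defaults_to_midpoint(self, tmp_path):
        f = tmp_path / "a.bed"
        f.write_text("chr1\t100\t300\tp1\t0\t.\n")
        (peak,) = read_peaks(f, format="BED6")
        assert peak.summit == 100

    def test_empty_file_gives_empty_list(self, tmp_path):
        f = tmp_path / "empty.narrowPeak"
        f.write_text("")
        assert read_peaks(f) == []

    def test_malformed_line_error_names_line_number(self, tmp_path):
        f = tmp_path / "bad.narrowPeak"
        f.write_text("chr1\t0\t100\tp1\t0\t.\t1\t1\t1\t50\nchr1\t100\n")
        with pytest.raises(ValueError, match="line 2"):
            read_peaks(f)

    def test_summit_beyond_length_is_rejected(self, tmp_path):
        f = tmp_path / "bad.narrowPeak"
        f.write_text("chr1\t100\t200\tp1\t0\t.\t1\t1\t1\t100\n")
        with pytest.raises(ValueError, match="summit"):
            read_peaks(f)

    def test_missing_names_get_stable_unique_ids(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text(
            "chr1\t100\t300\t.\t0\t.\t1\t1\t1\t50\n"
            "chr1\t400\t500\t.\t0\t.\t1\t1\t1\t10\n"
        )
        peaks = read_peaks(f)
        assert [p.peak_id for p in peaks] == ["chr1:100-300", "chr1:400-500"]

    def test_round_trip_preserves_coordinates(self, tmp_path, rng):
        peaks = []
        for i, iv in enumerate(random_intervals(rng, 100, max_pos=10_000, max_len=500)):
            peaks.append(Peak(iv, f"p{i}", int(rng.integers(0, len(iv))), float(i)))
        f = tmp_path / "rt.narrowPeak"
        write_narrowpeak(peaks, f)
        back = read_peaks(f)
        key = lambda p: (p.chrom, p.start, p.end, p.peak_id)
        for a, b in zip(sorted(peaks, key=key), sorted(back, key=key)):
            assert (a.chrom, a.start, a.end, a.peak_id, a.summit) == (
                b.chrom, b.start, b.end, b.peak_id, b.summit
            )

    def test_writer_sorts_unsorted_input(self, tmp_path):
        peaks = [
            Peak(GenomicInterval("chr2", 0, 10), "b", 0),
            Peak(GenomicInterval("chr1", 50, 60), "a2", 0),
            Peak(GenomicInterval("chr1", 0, 10), "a1", 0),
        ]
        f = tmp_path / "s.bed"
        write_bed(peaks, f)
        rows = [l.split("\t")[:2] for l in f.read_text().splitlines()]
        assert rows == [["chr1", "0"], ["chr1", "50"], ["chr2", "0"]]


class TestGFF3:
    def test_coordinates_converted_to_zero_based(self, tmp_path):
        f = tmp_path / "a.gff3"
        f.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tParent=t1\n"
            "chr1\tsrc\texon\t1801\t2000\t.\t+\t.\tParent=t1\n"
        )
        (gene,) = read_gff3_genes(f)
        assert (gene.interval.start, gene.interval.end) == (1000, 2000)
        assert gene.tss == 1000
        assert [(e.start, e.end) for e in gene.exons] == [(1000, 1200), (1800, 2000)]

    def test_minus_strand_tss_is_last_base(self, tmp_path):
        f = tmp_path / "a.gff3"
        f.write_text("chr1\tsrc\tgene\t501\t900\t.\t-\t.\tID=g1\n")
        (gene,) = read_gff3_genes(f)
        assert gene.tss == 899
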