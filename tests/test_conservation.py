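"""Liftover cleaning, conservation calls, aggregation, and the class test."""

import numpy as np
import pytest

from peaksyn.conservation import (
    CONSERVED_PEAK,
    CONSERVED_REGION,
    HIGH,
    NOT_CONSERVED,
    PARTIAL,
    AlignmentBlock,
    LiftoverFragmentSet,
    SpeciesConservationCall,
    aggregate_conservation,
    block_liftover,
    call_species_conservation,
    clean_fragments,
    conservation_contingency_test,
    conservation_fractions,
    summit_window,
)
from peaksyn.classify import ENHANCER, PROMOTER, UNCHARACTERIZED
from peaksyn.conservation import ConservationRecord
from peaksyn.core import GenomicInterval, Peak


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def peak(start, end, summit_abs, pid="p1", chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), pid, summit_abs - start)


class TestSummitWindow:
    def test_51_bp_centered_window(self):
        w = summit_window(peak(900, 1200, 1000))
        assert (w.start, w.end) == (975, 1026)
        assert len(w) == 51

    def test_left_clipped_at_chromosome_start(self):
        w = summit_window(peak(0, 100, 10))
        assert (w.start, w.end) == (0, 36)
        assert len(w) == 36

    def test_right_clipped_at_chromosome_end(self):
        w = summit_window(peak(900, 1000, 995), chrom_length=1000)
        assert w.end == 1000

    def test_width_never_exceeds_51(self, rng):
        for _ in range(100):
            start = int(rng.integers(0, 500))
            length = int(rng.integers(1, 200))
            s = int(rng.integers(0, length))
            w = summit_window(peak(start, start + length, start + s))
            assert len(w) <= 51


class TestCleanFragments:
    def _rgn(self, frags):
        return LiftoverFragmentSet("p1", "RGN", frags)

    def test_short_fragments_are_discarded(self):
        assert clean_fragments(self._rgn([iv(0, 15), iv(100, 110)])) == []

    def test_close_fragments_are_merged(self):
        out = clean_fragments(self._rgn([iv(100, 200), iv(250, 400)]))
        assert out == [iv(100, 400)]

    def test_gap_of_exactly_100_not_merged(self):
        out = clean_fragments(self._rgn([iv(100, 200), iv(300, 400)]))
        assert out == [iv(100, 200), iv(300, 400)]

    def test_length_filter_runs_before_merge(self):
        # the 19 bp fragment would bridge into the big one if merged first
        out = clean_fragments(self._rgn([iv(100, 119), iv(150, 400)]))
        assert out == [iv(150, 400)]

    def test_boundary_length_20_survives(self):
        out = clean_fragments(self._rgn([iv(0, 20)]))
        assert out == [iv(0, 20)]

    def test_never_merges_across_chromosomes(self):
        out = clean_fragments(self._rgn([iv(0, 30, "c1"), iv(40, 80, "c2")]))
        assert out == [iv(0, 30, "c1"), iv(40, 80, "c2")]

    def test_idempotent(self, rng):
        for _ in range(50):
            frags = [iv(int(s), int(s) + int(l))
                     for s, l in zip(rng.integers(0, 2000, 8), rng.integers(1, 300, 8))]
            once = clean_fragments(self._rgn(frags))
            again = clean_fragments(self._rgn(once))
            assert once == again

    def test_rejects_sum_kind(self):
        with pytest.raises(ValueError):
            clean_fragments(LiftoverFragmentSet("p1", "SUM", []))


class TestSpeciesCall:
    SRC = peak(1000, 1600, 1300)

    def _sum(self, frags):
        return LiftoverFragmentSet("p1", "SUM", frags)

    def test_sum_overlap_without_atac_is_conserved_region(self):
        call = call_species_conservation(
            self.SRC, [iv(1000, 1600)], self._sum([iv(1200, 1251)]), []
        )
        assert call.status == CONSERVED_REGION
        assert call.conserved_intervals == (iv(1000, 1600),)

    def test_recipient_atac_upgrades_to_conserved_peak(self):
        atac = [peak(1500, 1700, 1600, "ra")]
        call = call_species_conservation(
            self.SRC, [iv(1000, 1600)], self._sum([iv(1200, 1251)]), atac
        )
        assert call.status == CONSERVED_PEAK

    def test_rgn_without_sum_overlap_is_not_conserved(self):
        call = call_species_conservation(
            self.SRC, [iv(1000, 1600)], self._sum([iv(5000, 5051)]), []
        )
        assert call.status == NOT_CONSERVED
        assert call.conserved_intervals == ()

    def test_empty_cleaned_rgn_is_not_conserved(self):
        call = call_species_conservation(self.SRC, [], self._sum([iv(1200, 1251)]), [])
        assert call.status == NOT_CONSERVED

    def test_atac_overlapping_unsupported_fragment_does_not_upgrade(self):
        # second fragment lacks SUM support; ATAC over it must not count
        call = call_species_conservation(
            self.SRC,
            [iv(1000, 1600), iv(3000, 3200)],
            self._sum([iv(1200, 1251)]),
            [peak(3100, 3300, 3200, "ra")],
        )
        assert call.status == CONSERVED_REGION

    def test_adding_atac_only_moves_status_upward(self, rng):
        for _ in range(50):
            s = int(rng.integers(0, 3000))
            frag = iv(s, s + int(rng.integers(20, 600)))
            sum_frag = iv(int(rng.integers(0, 3500)), int(rng.integers(3501, 4000)))
            base = call_species_conservation(self.SRC, [frag], self._sum([sum_frag]), [])
            a = int(rng.integers(0, 3500))
            more = call_species_conservation(
                self.SRC, [frag], self._sum([sum_frag]),
                [peak(a, a + 200, a + 100, "ra")],
            )
            rank = {NOT_CONSERVED: 0, CONSERVED_REGION: 1, CONSERVED_PEAK: 2}
            assert rank[more.status] >= rank[base.status]
            if base.status == NOT_CONSERVED:
                assert more.status == NOT_CONSERVED


class TestAggregate:
    def _call(self, status, sp):
        frags = () if status == NOT_CONSERVED else (iv(0, 100),)
        return SpeciesConservationCall("p1", sp, status, frags)

    def test_all_conserved_peaks_is_high(self):
        rec = aggregate_conservation(
            [self._call(CONSERVED_PEAK, s) for s in ("a", "b", "c")]
        )
        assert rec.aggregate == HIGH

    def test_any_conservation_is_partial(self):
        rec = aggregate_conservation([
            self._call(CONSERVED_REGION, "a"),
            self._call(NOT_CONSERVED, "b"),
            self._call(NOT_CONSERVED, "c"),
        ])
        assert rec.aggregate == PARTIAL

    def test_nothing_conserved_anywhere(self):
        rec = aggregate_conservation([self._call(NOT_CONSERVED, s) for s in "abc"])
        assert rec.aggregate == NOT_CONSERVED

    def test_exhaustive_partition_over_all_combinations(self):
        statuses = (CONSERVED_PEAK, CONSERVED_REGION, NOT_CONSERVED)
        seen = {HIGH: 0, PARTIAL: 0, NOT_CONSERVED: 0}
        for a in statuses:
            for b in statuses:
                for c in statuses:
                    rec = aggregate_conservation(
                        [self._call(a, "a"), self._call(b, "b"), self._call(c, "c")]
                    )
                    seen[rec.aggregate] += 1
        assert seen[HIGH] == 1 and seen[NOT_CONSERVED] == 1 and seen[PARTIAL] == 25

    def test_requires_three_distinct_species(self):
        with pytest.raises(ValueError):
            aggregate_conservation([self._call(NOT_CONSERVED, "a")] * 3)


class TestBlockLiftover:
    def test_single_block_offset_map(self):
        blocks = [AlignmentBlock(iv(0, 1000), iv(5000, 6000))]
        (frags,) = block_liftover([iv(100, 200)], blocks)
        assert frags == [iv(5100, 5200)]

    def test_interval_spanning_two_blocks_fragments(self):
        blocks = [
            AlignmentBlock(iv(0, 150), iv(5000, 5150)),
            AlignmentBlock(iv(300, 500), iv(9000, 9200)),
        ]
        (frags,) = block_liftover([iv(100, 400)], blocks)
        assert frags == [iv(5100, 5150), iv(9000, 9100)]

    def test_interval_outside_all_blocks_is_empty(self):
        blocks = [AlignmentBlock(iv(0, 100), iv(5000, 5100))]
        (frags,) = block_liftover([iv(500, 600)], blocks)
        assert frags == []

    def test_minus_strand_flips_coordinates(self):
        # src [0,1000) -> dst [5000,6000) reversed: src pos x maps to
        # dst 5000 + (1000 - 1 - x); src [100,200) -> dst [5800,5900)
        blocks = [AlignmentBlock(iv(0, 1000), iv(5000, 6000), "-")]
        (frags,) = block_liftover([iv(100, 200)], blocks)
        assert frags == [iv(5800, 5900)]

    def test_matches_per_base_oracle(self, rng):
        for _ in range(100):
            bs = sorted(rng.choice(np.arange(0, 900, 10), size=4, replace=False))
            blocks = []
            for k, s in enumerate(bs):
                length = int(rng.integers(10, 100))
                strand = "+" if rng.random() < 0.5 else "-"
                blocks.append(
                    AlignmentBlock(iv(int(s), int(s) + length),
                                   iv(2000 * (k + 1), 2000 * (k + 1) + length), strand)
                )
            q = iv(int(rng.integers(0, 500)), int(rng.integers(501, 1000)))
            (frags,) = block_liftover([q], blocks)
            got = set()
            for f in frags:
                got.update(range(f.start, f.end))
            want = set()
            for b in blocks:
                for x in range(max(q.start, b.src.start), min(q.end, b.src.end)):
                    if b.dst_strand == "+":
                        want.add(b.dst.start + (x - b.src.start))
                    else:
                        want.add(b.dst.start + (b.src.end - 1 - x))
            assert got == want

    def test_unequal_block_sides_rejected(self):
        with pytest.raises(ValueError):
            AlignmentBlock(iv(0, 100), iv(0, 99))


class TestContingency:
    def _records(self, rows):
        recs, classes = [], {}
        for i, (cls, agg) in enumerate(rows):
            pid = f"p{i}"
            recs.append(ConservationRecord(pid, {"a": NOT_CONSERVED}, agg))
            classes[pid] = cls
        return recs, classes

    def test_full_3x3_table_has_df_4(self):
        rows = []
        for cls in (PROMOTER, ENHANCER, UNCHARACTERIZED):
            for agg in (HIGH, PARTIAL, NOT_CONSERVED):
                rows.extend([(cls, agg)] * 5)
        res, posthoc = conservation_contingency_test(*self._records(rows))
        assert res.df == 4
        assert res.table.shape == (3, 3)
        assert len(posthoc) == 3
        assert (posthoc["p_bonferroni"] >= posthoc["p"]).all()

    def test_independent_table_gives_zero_chi2(self):
        # counts equal to the outer product of margins / n
        rows = []
        for cls, r in ((PROMOTER, 2), (ENHANCER, 1)):
            for agg, c in ((HIGH, 3), (PARTIAL, 6)):
                rows.extend([(cls, agg)] * (r * c))
        with pytest.warns(UserWarning):  # absent levels dropped
            res, _ = conservation_contingency_test(*self._records(rows))
        assert res.chi2 == pytest.approx(0, abs=1e-9)
        assert res.cramers_v == pytest.approx(0, abs=1e-9)

    def test_hand_computed_2x2(self):
        rows = [(PROMOTER, HIGH)] * 10 + [(ENHANCER, NOT_CONSERVED)] * 10
        with pytest.warns(UserWarning):  # absent levels dropped
            res, _ = conservation_contingency_test(*self._records(rows))
        assert res.chi2 == pytest.approx(20.0)
        assert res.cramers_v == pytest.approx(1.0)

    def test_zero_margin_level_dropped_with_warning(self):
        rows = [(PROMOTER, HIGH)] * 5 + [(PROMOTER, PARTIAL)] * 5 + \
               [(ENHANCER, HIGH)] * 5 + [(ENHANCER, PARTIAL)] * 5
        with pytest.warns(UserWarning, match="zero-margin"):
            res, _ = conservation_contingency_test(*self._records(rows))
        assert res.table.shape == (2, 2)

    def test_permutation_p_consistent_with_analytic(self):
        rng = np.random.default_rng(7)
        rows = []
        for _ in range(300):
            cls = (PROMOTER, ENHANCER, UNCHARACTERIZED)[rng.integers(0, 3)]
            agg = (HIGH, PARTIAL, NOT_CONSERVED)[rng.integers(0, 3)]
            rows.append((cls, agg))
        res, _ = conservation_contingency_test(*self._records(rows), n_perm=999, seed=1)
        assert res.p_perm is not None
        # null data: both p-values should be unremarkable and similar
        assert abs(res.p_perm - res.p_analytic) < 0.2

    def test_fractions_partition(self):
        recs, _ = self._records([(PROMOTER, HIGH), (PROMOTER, PARTIAL),
                                 (ENHANCER, NOT_CONSERVED)])
        fr = conservation_fractions(recs)
        assert sum(fr.values()) == pytest.approx(1.0)
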