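"""Overlap predicate, overlap ratios, relative variation, outliers, R_av and
triple mining, each checked against direct enumeration where it matters."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cochip.colocalization import (
    EmptyRestrictionError,
    PairDynamics,
    PairOverlap,
    average_overlap_ratio,
    mine_combinations,
    outlier_pairs,
    overlap_ratio,
    overlap_ratio_in_regions,
    peaks_overlap,
    relative_variation,
)
from cochip.core import GenomicInterval

from conftest import make_peak, make_track, oracle_overlap_ratio, random_track


BASE = 100_000  # keeps test coordinates comfortably positive


def peak_cw(center, width, chrom="chr1"):
    start = BASE + center - width // 2
    return make_peak(chrom, start, start + width)


class TestOverlapPredicate:
    def test_close_centers_overlap(self):
        assert peaks_overlap(peak_cw(100, 50), peak_cw(120, 50))  # 20 < 50

    def test_identical_peaks_overlap(self):
        p = peak_cw(500, 80)
        assert peaks_overlap(p, p)

    def test_far_centers_do_not_overlap(self):
        assert not peaks_overlap(peak_cw(0, 50), peak_cw(100, 50))

    def test_boundary_is_strict(self):
        # centers 50 apart, half-widths sum to exactly 50: NOT overlapping
        assert not peaks_overlap(peak_cw(0, 50), peak_cw(50, 50))
        assert peaks_overlap(peak_cw(0, 50), peak_cw(49, 50))

    def test_different_chromosomes_never_overlap(self):
        assert not peaks_overlap(
            peak_cw(100, 50, "chr1"), peak_cw(100, 50, "chr2")
        )

    @given(
        c1=st.integers(0, 10_000), w1=st.integers(1, 500),
        c2=st.integers(0, 10_000), w2=st.integers(1, 500),
    )
    @settings(max_examples=300, deadline=None)
    def test_symmetric_and_matches_direct_formula(self, c1, w1, c2, w2):
        p, q = peak_cw(c1, w1), peak_cw(c2, w2)
        assert peaks_overlap(p, q) == peaks_overlap(q, p)
        assert peaks_overlap(p, q) == (abs(p.center - q.center) < (w1 + w2) / 2)


class TestOverlapRatio:
    def test_track_against_itself_is_one(self, rng):
        track = random_track(rng, 40)
        assert overlap_ratio(track, track).r_o == 1.0

    def test_disjoint_tracks_are_zero(self):
        a = make_track([(0, 100), (1000, 1100)], factor="A")
        b = make_track([(5000, 5100), (9000, 9100)], factor="B")
        assert overlap_ratio(a, b).r_o == 0.0

    def test_worked_example_half_matched(self):
        a = make_track([(0, 100), (200, 300)], factor="A")
        b = make_track([(50, 150), (400, 500)], factor="B")
        po = overlap_ratio(a, b)
        assert po.n_overlap == 1
        assert po.r_o == 0.5

    def test_both_empty_is_an_error(self):
        a = make_track([], factor="A")
        b = make_track([], factor="B")
        with pytest.raises(ValueError):
            overlap_ratio(a, b)

    def test_symmetry(self, rng):
        a = random_track(rng, 60, factor="A")
        b = random_track(rng, 35, factor="B")
        assert overlap_ratio(a, b).r_o == overlap_ratio(b, a).r_o

    def test_sweep_equals_brute_force_on_random_tracks(self, rng):
        for _ in range(40):
            n_a = int(rng.integers(1, 30))
            n_b = int(rng.integers(1, 30))
            a = random_track(rng, n_a, factor="A", span=50_000)
            b = random_track(rng, n_b, factor="B", span=50_000)
            assert overlap_ratio(a, b).r_o == pytest.approx(
                oracle_overlap_ratio(a, b), abs=1e-12
            )

    def test_multi_chromosome_tracks(self, rng):
        from cochip.core import FactorTrack

        peaks_a = random_track(rng, 20, chrom="chr1").peaks + random_track(
            rng, 20, chrom="chr2"
        ).peaks
        peaks_b = random_track(rng, 20, chrom="chr1").peaks + random_track(
            rng, 15, chrom="chr3"
        ).peaks
        a = FactorTrack(factor_name="A", cell_line="C", peaks=peaks_a)
        b = FactorTrack(factor_name="B", cell_line="C", peaks=peaks_b)
        assert overlap_ratio(a, b).r_o == pytest.approx(
            oracle_overlap_ratio(a, b), abs=1e-12
        )

    def test_pair_event_mode_counts_events(self):
        # one wide A peak overlapping two B peaks: 2 events vs 1.5 matched
        a = make_track([(0, 1000)], factor="A")
        b = make_track([(100, 200), (700, 800)], factor="B")
        matched = overlap_ratio(a, b, count_mode="matched")
        events = overlap_ratio(a, b, count_mode="pairs")
        assert matched.n_overlap == 1.5
        assert matched.r_o == 1.0
        assert events.n_overlap == 2
        assert events.r_o == pytest.approx(4 / 3)


class TestRegionRestriction:
    def test_whole_chromosome_region_is_identity(self, rng):
        a = random_track(rng, 25, factor="A", span=40_000)
        b = random_track(rng, 25, factor="B", span=40_000)
        regions = [GenomicInterval("chr1", 0, 10_000_000)]
        assert (
            overlap_ratio_in_regions(a, b, regions).r_o
            == overlap_ratio(a, b).r_o
        )

    def test_empty_restriction_is_flagged(self):
        a = make_track([(0, 100)], factor="A")
        b = make_track([(50, 150)], factor="B")
        with pytest.raises(EmptyRestrictionError):
            overlap_ratio_in_regions(a, b, [GenomicInterval("chr9", 0, 100)])

    def test_half_covering_regions_use_surviving_peaks_only(self):
        a = make_track([(0, 100), (10_000, 10_100)], factor="A")
        b = make_track([(50, 150), (10_050, 10_150)], factor="B")
        # only the second cluster's centers are inside the region
        regions = [GenomicInterval("chr1", 9_000, 11_000)]
        po = overlap_ratio_in_regions(a, b, regions)
        assert (po.n_a, po.n_b) == (1, 1)
        assert po.r_o == 1.0


class TestRelativeVariation:
    def test_equal_ratios_give_zero(self):
        assert relative_variation(0.3, 0.3) == 0.0

    def test_alpha_guards_double_zero(self):
        assert relative_variation(0.0, 0.0) == 0.0

    def test_printed_pair_value(self):
        # reference analysis prints 0.676 for these (rounded) inputs
        assert relative_variation(0.366, 0.071) == pytest.approx(0.676, abs=0.01)

    def test_antisymmetry(self):
        assert relative_variation(0.4, 0.1) == -relative_variation(0.1, 0.4)


class TestOutliers:
    def test_constant_irv_has_no_outliers(self):
        pairs = [PairDynamics("A", f"B{i}", 0.5, 0.5, 0.2) for i in range(5)]
        assert not any(p.is_outlier for p in outlier_pairs(pairs))

    def test_single_extreme_value_is_flagged(self):
        pairs = [
            PairDynamics("A", f"B{i}", 0.5, 0.5, 0.001 * i) for i in range(20)
        ]
        pairs.append(PairDynamics("A", "EXT", 0.9, 0.0, 0.99))
        flagged = [p.factor_b for p in outlier_pairs(pairs) if p.is_outlier]
        assert flagged == ["EXT"]

    def test_gaussian_two_sided_mass_near_4_6_percent(self, rng):
        values = rng.normal(0, 0.3, size=4000)
        pairs = [
            PairDynamics("A", f"B{i}", 0.5, 0.5, float(v))
            for i, v in enumerate(values)
        ]
        frac = np.mean([p.is_outlier for p in outlier_pairs(pairs)])
        assert frac == pytest.approx(0.0455, abs=0.012)


class TestAverageOverlap:
    def test_no_overlaps_give_zero(self):
        t = make_track([(0, 100)], factor="A")
        others = [make_track([(10_000, 10_100)], factor="B")]
        assert average_overlap_ratio(t, others).r_av == 0.0

    def test_all_factors_overlapping_give_one(self, rng):
        t = random_track(rng, 10, factor="A")
        others = [
            make_track([(p.start, p.end) for p in t.peaks], factor=f"B{i}")
            for i in range(3)
        ]
        assert average_overlap_ratio(t, others).r_av == 1.0

    def test_hand_computed_fraction(self):
        # 1 peak overlapped by exactly 2 of 54 other factors
        t = make_track([(0, 100)], factor="A")
        hit = [(40, 140)]
        miss = [(10_000, 10_100)]
        others = [make_track(hit, factor="B1"), make_track(hit, factor="B2")]
        others += [make_track(miss, factor=f"B{i}") for i in range(3, 55)]
        ao = average_overlap_ratio(t, others)
        assert ao.n_others == 54
        assert ao.r_av == pytest.approx(2 / 54)

    def test_counts_factors_not_peaks(self):
        # one other factor with 3 overlapping peaks still counts once
        t = make_track([(0, 1000)], factor="A")
        other = make_track([(100, 200), (300, 400), (500, 600)], factor="B")
        ao = average_overlap_ratio(t, [other])
        assert ao.x.tolist() == [1]
        assert ao.r_av == 1.0

    def test_empty_track_is_an_error(self):
        with pytest.raises(ValueError):
            average_overlap_ratio(
                make_track([], factor="A"), [make_track([(0, 10)], factor="B")]
            )


class TestCombinationMining:
    @staticmethod
    def pair_table(weights):
        return [
            PairOverlap(a, b, 0.0, 0, 0, w) for (a, b), w in weights.items()
        ]

    def test_full_triangle_reported(self):
        table = self.pair_table(
            {("A", "B"): 0.7, ("A", "C"): 0.7, ("B", "C"): 0.7}
        )
        assert mine_combinations(table) == [(("A", "B", "C"), 0.7)]

    def test_chain_is_not_a_clique(self):
        table = self.pair_table(
            {("A", "B"): 0.7, ("B", "C"): 0.7, ("A", "C"): 0.2}
        )
        assert mine_combinations(table) == []

    def test_threshold_is_strict(self):
        table = self.pair_table(
            {("A", "B"): 0.6, ("A", "C"): 0.9, ("B", "C"): 0.9}
        )
        assert mine_combinations(table, threshold=0.6) == []

    def test_matches_exhaustive_enumeration(self, rng):
        factors = [f"F{i}" for i in range(10)]
        weights = {
            (a, b): float(rng.uniform(0, 1))
            for a, b in itertools.combinations(factors, 2)
        }
        got = mine_combinations(self.pair_table(weights), k=3, threshold=0.5)
        expected = set()
        for combo in itertools.combinations(factors, 3):
            ws = [
                weights[(a, b)] for a, b in itertools.combinations(combo, 2)
            ]
            if all(w > 0.5 for w in ws):
                expected.add(combo)
        assert {c for c, _ in got} == expected
        mins = [w for _, w in got]
        assert mins == sorted(mins, reverse=True)
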