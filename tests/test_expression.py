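import numpy as np
import pytest

from spinqc.expression import (
    DEConfig,
    LibraryPair,
    SaturationPoint,
    correction_factor,
    corrected_counts,
    coverage,
    coverage_summary,
    exclusive_transcripts,
    length_count_correlation,
    pooled_records,
    saturation_curve,
    unmapped_fraction,
)
from spinqc.io_formats import CountRecord


def make_pair(counts_a, counts_b, total_a=None, total_b=None):
    ra = [CountRecord(t, 100, c) for t, c in counts_a.items()]
    rb = [CountRecord(t, 100, c) for t, c in counts_b.items()]
    return LibraryPair.from_records(ra, rb, total_a, total_b)


class TestCorrectionFactor:
    def test_six_decimal_factor_scales_larger_library(self):
        factor, scaled = correction_factor(331_060_788, 292_205_142)
        assert factor == 0.882633
        assert scaled == "a"

    def test_equal_totals(self):
        assert correction_factor(1000, 1000) == (1.0, "a")

    def test_half(self):
        assert correction_factor(200, 100) == (0.5, "a")
        assert correction_factor(100, 200) == (0.5, "b")

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            correction_factor(0, 100)

    def test_corrected_total_matches_smaller_library(self):
        rng = np.random.default_rng(0)
        counts = {f"t{i}": int(c) for i, c in enumerate(rng.integers(0, 5000, 500))}
        sum_a = sum(counts.values())
        counts_b = {t: c // 2 for t, c in counts.items()}
        sum_b = sum(counts_b.values())
        pair = make_pair(counts, counts_b, sum_a, sum_b)
        corr_a, corr_b = corrected_counts(pair)
        # multiplicative scaling with a 6-decimal factor: equal up to rounding
        assert sum(corr_a.values()) == pytest.approx(sum_b, rel=1e-5)
        assert sum(corr_b.values()) == sum_b


class TestCoverage:
    def test_reads_per_bp(self):
        assert coverage(CountRecord("t", 250, 500)) == 2.0
        assert coverage(CountRecord("t", 250, 0)) == 0.0
        assert coverage(CountRecord("t", 1, 1)) == 1.0

    def test_summary_worked_percentage(self):
        records = [CountRecord(f"a{i}", 100, 100) for i in range(110_176)] + [
            CountRecord(f"b{i}", 100, 1) for i in range(446_427 - 110_176)
        ]
        summary = coverage_summary(records)
        assert summary.pct_ge_1 == 24.68

    def test_summary_edge_fractions(self):
        records = [CountRecord("t1", 10, 0), CountRecord("t2", 10, 0)]
        summary = coverage_summary(records)
        assert summary.pct_zero_reads == 100.0
        single = coverage_summary([CountRecord("t", 100, 200)])
        assert single.mean_coverage == 2.0

    def test_disjoint_bins_plus_remainder_sum_to_one(self):
        rng = np.random.default_rng(1)
        records = [
            CountRecord(f"t{i}", int(rng.integers(50, 2000)), int(c))
            for i, c in enumerate(rng.integers(0, 300_000, 2000))
        ]
        s = coverage_summary(records)
        below_1 = 100.0 - s.pct_ge_1
        in_10_100 = s.pct_ge_1 - s.pct_1_to_10 - s.pct_gt_100
        total = below_1 + s.pct_1_to_10 + in_10_100 + s.pct_gt_100
        assert total == pytest.approx(100.0, abs=0.05)


class TestLengthCountCorrelation:
    def test_proportional_counts_give_spearman_one(self):
        records = [CountRecord(f"t{i}", 100 * i, 10 * i) for i in range(1, 30)]
        _, rho = length_count_correlation(records)
        assert rho == pytest.approx(1.0)

    def test_anti_monotone_counts_give_spearman_minus_one(self):
        records = [CountRecord(f"t{i}", 100 * i, 1000 - i) for i in range(1, 30)]
        _, rho = length_count_correlation(records)
        assert rho == pytest.approx(-1.0)

    def test_independent_planted_data_near_zero(self):
        rng = np.random.default_rng(2)
        records = [
            CountRecord(f"t{i}", int(le), int(c))
            for i, (le, c) in enumerate(
                zip(rng.integers(100, 5000, 10_000), rng.integers(0, 5000, 10_000))
            )
        ]
        r, rho = length_count_correlation(records)
        assert abs(r) < 0.03 and abs(rho) < 0.03

    def test_zero_variance_is_error(self):
        records = [CountRecord(f"t{i}", 100, 5) for i in range(5)]
        with pytest.raises(ValueError):
            length_count_correlation(records)


class TestExclusiveTranscripts:
    def test_boundary_at_threshold(self):
        pair = make_pair({"hit": 1000, "miss": 999}, {"hit": 0, "miss": 0},
                         10_000, 10_000)
        excl_a, excl_b = exclusive_transcripts(pair)
        assert excl_a == {"hit"} and excl_b == set()

    def test_single_read_on_other_side_blocks_call(self):
        pair = make_pair({"t": 5000}, {"t": 1}, 10_000, 10_000)
        assert exclusive_transcripts(pair) == (set(), set())

    def test_threshold_applies_to_corrected_count(self):
        # library a is twice as deep: factor 0.5 halves its counts
        pair = make_pair({"t": 1999}, {"t": 0}, 20_000, 10_000)
        assert exclusive_transcripts(pair) == (set(), set())
        pair = make_pair({"t": 2000}, {"t": 0}, 20_000, 10_000)
        assert exclusive_transcripts(pair) == ({"t"}, set())

    def test_sets_disjoint_and_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        counts_a = {f"t{i}": int(c) for i, c in enumerate(rng.integers(0, 3000, 300))}
        counts_b = {f"t{i}": int(c) for i, c in enumerate(rng.integers(0, 2, 300))}
        pair = make_pair(counts_a, counts_b, 100_000, 90_000)
        previous_a = previous_b = None
        for threshold in (200, 500, 1000, 2000):
            excl_a, excl_b = exclusive_transcripts(pair, DEConfig(min_reads=threshold))
            assert excl_a & excl_b == set()
            if previous_a is not None:
                assert excl_a <= previous_a and excl_b <= previous_b
            previous_a, previous_b = excl_a, excl_b


class TestUnmappedFraction:
    def test_worked_percentage(self):
        records = [CountRecord(f"u{i}", 100, 0) for i in range(8920)] + [
            CountRecord(f"m{i}", 100, 3) for i in range(446_427 - 8920)
        ]
        count, pct_int, pct_2dp = unmapped_fraction(records)
        assert (count, pct_int, pct_2dp) == (8920, 2, 2.0)

    def test_none_and_all(self):
        assert unmapped_fraction([CountRecord("t", 10, 5)])[1] == 0
        assert unmapped_fraction([CountRecord("t", 10, 0)])[1] == 100

    def test_pooled_records_sum_libraries(self):
        pair = make_pair({"t1": 3, "t2": 0}, {"t1": 4, "t2": 0}, 100, 100)
        pooled = pooled_records(pair)
        assert {r.transcript_id: r.mapped for r in pooled} == {"t1": 7, "t2": 0}


class TestSaturationCurve:
    def points(self, uniques):
        return [
            SaturationPoint(fraction=0.1 * (i + 1), n_transcripts=1000 * (i + 1),
                            n_unique_hits=u)
            for i, u in enumerate(uniques)
        ]

    def test_plateau_flagged_where_growth_stops(self):
        report = saturation_curve(self.points([100, 180, 240, 241, 241, 241, 241]))
        assert report.plateau_index == 3
        assert report.plateau_fraction == pytest.approx(0.4)

    def test_single_point_has_no_plateau(self):
        report = saturation_curve(self.points([100]))
        assert report.plateau_index is None

    def test_non_monotone_fractions_rejected(self):
        pts = self.points([1, 2])
        pts[1].fraction = pts[0].fraction
        with pytest.raises(ValueError):
            saturation_curve(pts)

    def test_no_plateau_when_growth_continues(self):
        report = saturation_curve(self.points([100, 200, 400, 800]))
        assert report.plateau_index is None


class TestLibraryPair:
    def test_zero_fills_missing_transcripts(self):
        pair = make_pair({"t1": 5}, {"t2": 7}, 100, 100)
        assert pair.counts_a["t2"].mapped == 0
        assert pair.counts_b["t1"].mapped == 0
        assert set(pair.counts_a) == set(pair.counts_b)

    def test_rejects_zero_totals(self):
        with pytest.raises(ValueError):
            make_pair({"t": 1}, {"t": 1}, 0, 10)
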