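"""Binned CNV differencing, region calling, correlation and coverage
ratios."""
import numpy as np
import pytest

from gcrtools import (
    BinnedCounts,
    CNVProfile,
    RegionSet,
    cnv_correlation,
    cnv_difference,
    common_regions,
    high_cnv_regions,
    interval_coverage_ratio,
    simulate_binned_counts,
)
from gcrtools.errors import DataError, SpecificationError, UndefinedRatioError
from gcrtools.rearrange import CopyNumberTruth

from _oracles import bitmap_intersection


def counts_from(values, sample_id="s", bin_size=1000):
    values = {c: np.asarray(v, dtype=np.int64) for c, v in values.items()}
    lengths = {c: len(v) * bin_size for c, v in values.items()}
    return BinnedCounts(sample_id, bin_size, values, lengths)


def profile_from(values, bin_size=1000):
    values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
    lengths = {c: len(v) * bin_size for c, v in values.items()}
    return CNVProfile("p", bin_size, values, lengths)


class TestCnvDifference:
    def test_identical_tables_give_zero_profile(self):
        a = counts_from({"chr1": [5, 8, 13]})
        b = counts_from({"chr1": [5, 8, 13]})
        profile = cnv_difference(a, b, normalization="none")
        assert np.allclose(profile.values["chr1"], 0.0)

    def test_doubled_bin_expected_difference(self):
        lengths = {"chr1": 50_000_000}
        truth = CopyNumberTruth.baseline(lengths, 50_000)
        truth.base_sum["chr1"][:100] *= 2
        diffs = []
        for s in range(50):
            gcr = simulate_binned_counts(truth, 100.0, seed=s)
            nc = simulate_binned_counts(
                CopyNumberTruth.baseline(lengths, 50_000), 100.0, seed=1000 + s)
            profile = cnv_difference(gcr, nc, normalization="none")
            diffs.append(profile.values["chr1"][:100].mean())
        assert 90 <= np.mean(diffs) <= 110

    def test_total_count_normalization_is_depth_invariant(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=500)
        a = counts_from({"chr1": base})
        a2 = counts_from({"chr1": base * 2})  # doubled library
        b = counts_from({"chr1": rng.poisson(100, size=500)})
        p1 = cnv_difference(a, b)
        p2 = cnv_difference(a2, b)
        # doubling the sample library leaves the normalized profile nearly
        # unchanged (not exactly: the scale target moves with the mean)
        assert np.corrcoef(p1.values["chr1"], p2.values["chr1"])[0, 1] > 0.99

    def test_antisymmetry_without_normalization(self):
        rng = np.random.default_rng(1)
        a = counts_from({"chr1": rng.poisson(100, 50)})
        b = counts_from({"chr1": rng.poisson(100, 50)})
        pab = cnv_difference(a, b, normalization="none")
        pba = cnv_difference(b, a, normalization="none")
        assert np.array_equal(pab.values["chr1"], -pba.values["chr1"])

    def test_mismatched_grid_rejected(self):
        a = counts_from({"chr1": [1, 2]})
        b = counts_from({"chr1": [1, 2, 3]})
        with pytest.raises(DataError):
            cnv_difference(a, b)


class TestHighCnvRegions:
    def test_flat_profile_yields_nothing(self):
        profile = profile_from({"chr1": [0.0] * 100})
        assert len(high_cnv_regions(profile, "abs_z", t=2.0)) == 0
        assert len(high_cnv_regions(profile, "abs_quantile", q=0.95)) == 0

    def test_single_extreme_bin_found_by_rank(self):
        values = [0.0] * 100
        values[37] = 50.0
        profile = profile_from({"chr1": values})
        regions = high_cnv_regions(profile, "abs_quantile", q=0.95)
        assert list(regions) == [("chr1", 37_000, 38_000)]

    def test_adjacent_extreme_bins_merge(self):
        values = [0.0] * 100
        values[10] = values[11] = -40.0
        profile = profile_from({"chr1": values})
        regions = high_cnv_regions(profile, "abs_quantile", q=0.95)
        assert list(regions) == [("chr1", 10_000, 12_000)]

    def test_rank_rule_matches_sorting_oracle(self, rng):
        values = rng.normal(0, 10, size=200)
        profile = profile_from({"chr1": values})
        regions = high_cnv_regions(profile, "abs_quantile", q=0.9)
        threshold = np.quantile(np.abs(values), 0.9)
        expected_bins = set(np.flatnonzero(np.abs(values) > threshold))
        got_bins = set()
        for _, s, e in regions:
            got_bins.update(range(s // 1000, e // 1000))
        assert got_bins == expected_bins

    def test_invalid_rule_parameters(self):
        profile = profile_from({"chr1": [1.0, 2.0]})
        with pytest.raises(SpecificationError):
            high_cnv_regions(profile, "abs_quantile", q=1.5)
        with pytest.raises(SpecificationError):
            high_cnv_regions(profile, "abs_z", t=-1)


class TestCommonRegions:
    def test_disjoint_and_identical(self):
        a = RegionSet([("chr1", 0, 10), ("chr2", 5, 15)])
        b = RegionSet([("chr1", 20, 30)])
        assert len(common_regions(a, b)) == 0
        assert list(common_regions(a, a)) == list(a)

    def test_matches_bitmap_oracle_on_random_sets(self, rng):
        lengths = {"chr1": 50_000, "chr2": 50_000}
        def random_set():
            ivs = []
            for _ in range(30):
                c = "chr1" if rng.random() < 0.5 else "chr2"
                s = int(rng.integers(0, 49_000))
                ivs.append((c, s, s + int(rng.integers(1, 1000))))
            return RegionSet(ivs)
        a, b = random_set(), random_set()
        got = list(common_regions(a, b))
        assert got == bitmap_intersection(list(a), list(b), lengths)


class TestCorrelation:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 5, 100)
        p1 = profile_from({"chr1": x})
        p2 = profile_from({"chr1": 2 * x})
        report = cnv_correlation(p1, p2)
        assert report.r_squared == pytest.approx(1.0)
        assert report.slope == pytest.approx(2.0)

    def test_independent_profiles_near_zero(self):
        rng = np.random.default_rng(3)
        p1 = profile_from({"chr1": rng.normal(0, 5, 1000)})
        p2 = profile_from({"chr1": rng.normal(0, 5, 1000)})
        assert cnv_correlation(p1, p2).r_squared < 0.05

    def test_snr_one_gives_half_r_squared(self):
        r2 = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            x = rng.normal(0, 5, 1000)
            p1 = profile_from({"chr1": x})
            p2 = profile_from({"chr1": x + rng.normal(0, 5, 1000)})
            r2.append(cnv_correlation(p1, p2).r_squared)
        assert 0.4 <= np.mean(r2) <= 0.6

    def test_per_chromosome_equals_manual_aggregation(self):
        rng = np.random.default_rng(4)
        vals1 = {f"chr{i}": rng.normal(0, 5, 50) for i in range(1, 7)}
        vals2 = {f"chr{i}": rng.normal(0, 5, 50) for i in range(1, 7)}
        p1, p2 = profile_from(vals1), profile_from(vals2)
        report = cnv_correlation(p1, p2, "per_chromosome")
        from scipy import stats
        x = [vals1[c].sum() for c in vals1]
        y = [vals2[c].sum() for c in vals2]
        fit = stats.linregress(x, y)
        assert report.r_squared == pytest.approx(fit.rvalue**2)
        assert report.slope == pytest.approx(fit.slope)
        assert report.n_points == 6


class TestIntervalCoverageRatio:
    def test_uniform_coverage_is_one(self):
        depth = np.full(1000, 7.0)
        assert interval_coverage_ratio(depth, (100, 300), (600, 900)) == 1.0

    def test_halved_numerator(self):
        depth = np.full(1000, 10.0)
        depth[100:300] = 5.0
        assert interval_coverage_ratio(depth, (100, 300), (600, 900)) == 0.5

    def test_cassette_deletion_detected(self, rng):
        # intact marker at one end, deleted central region: coverage drops
        depth = rng.poisson(100, size=5000).astype(float)
        depth[1000:3000] = rng.poisson(5, size=2000)  # residual mis-mapping
        ratio = interval_coverage_ratio(depth, (1123, 2900), (4000, 4800))
        assert ratio < 0.2

    def test_zero_denominator_raises(self):
        depth = np.zeros(100)
        depth[:50] = 1.0
        with pytest.raises(UndefinedRatioError):
            interval_coverage_ratio(depth, (0, 50), (50, 100))
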