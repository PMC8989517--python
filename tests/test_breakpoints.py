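"""Breakpoint statistics: counting oracle, permutation test behaviour,
Monte-Carlo null, nearest-element distances, linearization."""
import numpy as np
import pytest

from gcrtools import (
    Junction,
    RegionSet,
    count_breakpoints_in_regions,
    linearize_breakpoints,
    mc_intra_inter,
    nearest_element_distance,
    permutation_enrichment,
)
from gcrtools.breakpoints import IN_ELEMENT, LT_1KB, NO_ELEMENT
from gcrtools.experiments import (
    _random_junctions,
    _random_regions,
    oracle_nearest_distance,
)
from gcrtools.synthetic import RepeatAnnotation, RepeatRecord

from _oracles import naive_count_breakpoints

LENGTHS = {"chr1": 1_000_000, "chr2": 800_000, "chr3": 500_000}


def random_junctions(rng, n=50):
    return _random_junctions(LENGTHS, n, rng)


class TestCounting:
    def test_no_regions_counts_zero(self, rng):
        junctions = random_junctions(rng)
        assert count_breakpoints_in_regions(junctions, [], "per_breakpoint") == 0

    def test_all_inside_one_region(self):
        junctions = [Junction("chr1", 100 + i, "+", "chr1", 200 + i, "-",
                              "translocation_intra") for i in range(10)]
        regions = RegionSet([("chr1", 0, 1000)])
        assert count_breakpoints_in_regions(
            junctions, regions, "per_breakpoint") == 20
        assert count_breakpoints_in_regions(
            junctions, regions, "per_junction") == 10

    @pytest.mark.parametrize("counting", ["per_breakpoint", "per_junction"])
    def test_matches_double_loop_oracle(self, rng, counting):
        junctions = random_junctions(rng, 200)
        regions = _random_regions(LENGTHS, 0.15, 20_000, rng)
        got = count_breakpoints_in_regions(junctions, regions, counting)
        assert got == naive_count_breakpoints(junctions, list(regions),
                                              counting)

    def test_order_invariance(self, rng):
        junctions = random_junctions(rng, 100)
        regions = _random_regions(LENGTHS, 0.1, 20_000, rng)
        shuffled = list(junctions)
        rng.shuffle(shuffled)
        assert (count_breakpoints_in_regions(junctions, regions, "per_junction")
                == count_breakpoints_in_regions(shuffled, regions,
                                                "per_junction"))


class TestPermutationEnrichment:
    def test_zero_junctions_degenerate(self):
        regions = RegionSet([("chr1", 0, 10_000)])
        res = permutation_enrichment([], regions, LENGTHS, n_perm=100, seed=1)
        assert res.degenerate and res.p_value == 1.0

    def test_extreme_enrichment_is_significant(self, rng):
        regions = RegionSet([("chr1", 100_000, 150_000),
                             ("chr2", 0, 65_000)])  # 5% of the genome
        junctions = [Junction("chr1", int(rng.integers(100_000, 150_000)), "+",
                              "chr2", int(rng.integers(0, 65_000)), "-",
                              "translocation_inter") for _ in range(60)]
        res = permutation_enrichment(junctions, regions, LENGTHS,
                                     n_perm=1000, seed=2)
        assert res.p_value < 0.001
        assert res.empirical_p < 0.005

    def test_null_mean_tracks_region_fraction(self, rng):
        regions = _random_regions(LENGTHS, 0.10, 20_000, rng)
        junctions = random_junctions(rng, 150)  # 300 breakpoints
        res = permutation_enrichment(junctions, regions, LENGTHS,
                                     n_perm=1000, seed=3)
        fraction = regions.total_length / sum(LENGTHS.values())
        expectation = 300 * fraction
        binom_sd = np.sqrt(300 * fraction * (1 - fraction))
        assert abs(res.null_mean - expectation) < 3 * binom_sd

    def test_p_decreases_as_breakpoints_move_into_regions(self, rng):
        regions = _random_regions(LENGTHS, 0.10, 20_000, rng)
        p_values = []
        for enrichment in (1.0, 3.0, 10.0):
            junctions = _random_junctions(LENGTHS, 100, rng, regions=regions,
                                          enrichment=enrichment)
            res = permutation_enrichment(junctions, regions, LENGTHS,
                                         n_perm=500, seed=4)
            p_values.append(res.p_value)
        assert p_values[0] > p_values[1] > p_values[2]


class TestMcIntraInter:
    def test_single_chromosome_all_intra(self):
        junctions = [Junction("chr1", 10, "+", "chr1", 500, "-",
                              "translocation_intra")]
        res = mc_intra_inter(junctions, {"chr1": 10_000}, seed=1)
        assert res.closed_form_intra_fraction == 1.0
        assert res.expected_intra_mean == res.n_events

    def test_two_equal_chromosomes_closed_form_half(self):
        junctions = [Junction("chr1", 10, "+", "chr2", 500, "-",
                              "translocation_inter")]
        res = mc_intra_inter(junctions, {"chr1": 5_000, "chr2": 5_000}, seed=2)
        assert res.closed_form_intra_fraction == pytest.approx(0.5)

    def test_simulation_matches_closed_form(self):
        from gcrtools.experiments import HUMAN_LIKE_LENGTHS_MB
        lengths = {f"c{i}": m * 1_000_000
                   for i, m in enumerate(HUMAN_LIKE_LENGTHS_MB)}
        dummy = [Junction("c0", 1, "+", "c1", 2, "-", "translocation_inter")]
        res = mc_intra_inter(dummy, lengths, n_runs=1, seed=3,
                             n_events=100_000)
        sim = res.expected_intra_mean / res.n_events
        cf = res.closed_form_intra_fraction
        se = np.sqrt(cf * (1 - cf) / res.n_events)
        assert abs(sim - cf) <= 3 * se

    def test_estimator_unbiased_over_seeds(self):
        lengths = {"chr1": 600_000, "chr2": 300_000, "chr3": 100_000}
        dummy = [Junction("chr1", 1, "+", "chr2", 2, "-",
                          "translocation_inter")]
        cf = mc_intra_inter(dummy, lengths, seed=0).closed_form_intra_fraction
        sims = [mc_intra_inter(dummy, lengths, n_runs=1, seed=s,
                               n_events=1000).expected_intra_mean / 1000
                for s in range(200)]
        se_of_mean = np.sqrt(cf * (1 - cf) / 1000) / np.sqrt(200)
        assert abs(np.mean(sims) - cf) < 2 * se_of_mean


class TestNearestElement:
    def annotation(self):
        return RepeatAnnotation([
            RepeatRecord("chr1", 10_000, 10_300, "Alu_like", "+", "a0", 0),
            RepeatRecord("chr1", 50_000, 56_000, "L1_like", "+", "l0", 0),
        ])

    def test_inside_element_distance_zero(self):
        records = nearest_element_distance([("chr1", 10_150)],
                                           self.annotation(), "Alu_like")
        assert records[0].distance == 0
        assert records[0].category == IN_ELEMENT

    def test_gap_left_of_element(self):
        records = nearest_element_distance([("chr1", 9_500)],
                                           self.annotation(), "Alu_like")
        assert records[0].distance == 500
        assert records[0].category == LT_1KB

    def test_missing_class_on_chromosome(self):
        records = nearest_element_distance([("chr2", 100)],
                                           self.annotation(), "Alu_like")
        assert records[0].category == NO_ELEMENT

    def test_matches_exhaustive_scan(self, rng):
        records = []
        for i in range(500):
            chrom = f"chr{int(rng.integers(1, 4))}"
            start = int(rng.integers(0, 500_000))
            records.append(RepeatRecord(chrom, start, start + 300,
                                        "Alu_like", "+", f"e{i}", 0))
        # overlaps are irrelevant for distance; sort as the contract requires
        records.sort(key=lambda r: (r.chrom, r.start))
        annotation = RepeatAnnotation(records)
        points = [(f"chr{int(rng.integers(1, 4))}",
                   int(rng.integers(0, 500_000))) for _ in range(500)]
        got = [r.distance for r in
               nearest_element_distance(points, annotation, "Alu_like")]
        expected = oracle_nearest_distance(points, records)
        assert got == expected


class TestLinearize:
    def test_origin_junction_maps_to_origin(self):
        j = Junction("chr1", 0, "+", "chr1", 0, "-", "deletion")
        assert linearize_breakpoints([j], ["chr1"], {"chr1": 100})[0] == (0, 0)

    def test_offsets_match_cumulative_sum_oracle(self, rng):
        order = list(LENGTHS)
        junctions = random_junctions(rng, 100)
        points = linearize_breakpoints(junctions, order, LENGTHS)
        offsets = {c: sum(LENGTHS[o] for o in order[:i])
                   for i, c in enumerate(order)}
        idx = {c: i for i, c in enumerate(order)}
        for j, (x, y) in zip(junctions, points):
            ends = sorted([((idx[j.chromA], j.posA), j.chromA, j.posA),
                           ((idx[j.chromB], j.posB), j.chromB, j.posB)])
            expected_x = offsets[ends[0][1]] + ends[0][2]
            expected_y = offsets[ends[1][1]] + ends[1][2]
            assert (x, y) == (expected_x, expected_y)

    def test_intra_junction_points_near_diagonal(self, rng):
        junctions = [Junction("chr2", 100, "+", "chr2", 700_000, "-",
                              "translocation_intra")]
        (x, y), = linearize_breakpoints(junctions, list(LENGTHS), LENGTHS)
        assert abs(x - y) < LENGTHS["chr2"]

    def test_plot_writes_figure(self, rng, tmp_path):
        from gcrtools.breakpoints import plot_breakpoints
        junctions = random_junctions(rng, 20)
        points = linearize_breakpoints(junctions, list(LENGTHS), LENGTHS)
        path = tmp_path / "breakpoints.png"
        plot_breakpoints(points, list(LENGTHS), LENGTHS, path)
        assert path.stat().st_size > 0
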