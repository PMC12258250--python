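import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promoterscan.empirical_likelihood import (
    LOWER_TAIL,
    UPPER_TAIL,
    CagePeakSet,
    CorrelationTable,
    EmpiricalScoreTable,
    build_cpg_table,
    build_distance_table,
    build_overlap_table,
    build_tail_table,
    cpg_ratio,
    cpg_ratio_profile,
    genome_distance_vector,
    genome_overlap_vector,
    interval_distance,
    lls_atac,
    lls_cage,
    lls_conservation,
    lls_correlation,
    lls_cpg,
    lls_eqtl,
    lls_metaclusters,
)
from promoterscan.genome_io import ConfigurationError, GenomicInterval


def brute_force_distances(elements, length):
    """Oracle: per-position nearest-element distance by direct minimisation."""
    out = []
    for pos in range(length):
        best = math.inf
        for el in elements:
            if el.start <= pos < el.end:
                best = 0
                break
            best = min(best, el.start - pos if pos < el.start else pos - (el.end - 1))
        out.append(best)
    return np.array(out)


class TestEmpiricalScoreTable:
    def test_upper_tail_probabilities(self):
        # oracle: count of values >= 1 over the sample of 4
        table = build_tail_table([0, 0, 1, 2], UPPER_TAIL, "t")
        assert table.prob(1) == pytest.approx(0.5)
        assert table.lls(1) == pytest.approx(1.0)

    def test_query_below_support_upper_tail(self):
        table = build_tail_table([0, 0, 1, 2], UPPER_TAIL, "t")
        assert table.prob(-5) == 1.0
        assert table.lls(-5) == 0.0

    def test_query_above_support_hits_floor(self):
        table = build_tail_table([0, 0, 1, 2], UPPER_TAIL, "t")
        assert table.prob(99) == pytest.approx(1 / 5)  # eps = 1/(n+1)
        assert np.isfinite(table.lls(99))

    def test_lower_tail_mirror(self):
        table = build_tail_table([0, 1, 2, 3], LOWER_TAIL, "t")
        assert table.prob(0) == pytest.approx(0.25)
        assert table.prob(3) == 1.0
        assert table.prob(-1) == pytest.approx(table.eps)

    def test_json_round_trip(self, tmp_path):
        table = build_tail_table([0.5, 1.5, 2.5], UPPER_TAIL, "t")
        p = tmp_path / "t.json"
        table.to_json(p)
        back = EmpiricalScoreTable.from_json(p)
        np.testing.assert_array_equal(back.support, table.support)
        np.testing.assert_array_equal(back.probabilities, table.probabilities)
        assert back.direction == table.direction
        assert back.eps == table.eps

    @given(
        values=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=1, max_size=60
        ),
        direction=st.sampled_from([LOWER_TAIL, UPPER_TAIL]),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_finite_and_floored(self, values, direction):
        """LLS is monotone in the direction's sense, finite, and >= 0."""
        table = build_tail_table(values, direction, "prop")
        grid = np.linspace(min(values) - 1, max(values) + 1, 40)
        lls = np.asarray(table.lls(grid))
        assert np.all(np.isfinite(lls))
        assert np.all(lls >= 0)
        diffs = np.diff(lls)
        if direction == LOWER_TAIL:
            assert np.all(diffs <= 1e-9)  # closer (smaller) is more surprising
        else:
            assert np.all(diffs >= -1e-9)


class TestDistanceGeometry:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((10, 20), (15, 25), 0),   # overlap
            ((10, 20), (20, 30), 1),   # adjacent half-open
            ((10, 20), (25, 30), 6),
            ((25, 30), (10, 20), 6),   # symmetric
        ],
    )
    def test_interval_distance(self, a, b, expected):
        assert interval_distance(*a, *b) == expected

    def test_toy_genome_distance_vector(self):
        # oracle: per-position brute force on a length-10 genome, element [4, 6)
        elements = [GenomicInterval("g", 4, 6)]
        dist = genome_distance_vector(elements, {"g": 10})
        np.testing.assert_array_equal(dist, [4, 3, 2, 1, 0, 0, 1, 2, 3, 4])
        np.testing.assert_array_equal(dist, brute_force_distances(elements, 10))

    def test_distance_vector_matches_brute_force_random(self):
        rng = np.random.default_rng(12)
        length = 500
        elements = []
        for _ in range(8):
            s = int(rng.integers(0, length - 20))
            elements.append(GenomicInterval("g", s, s + int(rng.integers(1, 20))))
        got = genome_distance_vector(elements, {"g": length})
        np.testing.assert_array_equal(got, brute_force_distances(elements, length))

    def test_full_coverage_saturates(self):
        table = build_distance_table([GenomicInterval("g", 0, 10)], {"g": 10})
        assert table.prob(0) == 1.0
        assert table.lls(0) == 0.0

    def test_empty_elements_error_names_feature(self):
        with pytest.raises(ConfigurationError, match="conservation"):
            build_distance_table([], {"g": 10}, feature="conservation")

    def test_overlap_vector_matches_brute_force(self):
        rng = np.random.default_rng(13)
        length = 300
        elements = []
        for _ in range(10):
            s = int(rng.integers(0, length - 30))
            elements.append(GenomicInterval("g", s, s + int(rng.integers(1, 30))))
        got = genome_overlap_vector(elements, {"g": length})
        expected = np.array(
            [
                sum(1 for e in elements if e.start <= p < e.end)
                for p in range(length)
            ]
        )
        np.testing.assert_array_equal(got, expected)


class TestCageScore:
    def make_distance_table(self):
        # values (0,0,1,1,2,2,3,3): P(x<=0)=.25, <=1=.5, <=2=.75, <=3=1
        return build_tail_table([0, 0, 1, 1, 2, 2, 3, 3], LOWER_TAIL, "cage")

    def test_single_overlapping_peak_scores_zero(self):
        table = build_distance_table([GenomicInterval("g", 0, 10)], {"g": 10})
        peaks = CagePeakSet()
        peaks.add("gene", GenomicInterval("g", 2, 6), 5.0)
        hit = GenomicInterval("g", 3, 5)
        assert lls_cage(hit, peaks, "gene", table) == pytest.approx(0.0)

    def test_two_peak_hand_arithmetic(self):
        # oracle: -log2(0.5 * 0.75) + -log2(0.25 * 0.25)
        table = self.make_distance_table()
        peaks = CagePeakSet()
        hit = GenomicInterval("g", 10, 11)
        peaks.add("gene", GenomicInterval("g", 11, 12), 3.0)  # distance 1, P=0.5
        peaks.add("gene", GenomicInterval("g", 10, 11), 1.0)  # distance 0, P=0.25
        expected = -math.log2(0.5 * 0.75) + -math.log2(0.25 * 0.25)
        got = lls_cage(hit, peaks, "gene", table)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_inverted_weighting_multiplies_outside(self):
        table = self.make_distance_table()
        peaks = CagePeakSet()
        hit = GenomicInterval("g", 10, 11)
        peaks.add("gene", GenomicInterval("g", 11, 12), 3.0)
        peaks.add("gene", GenomicInterval("g", 10, 11), 1.0)
        expected = 0.75 * -math.log2(0.5) + 0.25 * -math.log2(0.25)
        assert lls_cage(hit, peaks, "gene", table, weighting="inverted") == (
            pytest.approx(expected, abs=1e-12)
        )

    def test_missing_gene_scores_zero(self):
        table = self.make_distance_table()
        assert lls_cage(GenomicInterval("g", 0, 5), CagePeakSet(), "nope", table) == 0.0


class TestCorrelationScore:
    def make_table(self):
        records = [(f"tf{i}", f"g{i}", c, None) for i, c in enumerate(
            [0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, -0.35, -0.55, 1.0]
        )]
        return CorrelationTable.from_records(records)

    def test_maximum_magnitude_scores_near_floor(self):
        table = self.make_table()
        # at the support maximum the empirical tail is 1/n; strictly beyond
        # it the floor eps = 1/(n+1) applies
        assert lls_correlation("tf9", "g9", table) == pytest.approx(-math.log2(1 / 10))
        assert float(table.magnitude_table.lls(1.5)) == pytest.approx(
            -math.log2(table.magnitude_table.eps)
        )

    def test_absent_pair_scores_zero(self):
        assert lls_correlation("tfX", "gX", self.make_table()) == 0.0

    def test_median_magnitude_is_about_one_bit(self):
        # oracle: direct tail count on the magnitude sample
        table = self.make_table()
        mags = np.abs([0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, -0.35, -0.55, 1.0])
        median = np.sort(mags)[5]  # P(x >= v) = 0.5 at this support point
        expected = -math.log2(np.mean(mags >= median))
        assert float(table.magnitude_table.lls(median)) == pytest.approx(expected)

    def test_sub_cutoff_pairs_rejected_at_build(self):
        with pytest.raises(ConfigurationError):
            CorrelationTable.from_records([("a", "b", 0.1, None)])

    def test_bonferroni_filter(self):
        records = [("a", "g1", 0.9, 0.001), ("b", "g2", 0.8, 0.04)]
        table = CorrelationTable.from_records(records, bonferroni_alpha=0.05)
        # corrected p of the second pair is 0.08 > 0.05
        assert table.get("a", "g1") == 0.9
        assert table.get("b", "g2") is None


class TestOverlapAndAdditiveScores:
    def test_metacluster_no_overlap_is_zero(self):
        table = build_tail_table([0, 1, 2, 3], UPPER_TAIL, "m")
        hit = GenomicInterval("g", 0, 5)
        assert lls_metaclusters(hit, np.array([50]), np.array([60]), table) == 0.0

    def test_metacluster_two_of_four_levels(self):
        # oracle: intersection count 2 against equal-mass levels (0,1,2,3)
        table = build_tail_table([0, 1, 2, 3], UPPER_TAIL, "m")
        hit = GenomicInterval("g", 10, 20)
        starts = np.array([5, 15, 50])
        ends = np.array([12, 25, 60])
        assert lls_metaclusters(hit, starts, ends, table) == pytest.approx(1.0)

    def test_metacluster_monotone_in_overlap(self):
        table = build_tail_table([0, 1, 2, 3], UPPER_TAIL, "m")
        hit = GenomicInterval("g", 10, 20)
        scores = []
        for k in (0, 1, 2, 3):
            starts = np.array([12] * k) if k else np.array([])
            ends = np.array([15] * k) if k else np.array([])
            scores.append(lls_metaclusters(hit, starts, ends, table))
        assert scores == sorted(scores)

    def test_atac_term_wise_sum(self):
        # oracle: -log2(0.5) + -log2(0.25) = 3 bits
        table = build_tail_table([0, 0, 1, 1, 2, 2, 3, 3], LOWER_TAIL, "a")
        hit = GenomicInterval("g", 10, 11)
        peaks = [GenomicInterval("g", 11, 12), GenomicInterval("g", 10, 11)]
        assert lls_atac(hit, peaks, table) == pytest.approx(3.0)

    def test_eqtl_overlap_and_additivity(self):
        mags = [0.1, 0.2, 0.3, 0.4]
        table = build_tail_table(mags, UPPER_TAIL, "e")
        hit = GenomicInterval("g", 10, 18)
        none = [GenomicInterval("g", 50, 51, ".", 0.4)]
        assert lls_eqtl(hit, none, table) == 0.0
        one = [GenomicInterval("g", 12, 13, ".", 0.3)]
        two = one + [GenomicInterval("g", 14, 15, ".", -0.4)]
        assert lls_eqtl(hit, two, table) == pytest.approx(
            lls_eqtl(hit, one, table) + float(table.lls(0.4))
        )

    def test_eqtl_median_magnitude_is_one_bit(self):
        table = build_tail_table([0.1, 0.2, 0.3, 0.4], UPPER_TAIL, "e")
        hit = GenomicInterval("g", 10, 18)
        (v,) = [GenomicInterval("g", 12, 13, ".", 0.3)]
        assert lls_eqtl(hit, [v], table) == pytest.approx(1.0)


class TestCpG:
    def test_alternating_cg_ratio(self):
        # oracle: direct dinucleotide count, 4 * 8 / (4 * 4) = 2.0
        assert cpg_ratio("CGCGCGCG", center=4, window=8) == pytest.approx(2.0)

    def test_no_c_gives_zero(self):
        assert cpg_ratio("GGGGAAAA", center=4, window=8) == 0.0

    def test_default_window_is_200(self):
        import inspect

        from promoterscan.empirical_likelihood import DEFAULT_CPG_WINDOW

        assert DEFAULT_CPG_WINDOW == 200
        sig = inspect.signature(cpg_ratio)
        assert sig.parameters["window"].default == 200

    def test_profile_matches_scalar(self):
        rng = np.random.default_rng(14)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        profile = cpg_ratio_profile(seq, window=50)
        for pos in range(0, 300, 7):
            assert profile[pos] == pytest.approx(
                cpg_ratio(seq, pos, window=50), abs=1e-12
            )

    def test_lls_cpg_boundaries(self):
        rng = np.random.default_rng(15)
        genome = {"g": "".join(rng.choice(list("ACGT"), size=2000))}
        table = build_cpg_table(genome, window=200)
        assert lls_cpg(0.0, table) == 0.0  # P(x >= 0) = 1
        top = float(table.support[-1])
        assert lls_cpg(top + 1, table) == pytest.approx(-math.log2(table.eps))

    def test_ratio_at_75th_percentile_scores_two_bits(self):
        # oracle: tail count on a synthetic ratio sample
        ratios = np.arange(1, 101) / 100
        table = build_tail_table(ratios, UPPER_TAIL, "cpg")
        v = 0.77  # P(x >= 0.77) = 24/100... use exact support point
        assert float(table.lls(ratios[74])) == pytest.approx(
            -math.log2(26 / 100)
        )
        assert float(table.lls(ratios[74])) == pytest.approx(2.0, abs=0.1)


class TestConservation:
    def test_hit_inside_element_on_toy_genome(self):
        # oracle: CDF of the brute-force distance vector, P(x <= 0) = 2/10
        table = build_distance_table([GenomicInterval("g", 4, 6)], {"g": 10})
        hit = GenomicInterval("g", 4, 6)
        got = lls_conservation(hit, np.array([4]), np.array([6]), table)
        assert got == pytest.approx(-math.log2(2 / 10))

    def test_maximal_distance_scores_zero_bits(self):
        table = build_distance_table([GenomicInterval("g", 4, 6)], {"g": 10})
        hit = GenomicInterval("g", 0, 1)  # distance 4 = maximum, P = 1
        assert lls_conservation(hit, np.array([4]), np.array([6]), table) == 0.0

    def test_non_increasing_in_distance(self):
        table = build_distance_table([GenomicInterval("g", 40, 60)], {"g": 100})
        starts, ends = np.array([40]), np.array([60])
        scores = [
            lls_conservation(GenomicInterval("g", p, p + 1), starts, ends, table)
            for p in range(0, 40)
        ]
        assert scores == sorted(scores)  # closer positions score higher
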