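"""Monte Carlo engine: p-value formula, BH adjustment, calibration basics,
and the question-level tests (coherence, per-track query, binned, cross-suite)."""

import numpy as np
import pytest

from tracksuite import GenomeDefinition, Track, make_bins
from tracksuite.mc import (
    adjust_p_values,
    classify_multiplicity,
    binned_variation_test,
    cross_suite_test,
    max_q_test,
    mc_p_value,
    monte_carlo_test,
    per_track_query_test,
    query_suite_mean_test,
    suite_coherence_test,
)
from tracksuite.synthetic import (
    SyntheticSuiteSpec,
    generate_query_and_suite,
    generate_suite,
)

from oracles import random_track


class TestPValueFormula:
    def test_observed_exceeds_all_nulls(self):
        assert mc_p_value(99.5, np.arange(99), "greater") == pytest.approx(0.01)

    def test_observed_equal_to_all_nulls(self):
        assert mc_p_value(5.0, np.full(99, 5.0), "greater") == 1.0

    def test_less_alternative(self):
        assert mc_p_value(-1.0, np.arange(99), "less") == pytest.approx(0.01)

    def test_two_sided(self):
        null = np.array([-1.0, 0.0, 1.0])
        assert mc_p_value(2.0, null, "two-sided") == pytest.approx(1 / 4)

    def test_p_times_m_plus_one_is_integer(self, rng):
        null = rng.normal(size=99)
        for obs in rng.normal(size=10):
            p = mc_p_value(obs, null, "greater")
            assert (p * 100) == pytest.approx(round(p * 100))
            assert 0.01 <= p <= 1.0

    def test_data_ignoring_statistic_is_uniform(self):
        """Calibration: statistic independent of the data gives p uniform on
        {1/(m+1), ..., 1} across seeds."""
        m = 19
        ps = []
        for seed in range(400):
            rng = np.random.default_rng(seed)
            obs = rng.normal()
            null = rng.normal(size=m)
            ps.append(mc_p_value(obs, null, "greater"))
        ps = np.array(ps)
        # each of the 20 values should appear ~20 times
        assert abs(ps.mean() - (m + 2) / (2 * (m + 1))) < 0.04
        assert (ps <= 0.05).mean() == pytest.approx(0.05, abs=0.035)


class TestMonteCarloTest:
    def test_reproducibility(self, small_genome, rng):
        tracks = [random_track(rng, small_genome, label=f"t{i}")
                  for i in range(3)]
        r1 = suite_coherence_test(tracks, "jaccard", m=19, seed=5)
        r2 = suite_coherence_test(tracks, "jaccard", m=19, seed=5)
        assert r1.observed == r2.observed
        assert np.array_equal(r1.null_values, r2.null_values)
        assert r1.p_value == r2.p_value

    def test_failed_statistic_aborts_with_diagnostics(self, small_genome, rng):
        def bad_stat(data):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="boom"):
            monte_carlo_test(
                lambda d: 1.0 if d == "obs" else bad_stat(d), "obs",
                sampler=lambda d, rng_: "null", m=5, seed=0)

    def test_m_must_be_positive(self):
        with pytest.raises(ValueError):
            monte_carlo_test(lambda d: 0.0, None,
                             sampler=lambda d, r: d, m=0)


class TestAdjustPValues:
    def test_single_p_unchanged(self):
        assert adjust_p_values([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_bh(self):
        # step-up: (0.01*3/1, 0.02*3/2, 0.03*3/3) -> monotone -> (.03,.03,.03)
        adj = adjust_p_values([0.01, 0.02, 0.03])
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert adjust_p_values([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 1, size=25)
        assert adjust_p_values(p) == pytest.approx(
            multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_p_values([0.0, 0.5])


class TestMultiplicityClassification:
    @pytest.mark.parametrize("stat_scope,sampler_scope,expected", [
        ("single-pair", "per-track", "contrasting"),
        ("across-tracks", "per-track", "integrative"),
        ("single-pair", "across-tracks", "integrative"),
        ("single-pair", "across-suites", "integrative"),
        ("higher-order", "per-track", "higher-order"),
        ("single-track", "per-track", "trivial"),
    ])
    def test_mechanical_derivation(self, stat_scope, sampler_scope, expected):
        assert classify_multiplicity(stat_scope, sampler_scope) == expected


@pytest.fixture(scope="module")
def sim_genome():
    return GenomeDefinition("sim", (("chr1", 20_000),))


class TestPerTrackQueryTest:
    def test_centered_statistics_sum_to_zero(self, sim_genome):
        query, suite, _ = generate_query_and_suite(
            sim_genome, (0.5, 0.0, 0.0), seed=1)
        results = per_track_query_test(query, suite, "forbes", centered=True,
                                       m=9, seed=2)
        assert sum(r.observed for r in results) == pytest.approx(0.0, abs=1e-9)
        null_sums = np.sum([r.null_values for r in results], axis=0)
        assert np.allclose(null_sums, 0.0, atol=1e-9)

    def test_disjoint_query_has_large_p(self, sim_genome):
        # query at the far end of the chromosome, suite at the start
        genome = GenomeDefinition("g", (("chr1", 10_000),))
        query = Track.from_segments(genome, [("chr1", 9000, 9100)], "q")
        suite = [
            Track.from_segments(genome, [("chr1", i * 200, i * 200 + 100)],
                                f"t{i}")
            for i in range(3)
        ]
        results = per_track_query_test(query, suite, "jaccard", m=49, seed=3)
        assert all(r.p_value > 0.5 for r in results)

    def test_planted_association_detected(self, sim_genome):
        hits = 0
        for rep in range(10):
            query, suite, _ = generate_query_and_suite(
                sim_genome, (0.8, 0.0, 0.0), seed=100 + rep)
            results = per_track_query_test(query, suite, "forbes",
                                           m=199, seed=rep)
            if results[0].p_value <= 0.05:
                hits += 1
        assert hits >= 8

    def test_bh_attached(self, sim_genome):
        query, suite, _ = generate_query_and_suite(
            sim_genome, (0.5, 0.0), seed=4)
        results = per_track_query_test(query, suite, "forbes", m=9, seed=5)
        assert all(r.adjusted_p is not None for r in results)


class TestSuiteCoherence:
    def test_identical_tracks_minimal_p(self, sim_genome):
        spec = SyntheticSuiteSpec(
            genome=sim_genome, n_tracks=1, coverage_fractions=(0.2,), seed=6)
        (t,), _ = generate_suite(spec)
        tracks = [t.with_label(f"c{i}") for i in range(3)]
        res = suite_coherence_test(tracks, "jaccard", m=19, seed=7)
        # R = 1 observed; no null sample can exceed it under jaccard
        assert res.observed == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 20)

    def test_shared_signal_suite_rejected(self, sim_genome):
        rejections = 0
        for rep in range(10):
            spec = SyntheticSuiteSpec(
                genome=sim_genome, n_tracks=4,
                coverage_fractions=(0.2,) * 4,
                latent_model="shared-signal", rho=(0.8,) * 4, seed=300 + rep)
            tracks, _ = generate_suite(spec)
            res = suite_coherence_test(tracks, "forbes", m=99, seed=rep)
            if res.p_value <= 0.05:
                rejections += 1
        assert rejections >= 8

    def test_multiplicity_class(self, sim_genome, rng):
        spec = SyntheticSuiteSpec(
            genome=sim_genome, n_tracks=2, coverage_fractions=(0.2, 0.2),
            seed=8)
        tracks, _ = generate_suite(spec)
        res = suite_coherence_test(tracks, "jaccard", m=9, seed=9)
        assert res.multiplicity_class == "integrative"


class TestMaxQTest:
    def test_runs_and_is_reproducible(self, sim_genome):
        spec = SyntheticSuiteSpec(
            genome=sim_genome, n_tracks=3, coverage_fractions=(0.2,) * 3,
            seed=10)
        tracks, _ = generate_suite(spec)
        r1 = max_q_test(tracks, "jaccard", m=19, seed=11)
        r2 = max_q_test(tracks, "jaccard", m=19, seed=11)
        assert r1.p_value == r2.p_value


class TestBinnedVariationTest:
    def test_concentrated_coverage_gives_min_p_in_that_bin(self):
        genome = GenomeDefinition("g", (("chr1", 2000),))
        bins = make_bins(genome, 500)
        # all coverage inside bin 1 ([500,1000)), many small segments
        tracks = [
            Track.from_segments(
                genome, [("chr1", 500 + j * 50 + i, 530 + j * 50 + i)
                         for j in range(8)], f"t{i}")
            for i in range(3)
        ]
        res = binned_variation_test(tracks, bins, mode="occurrence",
                                    m=99, seed=12)
        target = res.per_bin[1]
        assert target.p_value == pytest.approx(1 / 100)
        assert res.suite_result.p_value == pytest.approx(1 / 100)

    def test_cooccurrence_mode_runs(self, sim_genome):
        spec = SyntheticSuiteSpec(
            genome=sim_genome, n_tracks=3, coverage_fractions=(0.2,) * 3,
            seed=13)
        tracks, _ = generate_suite(spec)
        bins = make_bins(sim_genome, 5000)
        res = binned_variation_test(tracks, bins, mode="cooccurrence",
                                    stat="jaccard", m=19, seed=14)
        assert len(res.per_bin) == 4
        assert res.per_bin[0].multiplicity_class == "integrative"

    def test_requires_two_bins(self, sim_genome, rng):
        tracks = [random_track(rng, GenomeDefinition("g", (("chr1", 500),)))
                  for _ in range(2)]
        with pytest.raises(ValueError):
            binned_variation_test(
                tracks, make_bins(GenomeDefinition("g", (("chr1", 500),)),
                                  1000), m=9, seed=0)


class TestCrossSuiteTest:
    def test_normalized_cells_sum_to_zero(self, sim_genome):
        spec = SyntheticSuiteSpec(
            genome=sim_genome, n_tracks=6, coverage_fractions=(0.2,) * 6,
            seed=15)
        tracks, _ = generate_suite(spec)
        res = cross_suite_test(tracks[:3], tracks[3:], "forbes",
                               m=19, seed=16)
        assert abs(res.observed_normalized.sum()) < 1e-9

    def test_planted_pair_attains_min_cell_p(self, sim_genome):
        hits = 0
        for rep in range(10):
            spec = SyntheticSuiteSpec(
                genome=sim_genome, n_tracks=6,
                coverage_fractions=(0.2,) * 6,
                latent_model="planted-pair", planted_pair=(0, 3),
                planted_rho=0.9, seed=500 + rep)
            tracks, _ = generate_suite(spec)
            res = cross_suite_test(tracks[:3], tracks[3:], "forbes",
                                   m=99, seed=rep)
            # planted pair is (suite1 track 0, suite2 track 0)
            if res.cell_p[0, 0] == res.cell_p.min():
                hits += 1
        assert hits >= 8

    def test_suite_pair_statistic_and_seeds(self, sim_genome):
        spec = SyntheticSuiteSpec(
            genome=sim_genome, n_tracks=4, coverage_fractions=(0.2,) * 4,
            seed=17)
        tracks, _ = generate_suite(spec)
        r1 = cross_suite_test(tracks[:2], tracks[2:], "jaccard", m=19, seed=18)
        r2 = cross_suite_test(tracks[:2], tracks[2:], "jaccard", m=19, seed=18)
        assert r1.suite_pair_result.p_value == r2.suite_pair_result.p_value
        assert np.array_equal(r1.cell_p, r2.cell_p)


class TestQuerySuiteMean:
    def test_runs(self, sim_genome):
        query, suite, _ = generate_query_and_suite(
            sim_genome, (0.6, 0.3), seed=19)
        res = query_suite_mean_test(query, suite, "forbes", m=19, seed=20)
        assert res.multiplicity_class == "integrative"
        assert 0 < res.p_value <= 1
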