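import itertools
import math

import numpy as np
import pytest

from polydose.inference import (
    DPMemoryError,
    NaiveSizeError,
    approximate_posterior,
    best_config_for_distribution,
    counts_of,
    dp_map,
    fit,
    geometric_map,
    greedy_fit,
    individual_posteriors,
    log_joint,
    log_multinomial,
    naive_map,
    tau_from_epsilon,
    SearchSettings,
    _safe_logF,
)
from polydose.likelihood_model import build_table
from polydose.population_models import F1Params, HWParams, hw_frequencies

from conftest import (
    contiguous_up_to_ties,
    dataset_from_coords,
    is_contiguous,
    random_instance,
)


class TestLogJoint:
    def test_degenerate_frequency_gives_zero_multinomial(self):
        F = np.array([1.0, 0.0, 0.0])
        assert log_multinomial(np.array([5, 0, 0]), _safe_logF(F)) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "counts,expected",
        [([1, 1], 0.5), ([2, 0], 0.25)],
    )
    def test_two_class_multinomial(self, counts, expected):
        F = np.array([0.5, 0.5])
        val = log_multinomial(np.array(counts), _safe_logF(F))
        assert val == pytest.approx(math.log(expected))

    def test_excluded_configuration_is_minus_inf(self):
        F = np.array([0.5, 0.5, 0.0])
        assert log_multinomial(np.array([1, 0, 1]), _safe_logF(F)) == -np.inf

    def test_log_joint_sums_terms(self):
        F = np.array([0.5, 0.5])
        val = log_joint(np.array([1, 1]), -3.0, F, prior_terms=-1.0)
        assert val == pytest.approx(math.log(0.5) - 3.0 - 1.0)


class TestGreedy:
    def test_single_point_nearest_angle(self):
        table = build_table(dataset_from_coords([0.02]), 2, 0.1)
        res = greedy_fit(table, hw_frequencies(2, 0.5))
        assert res.assignment.tolist() == [0]

    def test_equals_naive_under_uniform_frequencies(self):
        # individuals exactly at angles: likelihood dominates, multinomial flat
        table = build_table(dataset_from_coords([0.0, 0.5, 0.5, 1.0]), 2, 0.1)
        F = np.full(3, 1 / 3)
        g = greedy_fit(table, F)
        nv = naive_map(table, F)
        assert g.log_joint == pytest.approx(nv.log_joint, abs=1e-9)

    def test_multinomial_coupling_beats_greedy(self):
        # all points midway: greedy piles everyone on the central dosage, but
        # the joint model prefers spreading because a concentrated count
        # vector with small F_1 has tiny multinomial probability
        table = build_table(dataset_from_coords([0.5] * 4), 2, 0.5)
        F = np.array([0.45, 0.1, 0.45])
        g = greedy_fit(table, F)
        nv = naive_map(table, F)
        assert g.assignment.tolist() == [1, 1, 1, 1]
        assert nv.assignment.tolist() != [1, 1, 1, 1]
        assert nv.log_joint > g.log_joint


class TestNaive:
    def test_single_individual_equals_greedy(self):
        table = build_table(dataset_from_coords([0.7]), 4, 0.1)
        F = hw_frequencies(4, 0.4)
        assert naive_map(table, F).log_joint == pytest.approx(
            greedy_fit(table, F).log_joint
        )

    def test_zero_frequency_dosage_never_used(self):
        table = build_table(dataset_from_coords([0.1, 0.6, 0.9]), 2, 0.3)
        F = np.array([0.5, 0.5, 0.0])
        res = naive_map(table, F)
        assert 2 not in res.assignment

    def test_guard_refuses_large_instances(self):
        table = build_table(dataset_from_coords(np.linspace(0.1, 0.9, 30)), 4, 0.1)
        with pytest.raises(NaiveSizeError):
            naive_map(table, hw_frequencies(4, 0.5))


class TestBestConfigForDistribution:
    def test_concentrated_counts(self):
        table = build_table(dataset_from_coords([0.2, 0.4, 0.6]), 2, 0.2)
        assignment, _ = best_config_for_distribution(table, np.array([0, 3, 0]))
        assert assignment.tolist() == [1, 1, 1]

    def test_blocks_follow_sorted_order(self):
        table = build_table(dataset_from_coords([0.05, 0.45, 0.55, 0.95]), 2, 0.1)
        assignment, _ = best_config_for_distribution(table, np.array([1, 2, 1]))
        assert assignment.tolist() == [0, 1, 1, 2]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_optimal_among_all_placements(self, seed):
        # brute force over every assignment with the same counts
        rng = np.random.default_rng(seed)
        coords = np.sort(rng.uniform(0, 1, 6))
        table = build_table(dataset_from_coords(coords), 2, 0.15)
        counts = np.array([2, 2, 2])
        _, best_ll = best_config_for_distribution(table, counts)
        labels = [g for g in range(3) for _ in range(counts[g])]
        for perm in set(itertools.permutations(labels)):
            ll = sum(table.logL[i, g] for i, g in enumerate(perm))
            assert ll <= best_ll + 1e-9


class TestEngineEquivalence:
    @pytest.mark.parametrize("trial", range(40))
    def test_geometric_and_dp_match_naive(self, trial):
        rng = np.random.default_rng(5000 + trial)
        n = int(rng.integers(5, 9))
        m = int(rng.choice([2, 4]))
        kind = "hw" if trial % 2 == 0 else "f1"
        table, F = random_instance(5000 + trial, n, m, kind)
        nv = naive_map(table, F)
        greedy = greedy_fit(table, F)
        geo = geometric_map(
            table, F, incumbent=greedy.log_joint, incumbent_assignment=greedy.assignment
        )
        dp, peak = dp_map(table, F)
        assert geo.log_joint == pytest.approx(nv.log_joint, abs=1e-9)
        assert dp.log_joint == pytest.approx(nv.log_joint, abs=1e-9)
        # MAP can only improve on greedy, and the optimum is contiguous
        assert geo.log_joint >= greedy.log_joint - 1e-12
        assert is_contiguous(geo.assignment)
        assert contiguous_up_to_ties(table, nv.assignment)

    @pytest.mark.parametrize("trial", range(10))
    def test_incumbent_independence(self, trial):
        table, F = random_instance(6000 + trial, 7, 4, "hw")
        greedy = greedy_fit(table, F)
        cold = geometric_map(table, F)
        warm = geometric_map(
            table, F, incumbent=greedy.log_joint, incumbent_assignment=greedy.assignment
        )
        assert cold.log_joint == pytest.approx(warm.log_joint, abs=1e-12)
        # pruning with an incumbent can only shrink the search
        assert warm.visited_nodes <= cold.visited_nodes

    def test_visited_nodes_bounded_by_distribution_count(self):
        n, m = 7, 2
        table, F = random_instance(42, n, m, "hw")
        res = geometric_map(table, F)
        assert res.visited_nodes <= math.comb(n + m, m) + 1


class TestDP:
    def test_memory_guard_aborts_with_diagnostic(self):
        table = build_table(dataset_from_coords(np.linspace(0.01, 0.99, 60)), 6, 0.3)
        F = hw_frequencies(6, 0.5)
        with pytest.raises(DPMemoryError, match="nodes"):
            dp_map(table, F, max_layer_nodes=500)

    def test_peak_layer_reported(self):
        table, F = random_instance(3, 6, 2, "hw")
        _, peak = dp_map(table, F)
        assert 1 <= peak <= math.comb(6 + 2, 2)


class TestPosteriorApproximation:
    def test_tau_values(self):
        assert tau_from_epsilon(0.01, 101) == pytest.approx(1e-4)
        assert tau_from_epsilon(0.01, 1) == pytest.approx(0.01)

    def test_single_setting_posterior_one(self):
        assert approximate_posterior({"a": -5.0}, "a") == pytest.approx(1.0)

    def test_equal_settings_split(self):
        scores = {"a": -2.0, "b": -2.0}
        assert approximate_posterior(scores, "a") == pytest.approx(0.5)

    def test_three_setting_ratio(self):
        scores = {"a": 0.0, "b": -math.log(2), "c": -math.log(2)}
        assert approximate_posterior(scores, "a") == pytest.approx(0.5)


class TestIndividualPosteriors:
    def test_rows_normalize(self):
        table, _ = random_instance(7, 8, 4, "hw")
        posts = individual_posteriors(table)
        for vec in posts.values():
            assert vec.sum() == pytest.approx(1.0)

    def test_point_at_angle_with_small_sigma_is_certain(self):
        table = build_table(dataset_from_coords([0.25]), 4, 0.01)
        posts = individual_posteriors(table)
        assert posts["i000"][1] == pytest.approx(1.0, abs=1e-12)

    def test_midpoint_symmetry(self):
        table = build_table(dataset_from_coords([0.5]), 2, 0.2)
        posts = individual_posteriors(table)
        assert posts["i000"][0] == pytest.approx(posts["i000"][2])


class TestFit:
    def test_recovers_tetraploid_hw(self, hw_locus_m4):
        ds, truth = hw_locus_m4
        res = fit(ds, SearchSettings(ploidy_range=(2, 4, 6)), model="hw")
        assert res.m == 4
        acc = np.mean([res.assignment[i] == g for i, g in truth.genotypes.items()])
        assert acc >= 0.99
        assert 0.0 <= res.config_posterior <= 1.0
        # the reported distribution is the count image of the configuration
        called = np.array([res.assignment[i] for i in ds.individuals])
        np.testing.assert_array_equal(counts_of(called, 4), res.distribution)

    def test_single_cluster_degenerates_to_lowest_ploidy(self):
        # every individual exactly midway: any even ploidy explains the data
        # equally well, so the ploidy tie breaks low
        ds = dataset_from_coords([0.5] * 12)
        res = fit(
            ds,
            SearchSettings(ploidy_range=(2, 4), sigma_grid=(0.05, 0.1)),
            model="hw",
        )
        assert res.m == 2

    def test_f1_odd_ploidy_rejected(self):
        ds = dataset_from_coords([0.1, 0.5, 0.9])
        with pytest.raises(ValueError):
            fit(ds, SearchSettings(ploidy_range=(3,)), model="f1")

    def test_engines_agree_end_to_end(self):
        ds = dataset_from_coords([0.03, 0.27, 0.48, 0.52, 0.77, 0.98])
        settings = dict(ploidy_range=(2, 4), sigma_grid=(0.05, 0.1), p_resolution=0.1)
        joints = {}
        for engine in ("geometric", "dp", "naive"):
            res = fit(ds, SearchSettings(engine=engine, **settings), model="hw")
            joints[engine] = res.log_joint
        assert joints["geometric"] == pytest.approx(joints["naive"], abs=1e-9)
        assert joints["dp"] == pytest.approx(joints["naive"], abs=1e-9)
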