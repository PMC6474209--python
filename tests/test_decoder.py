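"""The decoding machinery: kernels, bootstrap, features, kNN, full loop."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from tactile_decoding.decoder import (BootstrapError, DecoderParams,
                                      bootstrap_combine, decode_neuron,
                                      derive_windows, featurize,
                                      knn_classify, normalize_per_window,
                                      shuffle_assignment, shuffled_control,
                                      sweep_to_signal, time_window_evolution)
from tactile_decoding.segmentation import CompoundDensity, segment_windows
from tactile_decoding.synthetic import (NeuronModelSpec, generate_sweeps,
                                        make_schedule)


class TestSweepToSignal:
    def test_exponential_decay_by_one_tau(self):
        grid = np.arange(0.0, 101.0)
        s = sweep_to_signal([0.0], 5.0, grid)
        assert s[5] == pytest.approx(s[0] * np.exp(-1.0))

    def test_linearity_for_coincident_spikes(self):
        grid = np.arange(0.0, 101.0)
        one = sweep_to_signal([30.0], 5.0, grid)
        two = sweep_to_signal([30.0, 30.0], 5.0, grid)
        np.testing.assert_allclose(two, 2 * one)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(21)
        grid = np.arange(0.0, 301.0)
        for _ in range(20):
            spikes = np.sort(rng.uniform(-20, 290, rng.integers(1, 40)))
            got = sweep_to_signal(spikes, 5.0, grid)
            expected = np.zeros(grid.size)
            for i, t in enumerate(grid):
                for ts in spikes:
                    if t >= ts:
                        expected[i] += math.exp(-(t - ts) / 5.0)
            np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_empty_sweep_is_zero(self):
        grid = np.arange(0.0, 50.0)
        assert np.all(sweep_to_signal([], 5.0, grid) == 0)


class TestBootstrap:
    def _signals(self, n, rng):
        return rng.random((n, 40)) + 0.1

    def test_exhaustive_when_few_combinations(self):
        rng = np.random.default_rng(1)
        combined = bootstrap_combine(self._signals(12, rng), 10, 200, rng)
        assert combined.shape[0] == math.comb(12, 10)   # 66

    def test_failure_below_group_size(self):
        rng = np.random.default_rng(2)
        with pytest.raises(BootstrapError):
            bootstrap_combine(self._signals(9, rng), 10, 200, rng)

    def test_empty_sweeps_excluded(self):
        rng = np.random.default_rng(3)
        sig = self._signals(12, rng)
        sig[3] = 0.0
        sig[7] = 0.0
        with pytest.raises(BootstrapError):
            bootstrap_combine(sig, 11, 200, rng)
        combined, idx = bootstrap_combine(sig, 10, 200, rng,
                                          return_indices=True)
        assert 3 not in idx and 7 not in idx

    def test_every_sweep_covered_and_subsets_distinct(self):
        rng = np.random.default_rng(4)
        for n, target in [(30, 200), (25, 40), (40, 100)]:
            _, idx = bootstrap_combine(self._signals(n, rng), 10, target,
                                       rng, return_indices=True)
            assert idx.shape == (target, 10)
            assert len({tuple(r) for r in idx.tolist()}) == target
            assert set(np.unique(idx)) == set(range(n))

    def test_combination_is_sum_of_members(self):
        rng = np.random.default_rng(5)
        sig = self._signals(15, rng)
        combined, idx = bootstrap_combine(sig, 10, 50, rng,
                                          return_indices=True)
        np.testing.assert_allclose(combined[0], sig[idx[0]].sum(axis=0))


class TestFeaturize:
    def _windows(self):
        grid = np.arange(0.0, 301.0)
        v = np.exp(-0.5 * ((grid - 80) / 20) ** 2) \
            + np.exp(-0.5 * ((grid - 220) / 20) ** 2)
        return segment_windows(CompoundDensity(grid, v)), grid

    def test_zero_signal_all_zero_feature(self):
        w, grid = self._windows()
        f = featurize(np.zeros(grid.size), w, grid)
        assert f.shape == (w.n_kept,) and np.all(f == 0)

    def test_dominant_response_normalizes_to_ones(self):
        w, grid = self._windows()
        rng = np.random.default_rng(6)
        sigs = rng.random((10, grid.size))
        sigs[4] = 10.0 + rng.random(grid.size)
        feats = normalize_per_window(featurize(sigs, w, grid))
        np.testing.assert_allclose(feats[4], 1.0)
        assert np.all(feats <= 1.0 + 1e-12) and np.all(feats >= 0)

    def test_quadrature_matches_rectangle_oracle(self):
        w, grid = self._windows()
        rng = np.random.default_rng(7)
        for _ in range(20):
            spikes = np.sort(rng.uniform(0, 300, 400))
            sig = sweep_to_signal(spikes, 5.0, grid)
            f = featurize(sig, w, grid)
            # independent quadrature: mean of the left and right rectangle
            # sums over each window at 1 ms resolution
            rect = np.array([
                0.5 * (sig[int(lo):int(hi)].sum()
                       + sig[int(lo) + 1:int(hi) + 1].sum())
                for lo, hi in w.kept_windows()])
            np.testing.assert_allclose(f, rect, rtol=5e-3)


class TestKnn:
    def test_unanimous_neighbours(self):
        rng = np.random.default_rng(8)
        train = np.vstack([rng.normal(0, 0.1, (9, 3)),
                           rng.normal(5, 0.1, (9, 3))])
        labels = ["A"] * 9 + ["B"] * 9
        assert knn_classify(np.zeros(3), train, labels, k=9) == "A"

    def test_matches_brute_force_sort_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            train = rng.random((60, 4))
            labels = [f"L{i % 5}" for i in range(60)]
            q = rng.random(4)
            got = knn_classify(q, train, labels, k=9)
            d = np.sqrt(((train - q) ** 2).sum(axis=1))
            order = np.argsort(d, kind="stable")[:9]
            votes = {}
            for i in order:
                votes[labels[i]] = votes.get(labels[i], 0) + 1
            top = max(votes.values())
            winners = [lab for lab, c in votes.items() if c == top]
            expected = winners[0] if len(winners) == 1 else labels[order[0]]
            assert got == expected

    def test_tie_broken_by_single_nearest_neighbour(self):
        # 4-4-1 vote split between A and C: the overall nearest neighbour
        # is the lone B, and its label wins the tie.
        train = np.array([[0.1], [1.0], [1.1], [1.2], [1.3],
                          [2.0], [2.1], [2.2], [2.3]])
        labels = ["B", "A", "A", "A", "A", "C", "C", "C", "C"]
        assert knn_classify(np.array([0.0]), train, labels, k=9) == "B"

    def test_requires_enough_training_points(self):
        with pytest.raises(ValueError):
            knn_classify(np.zeros(2), np.zeros((5, 2)), ["A"] * 5, k=9)


class TestShuffling:
    def test_assignment_is_uniform(self):
        # Chi-square on how often trial ("A", 0) lands in each class.
        rng = np.random.default_rng(10)
        n_trials = {"A": 10, "B": 10, "C": 10, "D": 10}
        counts = {lab: 0 for lab in n_trials}
        reps = 4000
        for _ in range(reps):
            assignment = shuffle_assignment(n_trials, rng)
            for lab, items in assignment.items():
                if ("A", 0) in items:
                    counts[lab] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 1e-3

    def test_counts_preserved(self):
        rng = np.random.default_rng(11)
        n_trials = {"A": 7, "B": 13}
        a = shuffle_assignment(n_trials, rng)
        assert len(a["A"]) == 7 and len(a["B"]) == 13
        assert sorted(a["A"] + a["B"]) == sorted(
            (lab, i) for lab, n in n_trials.items() for i in range(n))


class TestDecodeNeuron:
    def test_separable_neuron_decodes_above_90(self):
        # Fully reliable neuron with three distinct response bumps per
        # pattern, decoded at the standard group size of 10.
        from tactile_decoding.synthetic import make_cohort_specs
        labels = [f"P{i}" for i in range(1, 9)]
        spec = make_cohort_specs(1, labels, seed=42, reliability=1.0)[0]
        sched = make_schedule(labels, repetitions_per_pattern=40, seed=1)
        ss = generate_sweeps(spec, sched, seed=7)
        w = derive_windows(ss)
        params = DecoderParams(n_iterations=8, seed=3)
        res = decode_neuron(ss, w, params)
        assert res.mean_decoding_performance > 90.0

    def test_identical_statistics_sit_at_chance(self, flat_sweepset,
                                                small_params):
        w = derive_windows(flat_sweepset)
        res = decode_neuron(flat_sweepset, w, small_params)
        sd = np.std(res.per_iteration_performance)
        assert abs(res.mean_decoding_performance - 12.5) < 3 * max(sd, 1.0)

    def test_confusion_rows_sum_to_100(self, selective_sweepset,
                                       selective_windows, small_params):
        res = decode_neuron(selective_sweepset, selective_windows,
                            small_params)
        np.testing.assert_allclose(
            res.mean_confusion.percentages.sum(axis=1), 100.0, atol=0.01)
        assert 0.0 <= res.mean_decoding_performance <= 100.0

    def test_deterministic_given_seed(self, selective_sweepset,
                                      selective_windows, small_params):
        a = decode_neuron(selective_sweepset, selective_windows, small_params)
        b = decode_neuron(selective_sweepset, selective_windows, small_params)
        np.testing.assert_array_equal(a.mean_confusion.percentages,
                                      b.mean_confusion.percentages)


class TestShuffledControl:
    def test_two_pattern_control_near_50(self, small_params):
        resp = {"A": [(50.0, 70.0, 6.0)], "B": [(200.0, 70.0, 6.0)]}
        spec = NeuronModelSpec(5.0, resp, 0.9)
        sched = make_schedule(["A", "B"], repetitions_per_pattern=30, seed=2)
        ss = generate_sweeps(spec, sched, seed=22)
        w = derive_windows(ss)
        res = shuffled_control(ss, w, small_params)
        assert res.shuffled
        sd = np.std(res.per_iteration_performance)
        assert abs(res.mean_decoding_performance - 50.0) < 3 * max(sd, 2.0)

    def test_selective_neuron_shuffles_to_chance(self, selective_sweepset,
                                                 selective_windows,
                                                 small_params):
        res = shuffled_control(selective_sweepset, selective_windows,
                               small_params)
        sd = np.std(res.per_iteration_performance)
        assert abs(res.mean_decoding_performance - 12.5) < 3 * max(sd, 1.0)


class TestTimeWindowEvolution:
    def test_late_discriminative_peak(self):
        labels = [f"P{i}" for i in range(1, 9)]
        resp = {lab: [(230.0 + 12.0 * i, 80.0, 5.0)]
                for i, lab in enumerate(labels)}
        spec = NeuronModelSpec(10.0, resp, 1.0)
        sched = make_schedule(labels, repetitions_per_pattern=40, seed=0)
        ss = generate_sweeps(spec, sched, seed=2)
        params = DecoderParams(group_size=5, target_combinations=50,
                               n_iterations=8, seed=9)
        evo = time_window_evolution(ss, params,
                                    durations=[100, 200, 400, 600])
        assert len(evo) == 4
        assert evo[100].mean_decoding_performance < 30.0
        assert evo[200].mean_decoding_performance < 30.0
        assert evo[400].mean_decoding_performance > 45.0

    def test_monotone_in_pattern_separation(self):
        # Increasing bump separation across patterns never decreases the
        # median decoding over seeds.
        medians = []
        for sep in (0.0, 8.0, 40.0):
            perfs = []
            for seed in range(5):
                labels = [f"P{i}" for i in range(1, 9)]
                resp = {lab: [(100.0 + sep * i, 60.0, 8.0)]
                        for i, lab in enumerate(labels)}
                spec = NeuronModelSpec(5.0, resp, 0.9)
                sched = make_schedule(labels, repetitions_per_pattern=20,
                                      seed=seed)
                ss = generate_sweeps(spec, sched, seed=1000 + seed)
                w = derive_windows(ss)
                if w.n_kept == 0:
                    perfs.append(12.5)
                    continue
                p = DecoderParams(group_size=5, target_combinations=40,
                                  n_iterations=4, seed=seed)
                perfs.append(decode_neuron(ss, w, p)
                             .mean_decoding_performance)
            medians.append(np.median(perfs))
        assert medians[0] <= medians[1] <= medians[2]
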