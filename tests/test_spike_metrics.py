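"""PSTH arithmetic, latency/intensity rules and the KDE machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from tactile_decoding.spike_metrics import (DegenerateBaselineError,
                                            bandwidth_cost, compute_kde,
                                            compute_psth, optimal_bandwidth,
                                            response_intensity,
                                            response_latency)


class TestPsth:
    def test_single_bin_rate_arithmetic(self):
        # 10 sweeps with exactly one spike each in [0, 5) ms:
        # 10 spikes / (10 sweeps * 5 ms) = 200 Hz.
        sweeps = [np.array([2.5])] * 10
        p = compute_psth(sweeps, bin_size=5.0, pre_span=500, post_span=500)
        i = np.flatnonzero(p.bin_edges[:-1] == 0.0)[0]
        assert p.rates[i] == pytest.approx(200.0)

    def test_empty_sweeps_zero_everything(self):
        p = compute_psth([np.empty(0)] * 5)
        assert np.all(p.rates == 0)
        assert p.baseline_mean == 0 and p.baseline_sd == 0

    def test_homogeneous_poisson_baseline(self):
        rng = np.random.default_rng(4)
        sweeps = [np.sort(rng.uniform(-500, 500, rng.poisson(20)))
                  for _ in range(200)]
        p = compute_psth(sweeps)
        # 20 spikes over 1 s -> 20 Hz
        n_pre = int(np.sum(p.bin_edges[:-1] < 0))
        se = p.baseline_sd / np.sqrt(n_pre)
        assert abs(p.baseline_mean - 20.0) < 3 * se + 0.5

    def test_rejects_empty_input(self):
        with pytest.raises(ValueError):
            compute_psth([])


def _psth_with_rates(pre, post, bin_size=5.0):
    from tactile_decoding.spike_metrics import Psth
    rates = np.concatenate([pre, post])
    edges = (np.arange(rates.size + 1) - len(pre)) * bin_size
    return Psth(bin_size, edges, rates, float(np.mean(pre)),
                float(np.std(pre)), n_sweeps=10)


class TestLatencyAndIntensity:
    def test_two_consecutive_bins_define_latency(self):
        pre = np.array([10.0, 10, 12, 8, 10, 10, 12, 8, 10, 10])
        post = np.full(20, 10.0)
        thr = np.mean(pre) + 4 * np.std(pre)
        post[3] = thr    # bins starting at 15 and 20 ms
        post[4] = thr
        psth = _psth_with_rates(pre, post)
        assert response_latency(psth) == pytest.approx(15.0)

    def test_single_isolated_bin_is_not_a_response(self):
        pre = np.array([10.0, 10, 12, 8, 10, 10, 12, 8, 10, 10])
        post = np.full(20, 10.0)
        post[3] = 100.0
        assert response_latency(_psth_with_rates(pre, post)) is None

    def test_flat_psth_has_no_latency(self):
        pre = np.array([10.0, 12, 8, 10, 10, 12])
        post = np.full(20, 10.0)
        assert response_latency(_psth_with_rates(pre, post)) is None

    def test_latency_matches_brute_force_scan(self):
        # Order-2 run detection against an exhaustive scan on random PSTHs.
        rng = np.random.default_rng(8)
        for _ in range(50):
            pre = rng.uniform(5, 15, 10)
            post = rng.uniform(5, 40, 30)
            psth = _psth_with_rates(pre, post)
            thr = psth.baseline_mean + 3 * psth.baseline_sd
            expected = None
            for i in range(post.size - 1):
                if post[i] > thr and post[i + 1] > thr:
                    expected = i * 5.0
                    break
            assert response_latency(psth) == (
                pytest.approx(expected) if expected is not None else None)

    def test_intensity_arithmetic(self):
        pre = np.array([10.0, 14, 6, 10, 10, 14, 6, 10])
        post = np.full(20, 10.0)
        post[2], post[3], post[7] = 25.0, 25.0, 30.0
        psth = _psth_with_rates(pre, post)
        sd = float(np.std(pre))
        lat = response_latency(psth)
        assert response_intensity(psth, lat) == pytest.approx(20.0 / sd)

    def test_peak_at_baseline_gives_zero(self):
        pre = np.array([10.0, 14, 6, 10, 10, 14, 6, 10])
        post = np.full(20, 10.0)
        assert response_intensity(_psth_with_rates(pre, post), 0.0) == 0.0

    def test_zero_baseline_sd_signals_degenerate(self):
        pre = np.full(8, 10.0)
        post = np.full(20, 12.0)
        with pytest.raises(DegenerateBaselineError):
            response_intensity(_psth_with_rates(pre, post), 0.0)


class TestBandwidth:
    def test_minimizer_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        grid = np.arange(0.5, 40.0, 0.1)
        for _ in range(5):
            x = np.sort(rng.normal(100, 8, 60))
            w = optimal_bandwidth(x, candidates=grid)
            costs = [bandwidth_cost(x, c) for c in grid]
            assert w == pytest.approx(grid[int(np.argmin(costs))])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(13)
        x = np.sort(rng.normal(50, 4, 80))
        w1 = optimal_bandwidth(x)
        w2 = optimal_bandwidth(3.0 * x)
        # log-grid resolution is ~11%, allow two grid steps
        assert w2 / w1 == pytest.approx(3.0, rel=0.25)

    def test_two_far_clusters_get_narrow_kernel(self):
        rng = np.random.default_rng(14)
        x = np.concatenate([rng.normal(50, 3, 50), rng.normal(250, 3, 50)])
        assert optimal_bandwidth(np.sort(x)) < 40.0

    def test_requires_two_spikes(self):
        with pytest.raises(ValueError):
            optimal_bandwidth([5.0])


class TestKde:
    def test_single_spike_peaks_at_spike_time(self):
        k = compute_kde([np.array([100.0])])
        assert k.time_grid[np.argmax(k.values)] == pytest.approx(100.0)

    def test_pointwise_gaussian_sum_oracle(self):
        rng = np.random.default_rng(15)
        sweeps = [np.sort(rng.uniform(0, 400, 20)) for _ in range(5)]
        k = compute_kde(sweeps)
        pooled = np.concatenate(sweeps)
        inside = k.time_grid[(k.time_grid >= 0) & (k.time_grid <= 400)]
        pts = rng.choice(inside, 20, replace=False)
        for t in pts:
            expected = norm.pdf(t, loc=pooled, scale=k.bandwidth).sum() \
                * 1000.0 / len(sweeps)
            got = k.values[np.flatnonzero(k.time_grid == t)[0]]
            assert got == pytest.approx(expected, rel=1e-3)

    def test_zero_spikes_flagged_flat(self):
        k = compute_kde([np.empty(0)] * 3)
        assert k.is_empty and np.all(k.values == 0)

    def test_kde_tracks_psth_on_smooth_bump_data(self):
        # Deterministic quantile-sampled sweeps from two Gaussian bumps:
        # the peak-normalized KDE and 5 ms PSTH must agree closely.
        n = 200
        q = (np.arange(n) + 0.5) / n
        sweeps = [np.sort(np.array([norm.ppf(qi, 150, 20),
                                    norm.ppf(qj, 350, 25)]))
                  for qi, qj in zip(q, q[::-1])]
        k = compute_kde(sweeps)
        p = compute_psth(sweeps, bin_size=5.0, pre_span=500, post_span=500)
        sel = p.bin_edges[:-1] >= 0
        kde_binned = []
        for a, b in zip(p.bin_edges[:-1][sel], p.bin_edges[1:][sel]):
            m = (k.time_grid >= a) & (k.time_grid < b)
            kde_binned.append(k.values[m].mean())
        kde_binned = np.asarray(kde_binned)
        pv = p.rates[sel]
        dev = np.abs(kde_binned / kde_binned.max() - pv / pv.max())
        assert dev.max() < 0.15

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_kde_nonnegative_on_random_sweeps(self, seed):
        rng = np.random.default_rng(seed)
        sweeps = [np.sort(rng.uniform(-200, 800, rng.integers(0, 30)))
                  for _ in range(rng.integers(1, 6))]
        k = compute_kde(sweeps, bandwidth=float(rng.uniform(1, 50)))
        assert np.all(k.values >= 0)
        assert k.time_grid.size == 1501
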