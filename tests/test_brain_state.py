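"""ECoG state segmentation, presentation classification and
state-conditioned decoding."""

import numpy as np
import pytest

from tactile_decoding.brain_state import (StateSegmentation,
                                          classify_stimulus_state,
                                          segment_states,
                                          state_conditioned_decoding)
from tactile_decoding.decoder import DecoderParams, derive_windows
from tactile_decoding.spike_metrics import SweepSet
from tactile_decoding.synthetic import (ContinuousTrace, NeuronModelSpec,
                                        generate_ecog_trace, generate_sweeps,
                                        make_schedule)

LABELS = [f"P{i}" for i in range(1, 9)]


def _alternating_schedule(total_ms, epoch_ms=5000.0):
    out, cur, state = [], 0.0, "synchronized"
    while cur < total_ms:
        out.append((cur, min(cur + epoch_ms, total_ms), state))
        state = ("desynchronized" if state == "synchronized"
                 else "synchronized")
        cur += epoch_ms
    return out


def _desync_mask(intervals, grid):
    m = np.zeros(grid.size, bool)
    for a, b, s in intervals:
        if s == "desynchronized":
            m |= (grid >= a) & (grid < b)
    return m


class TestSegmentation:
    def test_label_recovery_jaccard(self):
        sched = _alternating_schedule(80_000.0)
        tr = generate_ecog_trace(80_000.0, sched, seed=11)
        seg = segment_states(tr)
        grid = np.arange(0.0, 80_000.0, 10.0)
        true_m = _desync_mask(sched, grid)
        est_m = _desync_mask(seg.state_intervals, grid)
        jaccard = (true_m & est_m).sum() / (true_m | est_m).sum()
        assert jaccard > 0.8

    def test_single_below_median_segment_stays_synchronized(self):
        # A trace engineered so exactly one analysis segment has low power:
        # the >= 2-segment run rule must keep it synchronized.
        fs = 1000.0
        n_seg = 9
        hop = 875
        n = hop * (n_seg - 1) + 1000
        t = np.arange(n) / fs
        amp = np.full(n, 50.0)
        # one low-power dip inside the part of segment 4 that no other
        # (overlapping) segment sees
        lo = 4 * hop + 200
        amp[lo:lo + 600] = 1.0
        x = amp * np.sin(2 * np.pi * 3.0 * t)
        seg = segment_states(ContinuousTrace(fs, 0.0, x))
        assert all(s == "synchronized" for _, _, s in seg.state_intervals)

    def test_contiguous_low_block_is_desynchronized(self):
        fs = 1000.0
        hop = 875
        n_seg = 8
        n = hop * (n_seg - 1) + 1000
        t = np.arange(n) / fs
        amp = np.full(n, 50.0)
        amp[:4 * hop] = 1.0          # first half low power
        x = amp * np.sin(2 * np.pi * 3.0 * t) \
            + np.random.default_rng(0).normal(0, 0.5, n)
        seg = segment_states(ContinuousTrace(fs, 0.0, x))
        states = [s for _, _, s in seg.state_intervals]
        assert states[0] == "desynchronized"
        assert seg.desynchronized_intervals()[0][0] == 0.0

    def test_constant_zero_trace_has_no_desync(self):
        tr = ContinuousTrace(1000.0, 0.0, np.zeros(10_000))
        seg = segment_states(tr)
        assert seg.desynchronized_intervals() == []

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            segment_states(ContinuousTrace(1000.0, 0.0, np.zeros(1200)))

    def test_amplitude_rescaling_invariance(self):
        sched = _alternating_schedule(40_000.0)
        tr = generate_ecog_trace(40_000.0, sched, seed=3)
        seg1 = segment_states(tr)
        seg2 = segment_states(ContinuousTrace(
            tr.sampling_rate, tr.start_time, 10.0 * tr.values))
        assert seg1.state_intervals == seg2.state_intervals


class TestStimulusClassification:
    def _seg(self):
        return StateSegmentation(
            segment_starts=np.arange(0, 10_000, 875.0),
            segment_ms=1000.0, hop_ms=875.0,
            compound_power=np.zeros(12), median_power=0.0,
            state_intervals=[
                (0.0, 3000.0, "synchronized"),
                (3000.0, 7000.0, "desynchronized"),
                (7000.0, 10_000.0, "synchronized"),
            ])

    def test_onset_too_close_to_epoch_end_is_synchronized(self):
        assert classify_stimulus_state(6900.0, self._seg()) == "synchronized"

    def test_onset_with_room_is_desynchronized(self):
        assert classify_stimulus_state(6600.0, self._seg()) \
            == "desynchronized"

    def test_onset_in_synchronized_interval(self):
        assert classify_stimulus_state(1000.0, self._seg()) == "synchronized"

    def test_onset_outside_span_rejected(self):
        with pytest.raises(ValueError):
            classify_stimulus_state(20_000.0, self._seg())

    def test_fraction_matches_interval_overlap_oracle(self):
        sched = _alternating_schedule(60_000.0)
        tr = generate_ecog_trace(60_000.0, sched, seed=4)
        seg = segment_states(tr)
        onsets = np.arange(500.0, 59_000.0, 1800.0)
        frac = np.mean([classify_stimulus_state(o, seg) == "desynchronized"
                        for o in onsets])
        # brute-force oracle over the intervals with the 350 ms exclusion
        hits = 0
        for o in onsets:
            for a, b, s in seg.state_intervals:
                if a <= o < b:
                    hits += (s == "desynchronized") and (b - o > 350.0)
                    break
        assert frac == pytest.approx(hits / onsets.size)


class TestStateConditionedDecoding:
    def _merged(self, seed, rel_sync=0.35, rel_desync=1.0, reps=16):
        resp = {lab: [(30.0 + 45.0 * i, 70.0, 6.0)]
                for i, lab in enumerate(LABELS)}
        sched = make_schedule(LABELS, repetitions_per_pattern=reps, seed=seed)
        lo = generate_sweeps(NeuronModelSpec(5.0, resp, rel_sync),
                             sched, seed=200 + seed)
        hi = generate_sweeps(NeuronModelSpec(5.0, resp, rel_desync),
                             sched, seed=100 + seed)
        sweeps, states = {}, {}
        for lab in LABELS:
            sweeps[lab] = lo.sweeps[lab] + hi.sweeps[lab]
            states[lab] = ["synchronized"] * reps + ["desynchronized"] * reps
        return SweepSet("x", sweeps), states

    def test_desync_trials_decode_better(self):
        diffs = []
        for seed in range(6):
            ss, states = self._merged(seed)
            w = derive_windows(ss)
            params = DecoderParams(group_size=3, target_combinations=60,
                                   n_iterations=6, seed=seed)
            res = state_conditioned_decoding(ss, states, w, params)
            diffs.append(res["desynchronized"].mean_decoding_performance
                         - res["synchronized"].mean_decoding_performance)
        assert np.median(diffs) > 0

    def test_identical_noise_states_are_comparable(self):
        ss, states = self._merged(1, rel_sync=0.9, rel_desync=0.9)
        w = derive_windows(ss)
        params = DecoderParams(group_size=3, target_combinations=60,
                               n_iterations=8, seed=5)
        res = state_conditioned_decoding(ss, states, w, params)
        d = res["desynchronized"]
        s = res["synchronized"]
        pooled_sd = np.std(d.per_iteration_performance
                           + s.per_iteration_performance)
        assert abs(d.mean_decoding_performance
                   - s.mean_decoding_performance) < 3 * max(pooled_sd, 2.0)

    def test_pattern_with_too_few_sweeps_dropped(self):
        ss, states = self._merged(2)
        # leave only 2 desynchronized trials for P1 (group size is 3)
        states["P1"] = ["synchronized"] * 30 + ["desynchronized"] * 2
        w = derive_windows(ss)
        params = DecoderParams(group_size=3, target_combinations=60,
                               n_iterations=4, seed=2)
        res = state_conditioned_decoding(ss, states, w, params)
        conf = res["desynchronized"].mean_confusion.percentages
        i = res["desynchronized"].labels.index("P1")
        assert np.all(np.isnan(conf[i]))
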