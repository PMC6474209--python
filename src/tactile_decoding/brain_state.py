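"""ECoG brain-state segmentation and state-conditioned decoding.

The ECoG is windowed into 1000 ms segments with 125 ms overlap; summed
0-12 Hz spectral density (delta + theta + alpha) per mean-detrended segment
gives a compound power series.  Runs of at least two consecutive segments
below the recording-wide median are desynchronized epochs; everything else
is synchronized.  Stimulus presentations are assigned to a state, and the
decoding analysis is re-run per state with a bootstrap group size of 3
(fewer trials are available per state and pattern).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.signal import periodogram

from .decoder import (BootstrapError, DecoderParams, DecodingResult,
                      decode_neuron, run_decoding, _channel_for)
from .segmentation import TimeWindowSet
from .spike_metrics import SweepSet

logger = logging.getLogger(__name__)

__all__ = [
    "StateSegmentation",
    "segment_states",
    "classify_stimulus_state",
    "split_sweepset_by_state",
    "state_conditioned_decoding",
    "STATE_GROUP_SIZE",
]

STATE_GROUP_SIZE = 3            # bootstrap N in the state-conditioned mode
MIN_REMAINING_MS = 350.0        # stimulus must fit inside the desync epoch
State = Literal["synchronized", "desynchronized"]


@dataclass
class StateSegmentation:
    segment_starts: np.ndarray      # ms
    segment_ms: float
    hop_ms: float
    compound_power: np.ndarray      # summed 0-12 Hz density per segment
    median_power: float
    state_intervals: list[tuple[float, float, str]]   # tile the recording

    def desynchronized_intervals(self) -> list[tuple[float, float]]:
        return [(a, b) for a, b, s in self.state_intervals
                if s == "desynchronized"]


def segment_states(
    trace,
    segment_ms: float = 1000.0,
    overlap_ms: float = 125.0,
    band_hz: tuple[float, float] = (0.0, 12.0),
    min_run: int = 2,
) -> StateSegmentation:
    """Segment an ECoG trace into synchronized/desynchronized intervals.

    Each segment is mean-detrended and its periodogram power summed over the
    closed band [0, 12] Hz.  Desynchronized epochs are runs of >= `min_run`
    segments strictly below the median compound power.  For the interval
    tiling, segment k owns [k*hop, (k+1)*hop) with the last segment owning
    through the end of the trace.
    """
    fs = trace.sampling_rate
    x = np.asarray(trace.values, dtype=float)
    seg_n = int(round(segment_ms / 1000.0 * fs))
    hop_n = int(round((segment_ms - overlap_ms) / 1000.0 * fs))
    if x.size < seg_n + hop_n:
        raise ValueError("trace shorter than two analysis segments")
    n_seg = (x.size - seg_n) // hop_n + 1
    power = np.empty(n_seg)
    for k in range(n_seg):
        seg = x[k * hop_n:k * hop_n + seg_n]
        f, p = periodogram(seg, fs=fs, detrend="constant")
        power[k] = p[(f >= band_hz[0]) & (f <= band_hz[1])].sum()
    med = float(np.median(power))
    below = power < med
    labels = np.full(n_seg, "synchronized", dtype=object)
    i = 0
    while i < n_seg:
        if below[i]:
            j = i
            while j < n_seg and below[j]:
                j += 1
            if j - i >= min_run:
                labels[i:j] = "desynchronized"
            i = j
        else:
            i += 1
    ms_per = 1000.0 / fs
    hop_ms = hop_n * ms_per
    t0 = trace.start_time
    intervals: list[tuple[float, float, str]] = []
    for k in range(n_seg):
        start = t0 + k * hop_ms
        end = t0 + (k + 1) * hop_ms if k < n_seg - 1 else t0 + x.size * ms_per
        if intervals and intervals[-1][2] == labels[k]:
            intervals[-1] = (intervals[-1][0], end, labels[k])
        else:
            intervals.append((start, end, labels[k]))
    return StateSegmentation(
        segment_starts=t0 + np.arange(n_seg) * hop_ms,
        segment_ms=segment_ms,
        hop_ms=hop_ms,
        compound_power=power,
        median_power=med,
        state_intervals=intervals,
    )


def classify_stimulus_state(
    onset_ms: float,
    seg: StateSegmentation,
    min_remaining_ms: float = MIN_REMAINING_MS,
) -> State:
    """State of one stimulus presentation.

    Desynchronized iff the onset lies inside a desynchronized interval and
    more than `min_remaining_ms` of that interval remains after the onset
    (the stimulus must play out within the epoch); otherwise synchronized.
    """
    span_lo = seg.state_intervals[0][0]
    span_hi = seg.state_intervals[-1][1]
    if not span_lo - 1e-9 <= onset_ms <= span_hi + 1e-9:
        raise ValueError("stimulus onset outside the segmented span")
    for a, b, s in seg.state_intervals:
        if a - 1e-9 <= onset_ms < b:
            if s == "desynchronized" and (b - onset_ms) > min_remaining_ms:
                return "desynchronized"
            return "synchronized"
    return "synchronized"


def split_sweepset_by_state(
    sweepset: SweepSet,
    trial_states: dict[str, Sequence[str]],
) -> dict[str, SweepSet]:
    """Partition a SweepSet by per-trial state labels (aligned to sweeps)."""
    out: dict[str, SweepSet] = {}
    for state in ("synchronized", "desynchronized"):
        sweeps = {}
        for lab, trials in sweepset.sweeps.items():
            states = trial_states[lab]
            if len(states) != len(trials):
                raise ValueError("state labels not aligned to sweeps")
            sel = [t for t, s in zip(trials, states) if s == state]
            if sel:
                sweeps[lab] = sel
        if sweeps:
            out[state] = SweepSet(
                neuron_id=sweepset.neuron_id,
                sweeps=sweeps,
                pretrigger_span=sweepset.pretrigger_span,
                posttrigger_span=sweepset.posttrigger_span,
                area_tag=sweepset.area_tag,
                depth=sweepset.depth,
            )
    return out


def state_conditioned_decoding(
    sweepset: SweepSet,
    trial_states: dict[str, Sequence[str]],
    windows: TimeWindowSet,
    params: DecoderParams,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, DecodingResult]:
    """Decoding per ECoG state with the reduced bootstrap group size.

    Patterns with too few usable sweeps in a state fail their bootstrap and
    are dropped from that state's confusion matrix (logged); a state where
    every pattern fails raises BootstrapError.
    """
    p = replace(params, group_size=STATE_GROUP_SIZE)
    by_state = split_sweepset_by_state(sweepset, trial_states)
    results: dict[str, DecodingResult] = {}
    for state, subset in by_state.items():
        sub_rng = rng if rng is not None else np.random.default_rng(p.seed)
        results[state] = run_decoding(
            [_channel_for(subset, windows, p)], p, rng=sub_rng)
    return results
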