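"""Local field potential event detection.

Two detectors: a single-pulse sensory-evoked LFP (SE-LFP) detector operating
on the trimmed average of onset-aligned sweeps, and a pattern-evoked LFP
event detector operating on individual 400 ms pre / 400 ms post trace
segments through a boxcar -> decimate -> band-pass chain.  Cortical LFPs at
the recording depths used are negative-going, so both detectors look for
downward deflections relative to the pretrigger baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.stats import wilcoxon

__all__ = [
    "LfpEvent",
    "SeLfpResult",
    "DegenerateTestError",
    "detect_se_lfp",
    "detect_pattern_lfps",
    "threshold_events",
    "lfp_boxcar_auc",
    "reconstruct_boxcar_signal",
    "compare_pre_post",
]


class DegenerateTestError(ValueError):
    """Paired test undefined (single pair or all-zero differences)."""


@dataclass
class LfpEvent:
    onset: float          # ms relative to trigger
    duration: float       # ms
    amplitude: float      # signal units, negative
    epoch_tag: Literal["pre", "post"]

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if self.amplitude >= 0:
            raise ValueError("LFP events are negative deflections")


@dataclass
class SeLfpResult:
    detected: bool
    latency: Optional[float] = None     # ms
    duration: Optional[float] = None    # ms
    amplitude: Optional[float] = None


def _trimmed_average(sweeps: np.ndarray) -> np.ndarray:
    """Per-timepoint mean of the central 50% of values (symmetric trim)."""
    srt = np.sort(sweeps, axis=0)
    n = sweeps.shape[0]
    lo = n // 4
    hi = n - lo
    return srt[lo:hi].mean(axis=0)


def detect_se_lfp(
    sweeps: np.ndarray,
    sampling_rate_hz: float,
    pretrigger_ms: float = 100.0,
    detect_window_ms: float = 100.0,
    gate_sd: float = 5.0,
    edge_sd: float = 2.0,
    filter_window: int = 10,
    filter_kind: Literal["median", "mean"] = "median",
) -> SeLfpResult:
    """Detect a single-pulse sensory-evoked LFP from aligned sweeps.

    The 50% most extreme values at each time point are trimmed away before
    averaging; baseline statistics come from the `pretrigger_ms` span of the
    trimmed average.  A response is detected when the trimmed average drops
    below mean - `gate_sd`*SD within `detect_window_ms` after the trigger;
    latency, duration and amplitude are then read from the running-median
    (or moving-average) filtered average at the -`edge_sd`*SD crossings.
    """
    sweeps = np.atleast_2d(np.asarray(sweeps, dtype=float))
    if sweeps.shape[0] < 4:
        raise ValueError("at least 4 sweeps are required for the 50% trim")
    n_pre = int(round(pretrigger_ms / 1000.0 * sampling_rate_hz))
    if n_pre < 2 or n_pre >= sweeps.shape[1]:
        raise ValueError("pretrigger span missing from the sweeps")
    avg = _trimmed_average(sweeps)
    base_mean = float(avg[:n_pre].mean())
    base_sd = float(avg[:n_pre].std(ddof=0))
    if base_sd <= 0:
        return SeLfpResult(detected=False)
    n_detect = int(round(detect_window_ms / 1000.0 * sampling_rate_hz))
    post = avg[n_pre:n_pre + n_detect]
    if not np.any(post < base_mean - gate_sd * base_sd):
        return SeLfpResult(detected=False)
    if filter_kind == "median":
        filt = median_filter(avg, size=filter_window, mode="nearest")
    else:
        filt = uniform_filter1d(avg, size=filter_window, mode="nearest")
    edge = base_mean - edge_sd * base_sd
    below = filt[n_pre:] < edge
    starts = np.flatnonzero(below)
    if starts.size == 0:
        return SeLfpResult(detected=False)
    i0 = starts[0]
    i1 = i0
    while i1 < below.size and below[i1]:
        i1 += 1
    ms_per_sample = 1000.0 / sampling_rate_hz
    latency = i0 * ms_per_sample
    duration = (i1 - i0) * ms_per_sample
    amplitude = float(filt[n_pre + i0:n_pre + i1].min())
    return SeLfpResult(True, latency=latency, duration=duration,
                       amplitude=amplitude)


def detect_pattern_lfps(
    segment: np.ndarray,
    sampling_rate_hz: float,
    pre_ms: float = 400.0,
    post_ms: float = 400.0,
    boxcar_ms: float = 10.0,
    resample_to_hz: float = 1000.0,
    band_hz: tuple[float, float] = (50.0, 499.0),
    threshold_sd: float = 2.0,
    min_duration_ms: float = 10.0,
) -> list[LfpEvent]:
    """Pattern-evoked LFP events in one pre+post trace segment.

    Chain: 10 ms rolling boxcar mean -> decimation to 1 kHz -> first-order
    Butterworth band-pass (zero-phase) -> pretrigger-median DC removal.
    Events are runs of >= `min_duration_ms` below baseline mean - 2 SD
    (baseline from the pre epoch); an event starting before the trigger is
    tagged "pre" even when it crosses into the post epoch.
    """
    x = np.asarray(segment, dtype=float)
    n_pre = int(round(pre_ms / 1000.0 * sampling_rate_hz))
    n_post = int(round(post_ms / 1000.0 * sampling_rate_hz))
    if x.size < n_pre + n_post or n_pre == 0 or n_post == 0:
        raise ValueError("segment must cover the pre and post epochs")
    box = max(int(round(boxcar_ms / 1000.0 * sampling_rate_hz)), 1)
    sm = uniform_filter1d(x, size=box, mode="nearest")
    step = max(int(round(sampling_rate_hz / resample_to_hz)), 1)
    y = sm[::step]
    fs = sampling_rate_hz / step
    nyq = fs / 2.0
    lo = band_hz[0] / nyq
    hi = min(band_hz[1] / nyq, 0.999)
    b, a = sps.butter(1, [lo, hi], btype="bandpass")
    y = sps.filtfilt(b, a, y)
    n_pre_r = int(round(pre_ms / 1000.0 * fs))
    y = y - np.median(y[:n_pre_r])
    base_mean = float(y[:n_pre_r].mean())
    base_sd = float(y[:n_pre_r].std(ddof=0))
    if base_sd <= 0:
        return []
    thr = base_mean - threshold_sd * base_sd
    return threshold_events(y, n_pre_r, fs, thr, min_duration_ms)


def threshold_events(
    y: np.ndarray,
    n_pre_samples: int,
    fs_hz: float,
    threshold: float,
    min_duration_ms: float = 10.0,
) -> list[LfpEvent]:
    """Runs of at least `min_duration_ms` below `threshold` as LfpEvents.

    Onsets are in ms relative to the trigger (sample `n_pre_samples`); an
    event whose run begins before the trigger is tagged "pre" even when it
    continues into the post epoch.
    """
    below = np.asarray(y) < threshold
    ms_per_sample = 1000.0 / fs_hz
    min_run = int(round(min_duration_ms / ms_per_sample))
    events: list[LfpEvent] = []
    i = 0
    while i < below.size:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < below.size and below[j]:
            j += 1
        if j - i >= min_run:
            onset = (i - n_pre_samples) * ms_per_sample
            events.append(LfpEvent(
                onset=onset,
                duration=(j - i) * ms_per_sample,
                amplitude=float(np.min(y[i:j])),
                epoch_tag="pre" if onset < 0 else "post",
            ))
        i = j
    return events


def lfp_boxcar_auc(events: Sequence[LfpEvent]) -> np.ndarray:
    """AUC of each event's boxcar reconstruction: |amplitude| x duration."""
    return np.asarray([abs(e.amplitude) * e.duration for e in events])


def reconstruct_boxcar_signal(
    events: Sequence[LfpEvent],
    t_lo: float,
    t_hi: float,
    ms_per_sample: float = 1.0,
) -> np.ndarray:
    """Event-train signal: a boxcar of the event's amplitude and duration at
    each onset, zero elsewhere."""
    n = int(round((t_hi - t_lo) / ms_per_sample))
    out = np.zeros(n)
    for e in events:
        i0 = int(round((e.onset - t_lo) / ms_per_sample))
        i1 = int(round((e.onset + e.duration - t_lo) / ms_per_sample))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 > i0:
            out[i0:i1] += e.amplitude
    return out


def compare_pre_post(
    pre_values: Sequence[float],
    post_values: Sequence[float],
) -> dict:
    """Wilcoxon signed-rank test on paired pre/post measurements."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (same length)")
    if pre.size < 2:
        raise DegenerateTestError("at least two paired sweeps are required")
    diffs = post - pre
    if np.all(diffs == 0):
        raise DegenerateTestError("all paired differences are zero")
    stat, p = wilcoxon(post, pre)
    return {"statistic": float(stat), "p_value": float(p), "n": int(pre.size)}
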