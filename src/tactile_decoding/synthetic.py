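"""Synthetic experiment generator.

Everything the analysis pipeline consumes can be produced here with seeded
randomness: 4-channel spatiotemporal stimulation patterns, pattern-selective
spike sweeps from inhomogeneous Poisson neurons, stimulus-locked LFP voltage
traces, and ECoG traces alternating between synchronized (low-frequency
dominated) and desynchronized (broadband, low-power) cortical states.

Spike generation uses thinning, which is exact for an inhomogeneous Poisson
process: candidate events are drawn at the rate ceiling and kept with
probability lambda(t) / lambda_max.
"""

from __future__ import annotations

import importlib.resources as resources
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spike_metrics import SweepSet

__all__ = [
    "StimulationPattern",
    "SessionSchedule",
    "NeuronModelSpec",
    "ContinuousTrace",
    "CANONICAL_LABELS",
    "canonical_patterns",
    "generate_patterns",
    "make_schedule",
    "generate_sweeps",
    "generate_population_sweeps",
    "generate_lfp_trace",
    "extract_trace_sweeps",
    "generate_ecog_trace",
    "make_cohort_specs",
]

CANONICAL_LABELS = ["F5", "S5", "F10", "S10", "F20", "S20", "Finf", "Sinf"]


@dataclass
class StimulationPattern:
    """A labeled 4-channel schedule of skin-stimulation pulse times (ms)."""

    label: str
    channel_pulses: list[np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pattern duration must be positive")
        pulses = [np.asarray(c, dtype=float) for c in self.channel_pulses]
        for c in pulses:
            if c.size and c.min() < 0:
                raise ValueError("pulse times must be non-negative")
            if c.size > 1 and not np.all(np.diff(c) > 0):
                raise ValueError("pulse times must be strictly increasing")
            if c.size and c.max() > self.duration:
                raise ValueError("pulse time beyond pattern duration")
        self.channel_pulses = pulses

    @property
    def n_channels(self) -> int:
        return len(self.channel_pulses)

    def discretize(self, resolution_ms: float = 1.0) -> np.ndarray:
        """Binary (n_channels, n_bins) pulse raster at the given resolution."""
        n_bins = int(np.ceil(self.duration / resolution_ms))
        out = np.zeros((self.n_channels, n_bins), dtype=int)
        for i, c in enumerate(self.channel_pulses):
            idx = np.minimum((c / resolution_ms).astype(int), n_bins - 1)
            out[i, idx] = 1
        return out


@dataclass
class SessionSchedule:
    """Pseudo-random trial order of pattern presentations."""

    trial_onsets: np.ndarray        # ms
    trial_labels: list[str]
    inter_trial_interval: float = 1800.0
    repetitions_per_pattern: int = 100

    def __post_init__(self) -> None:
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=float)
        if len(self.trial_onsets) != len(self.trial_labels):
            raise ValueError("onsets and labels must have equal length")
        if (len(self.trial_onsets) > 1
                and np.any(np.diff(self.trial_onsets)
                           < self.inter_trial_interval - 1e-9)):
            raise ValueError("onsets closer than the inter-trial interval")

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.trial_labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def trials_for(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.trial_labels) == label)


@dataclass
class NeuronModelSpec:
    """Rate model of one synthetic neuron.

    The firing rate on a trial of pattern `p` is
    ``baseline_rate + sum of expressed Gaussian bumps of responses[p]``,
    where each bump (peak_time ms, peak_rate Hz, peak_width ms) is expressed
    independently with probability `reliability`.
    """

    baseline_rate: float
    responses: dict[str, list[tuple[float, float, float]]]
    reliability: float = 1.0
    area_tag: str = "S1"
    depth: float = 500.0
    neuron_id: str = "n0"

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline rate must be non-negative")
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError("reliability must lie in [0, 1]")
        for bumps in self.responses.values():
            for _, rate, width in bumps:
                if rate < 0:
                    raise ValueError("bump peak rate must be non-negative")
                if width <= 0:
                    raise ValueError("bump width must be positive")


@dataclass
class ContinuousTrace:
    """Uniformly sampled voltage trace (arbitrary units)."""

    sampling_rate: float     # Hz
    start_time: float        # ms
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def duration_ms(self) -> float:
        return self.values.size / self.sampling_rate * 1000.0

    def time_ms(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) \
            / self.sampling_rate * 1000.0


# ---------------------------------------------------------------------------
# Stimulation patterns
# ---------------------------------------------------------------------------

def canonical_patterns() -> list[StimulationPattern]:
    """The eight canonical labeled patterns (F5 ... Sinf).

    Loaded from a bundled synthetic fixture: four-channel pulse schedules
    shaped like fast-adapting (F, dense onset bursts) and slowly adapting
    (S, sustained sparser trains) sensor output during indentation against
    objects of varying curvature.  They are illustrative event lists, not
    measured data.
    """
    ref = resources.files("tactile_decoding").joinpath(
        "data/canonical_patterns_synthetic.json")
    spec = json.loads(ref.read_text())
    return [
        StimulationPattern(
            label=p["label"],
            channel_pulses=[np.asarray(c, dtype=float)
                            for c in p["channel_pulses"]],
            duration=p["duration"],
        )
        for p in spec["patterns"]
    ]


def generate_patterns(
    seed: int,
    n_patterns: int = 8,
    n_channels: int = 4,
    duration_ms: float = 340.0,
    canonical: bool = False,
) -> list[StimulationPattern]:
    """Generate pairwise-distinct random stimulation patterns.

    In canonical mode the bundled eight labeled patterns are returned and
    the remaining arguments are ignored.  Otherwise each channel of each
    pattern receives a jittered pulse train at a randomly drawn rate, which
    makes patterns distinct with probability one.
    """
    if canonical:
        return canonical_patterns()
    if n_patterns < 2:
        raise ValueError("at least 2 patterns are required")
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    patterns: list[StimulationPattern] = []
    rasters: set[bytes] = set()
    i = 0
    while len(patterns) < n_patterns:
        label = f"P{len(patterns) + 1}"
        channels = []
        for _ in range(n_channels):
            n_pulses = int(rng.integers(3, 13))
            base = np.sort(rng.uniform(0.0, duration_ms, n_pulses))
            # Enforce a refractory 2 ms gap so times stay strictly increasing.
            for j in range(1, n_pulses):
                base[j] = max(base[j], base[j - 1] + 2.0)
            base = base[base <= duration_ms]
            if base.size < 2:
                base = np.array([0.0, duration_ms / 2.0])
            channels.append(base)
        pat = StimulationPattern(label, channels, duration_ms)
        key = pat.discretize(1.0).tobytes()
        if key in rasters:   # pragma: no cover - vanishingly unlikely
            i += 1
            continue
        rasters.add(key)
        patterns.append(pat)
    return patterns


def make_schedule(
    labels: Sequence[str],
    repetitions_per_pattern: int = 100,
    inter_trial_interval: float = 1800.0,
    seed: int = 0,
) -> SessionSchedule:
    """Pseudo-random presentation order: repeated shuffles of the label set
    (each block presents every pattern once), trials 1.8 s apart."""
    if not 1 <= repetitions_per_pattern:
        raise ValueError("repetitions must be positive")
    rng = np.random.default_rng(seed)
    order: list[str] = []
    for _ in range(repetitions_per_pattern):
        block = list(labels)
        rng.shuffle(block)
        order.extend(block)
    onsets = np.arange(len(order)) * inter_trial_interval
    return SessionSchedule(onsets, order, inter_trial_interval,
                           repetitions_per_pattern)


# ---------------------------------------------------------------------------
# Spike sweeps
# ---------------------------------------------------------------------------

def _trial_rate_spikes(
    rng: np.random.Generator,
    baseline: float,
    bumps: list[tuple[float, float, float]],
    t_lo: float,
    t_hi: float,
) -> np.ndarray:
    """One inhomogeneous-Poisson sweep by thinning on [t_lo, t_hi] (ms)."""
    lam_max = baseline + sum(rate for _, rate, _ in bumps)
    if lam_max <= 0:
        return np.empty(0)
    span_s = (t_hi - t_lo) / 1000.0
    n_cand = rng.poisson(lam_max * span_s)
    if n_cand == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t_lo, t_hi, n_cand))
    lam = np.full(n_cand, float(baseline))
    for t0, rate, width in bumps:
        lam += rate * np.exp(-0.5 * ((cand - t0) / width) ** 2)
    keep = rng.uniform(0.0, lam_max, n_cand) < lam
    return cand[keep]


def generate_sweeps(
    spec: NeuronModelSpec,
    schedule: SessionSchedule,
    seed: int,
    pretrigger_ms: float = 500.0,
    posttrigger_ms: float = 1000.0,
) -> SweepSet:
    """Simulate one neuron's spike sweeps for every scheduled trial.

    Each trial draws from rate lambda(t) = baseline + sum of the expressed
    bumps of the presented pattern; each bump is expressed with probability
    `spec.reliability`.  Deterministic given the seed.
    """
    if len(schedule.trial_labels) == 0:
        raise ValueError("schedule is empty")
    rng = np.random.default_rng(seed)
    sweeps: dict[str, list[np.ndarray]] = {lab: [] for lab in schedule.labels}
    for label in schedule.trial_labels:
        bumps = spec.responses.get(label, [])
        expressed = [b for b in bumps
                     if rng.uniform() < spec.reliability]
        spikes = _trial_rate_spikes(rng, spec.baseline_rate, expressed,
                                    -pretrigger_ms, posttrigger_ms)
        sweeps[label].append(spikes)
    return SweepSet(
        neuron_id=spec.neuron_id,
        sweeps=sweeps,
        pretrigger_span=pretrigger_ms,
        posttrigger_span=posttrigger_ms,
        area_tag=spec.area_tag,
        depth=spec.depth,
    )


def generate_population_sweeps(
    specs: Sequence[NeuronModelSpec],
    schedule: SessionSchedule,
    seed: int,
    **kwargs,
) -> list[SweepSet]:
    """Co-recorded population: every neuron sees the same trial schedule,
    so trial indices are aligned across the returned SweepSets."""
    seeds = np.random.SeedSequence(seed).spawn(len(specs))
    return [
        generate_sweeps(spec, schedule,
                        seed=int(ss.generate_state(1)[0] % (2 ** 31)),
                        **kwargs)
        for spec, ss in zip(specs, seeds)
    ]


def make_cohort_specs(
    n_neurons: int,
    pattern_labels: Sequence[str],
    seed: int,
    baseline_rate: float = 5.0,
    n_bumps: int = 3,
    peak_rate_range: tuple[float, float] = (40.0, 90.0),
    peak_width_range: tuple[float, float] = (4.0, 12.0),
    response_span: tuple[float, float] = (10.0, 500.0),
    reliability: float = 0.85,
    area_tags: Sequence[str] = ("S1", "non-S1"),
) -> list[NeuronModelSpec]:
    """Random pattern-selective neuron specs for cohort-level analyses.

    Each neuron gets `n_bumps` Gaussian response bumps per pattern with
    pattern-specific random timing, so different patterns evoke different
    temporal response profiles (the structure the decoder exploits).
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_neurons):
        responses = {}
        for lab in pattern_labels:
            times = np.sort(rng.uniform(*response_span, n_bumps))
            bumps = [
                (float(t), float(rng.uniform(*peak_rate_range)),
                 float(rng.uniform(*peak_width_range)))
                for t in times
            ]
            responses[lab] = bumps
        specs.append(NeuronModelSpec(
            baseline_rate=baseline_rate,
            responses=responses,
            reliability=reliability,
            area_tag=area_tags[i % len(area_tags)],
            depth=float(rng.uniform(200.0, 1400.0)),
            neuron_id=f"n{i:03d}",
        ))
    return specs


# ---------------------------------------------------------------------------
# Voltage traces
# ---------------------------------------------------------------------------

def generate_lfp_trace(
    schedule: SessionSchedule,
    response_amplitude: float,
    noise_sd: float,
    seed: int,
    sampling_rate_hz: float = 10_000.0,
    response_latency_ms: float = 8.0,
    response_width_ms: float = 15.0,
    padding_ms: float = 500.0,
) -> ContinuousTrace:
    """Gaussian noise plus a negative-going deflection after each trial onset.

    `response_amplitude` is the (positive) peak magnitude of the evoked
    negative deflection; 0 yields pure noise.  Deflections are alpha-shaped
    (-A * x * exp(1 - x), x = (t - onset - latency)/width for x >= 0): they
    start abruptly at `response_latency_ms` after the trial onset, peak one
    `response_width_ms` later and decay, so the onset latency is sharp.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    t_end = float(schedule.trial_onsets[-1]) + padding_ms \
        if len(schedule.trial_onsets) else padding_ms
    start = -padding_ms
    n = int(round((t_end - start) / 1000.0 * sampling_rate_hz))
    values = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    if response_amplitude != 0.0:
        t = start + np.arange(n) / sampling_rate_hz * 1000.0
        for onset in schedule.trial_onsets:
            t0 = onset + response_latency_ms
            lo = int(np.searchsorted(t, t0))
            hi = int(np.searchsorted(t, t0 + 8.0 * response_width_ms))
            x = (t[lo:hi] - t0) / response_width_ms
            values[lo:hi] -= abs(response_amplitude) * x * np.exp(1.0 - x)
    return ContinuousTrace(sampling_rate_hz, start, values)


def extract_trace_sweeps(
    trace: ContinuousTrace,
    onsets_ms: Sequence[float],
    pre_ms: float,
    post_ms: float,
) -> np.ndarray:
    """Cut onset-aligned segments out of a trace: (n_sweeps, n_samples),
    each covering [-pre_ms, +post_ms) around its onset."""
    fs = trace.sampling_rate
    n_pre = int(round(pre_ms / 1000.0 * fs))
    n_post = int(round(post_ms / 1000.0 * fs))
    rows = []
    for onset in onsets_ms:
        i0 = int(round((onset - trace.start_time) / 1000.0 * fs))
        lo, hi = i0 - n_pre, i0 + n_post
        if lo < 0 or hi > trace.values.size:
            raise ValueError("sweep window outside the recorded trace")
        rows.append(trace.values[lo:hi])
    return np.asarray(rows)


def generate_ecog_trace(
    duration_ms: float,
    state_schedule: Sequence[tuple[float, float, str]],
    seed: int,
    sampling_rate_hz: float = 1000.0,
    sync_amplitude: float = 60.0,
    desync_amplitude: float = 8.0,
) -> ContinuousTrace:
    """ECoG with alternating cortical states at 1 kHz.

    Synchronized intervals carry a strong slow oscillation (1-4 Hz with
    drifting frequency) plus noise, i.e. high summed 0-12 Hz power;
    desynchronized intervals carry weak broadband noise only.
    `state_schedule` is a list of (start_ms, end_ms, label) covering the
    duration without overlap.
    """
    ivals = sorted(state_schedule, key=lambda iv: iv[0])
    cursor = 0.0
    for start, end, label in ivals:
        if label not in ("synchronized", "desynchronized"):
            raise ValueError(f"unknown state label {label!r}")
        if start < cursor - 1e-9:
            raise ValueError("state schedule intervals overlap")
        if end <= start:
            raise ValueError("empty state interval")
        cursor = end
    if cursor < duration_ms - 1e-9:
        raise ValueError("state schedule does not cover the duration")
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms / 1000.0 * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz          # seconds
    values = rng.normal(0.0, desync_amplitude, n)
    phase = np.cumsum(
        2.0 * np.pi * (2.5 + 1.0 * rng.standard_normal(n) * 0.05)
        / sampling_rate_hz)
    slow = np.sin(phase)
    for start, end, label in ivals:
        if label != "synchronized":
            continue
        lo = int(round(start / 1000.0 * sampling_rate_hz))
        hi = min(int(round(end / 1000.0 * sampling_rate_hz)), n)
        values[lo:hi] += sync_amplitude * slow[lo:hi]
    return ContinuousTrace(sampling_rate_hz, 0.0, values)
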