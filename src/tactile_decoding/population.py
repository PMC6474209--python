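"""Population-level decoding.

Two analyses: (i) inter-neuron response discrimination, where the classes of
the confusion matrix are neuron identities and the responses compared are
those evoked by a single stimulation pattern in different neurons; and
(ii) cooperative decoding, a greedy forward selection of up to 10 neurons
whose concatenated window-AUC features jointly maximize kNN decoding of the
stimulation patterns at a given response duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .decoder import (ChannelData, DecoderParams, DecodingResult,
                      run_decoding, signals_on_grid)
from .segmentation import compound_density, segment_windows
from .spike_metrics import SweepSet, kdes_by_pattern

logger = logging.getLogger(__name__)

__all__ = ["CooperativeResult", "inter_neuron_confusion", "cooperative_decode"]

MAX_COOPERATIVE_NEURONS = 10


@dataclass
class CooperativeResult:
    """Greedy selection trace for one response duration."""

    duration: float
    selected_neurons: list[str]
    performance_per_step: list[float]
    dimensionality_per_step: list[int]


def inter_neuron_confusion(
    neurons: Sequence[SweepSet],
    pattern_label: str,
    params: DecoderParams,
    rng: Optional[np.random.Generator] = None,
    shuffle: bool = False,
) -> DecodingResult:
    """Discriminate which neuron produced a response to one pattern.

    Time windows are derived from the pooled compound density across the
    compared neurons' curves for that pattern; chance is 100/M % for M
    neurons.  `shuffle` permutes the neuron-identity labels before each
    split (the null control).
    """
    if len(neurons) < 2:
        raise ValueError("at least two neurons are required")
    kdes = []
    for n in neurons:
        if pattern_label not in n.sweeps:
            raise ValueError(
                f"neuron {n.neuron_id} has no sweeps for {pattern_label!r}")
        kdes.append(kdes_by_pattern(n)[pattern_label])
    comp = compound_density(kdes, span_ms=params.analysis_span)
    windows = segment_windows(comp, auc_floor=params.auc_floor)
    if windows.n_kept == 0:
        raise ValueError("no kept time windows for this pattern")
    grid = np.arange(0.0, params.analysis_span + 0.5)
    signals = {
        n.neuron_id: signals_on_grid(n.sweeps[pattern_label],
                                     params.kernel_tau, grid)
        for n in neurons
    }
    channel = ChannelData(signals=signals, windows=windows, grid=grid)
    return run_decoding([channel], params, shuffle_labels=shuffle, rng=rng)


def _neuron_channel(
    sweepset: SweepSet,
    params: DecoderParams,
    span: float,
    kdes,
) -> Optional[ChannelData]:
    comp = compound_density(list(kdes.values()), span_ms=span)
    windows = segment_windows(comp, auc_floor=params.auc_floor)
    if windows.n_kept == 0:
        return None
    grid = np.arange(0.0, span + 0.5)
    signals = {
        lab: signals_on_grid(trials, params.kernel_tau, grid)
        for lab, trials in sweepset.sweeps.items()
    }
    return ChannelData(signals=signals, windows=windows, grid=grid)


def cooperative_decode(
    neurons: Sequence[SweepSet],
    params: DecoderParams,
    durations: Sequence[float] = tuple(range(100, 1001, 100)),
    max_neurons: int = MAX_COOPERATIVE_NEURONS,
) -> list[CooperativeResult]:
    """Greedy forward selection of co-recorded neurons per duration.

    Step 1 keeps the best single-neuron decoder; each further step adds the
    remaining neuron that maximizes joint decoding on the concatenated
    feature spaces.  Within one scan step every candidate is evaluated with
    identical iteration seeds, so splits and trial-subset draws are paired
    across candidates.  Neurons with no kept windows in the interval are
    skipped; ties prefer the lower neuron index.
    """
    if len(neurons) == 0:
        raise ValueError("empty neuron list")
    all_kdes = [kdes_by_pattern(n) for n in neurons]
    results = []
    root = np.random.SeedSequence(params.seed)
    for d_i, dur in enumerate(durations):
        p = replace(params, analysis_span=float(dur))
        channels: list[Optional[ChannelData]] = [
            _neuron_channel(n, p, float(dur), k)
            for n, k in zip(neurons, all_kdes)
        ]
        available = [i for i, ch in enumerate(channels) if ch is not None]
        if not available:
            logger.warning("no neuron has kept windows at %s ms", dur)
            results.append(CooperativeResult(float(dur), [], [], []))
            continue
        selected: list[int] = []
        perf_steps: list[float] = []
        dim_steps: list[int] = []
        step_seeds = root.spawn(len(durations))[d_i].spawn(max_neurons)
        while available and len(selected) < max_neurons:
            step_seed = step_seeds[len(selected)]
            best_i, best_perf = None, -np.inf
            for i in available:
                ens = [channels[j] for j in selected] + [channels[i]]
                res = run_decoding(
                    ens, p,
                    rng=np.random.default_rng(step_seed.generate_state(4)))
                if res.mean_decoding_performance > best_perf:
                    best_perf = res.mean_decoding_performance
                    best_i = i
            selected.append(best_i)
            available.remove(best_i)
            perf_steps.append(best_perf)
            dim_steps.append(sum(channels[j].windows.n_kept
                                 for j in selected))
        results.append(CooperativeResult(
            duration=float(dur),
            selected_neurons=[neurons[i].neuron_id for i in selected],
            performance_per_step=perf_steps,
            dimensionality_per_step=dim_steps,
        ))
    return results
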