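"""Plain-text readers and writers for the pipeline's data objects.

Sweeps travel as tidy tab-separated tables (neuron_id, trial_id,
pattern_label, spike_time_ms), traces as single-column text with a JSON
sidecar carrying the sampling metadata, and patterns/window sets as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import TimeWindowSet
from .spike_metrics import SweepSet
from .synthetic import ContinuousTrace, StimulationPattern

__all__ = [
    "write_sweeps", "read_sweeps",
    "write_patterns", "read_patterns",
    "write_trace", "read_trace",
    "write_windows", "read_windows",
    "write_density", "write_session_bundle", "read_session_bundle",
]


def write_sweeps(path, sweepsets: Sequence[SweepSet]) -> None:
    rows = []
    for ss in sweepsets:
        for label, trials in ss.sweeps.items():
            for trial_id, spikes in enumerate(trials):
                if len(spikes) == 0:
                    rows.append((ss.neuron_id, trial_id, label, np.nan))
                for t in spikes:
                    rows.append((ss.neuron_id, trial_id, label, float(t)))
    df = pd.DataFrame(rows, columns=["neuron_id", "trial_id",
                                     "pattern_label", "spike_time_ms"])
    df.to_csv(path, sep="\t", index=False)


def read_sweeps(
    path,
    pretrigger_span: float = 500.0,
    posttrigger_span: float = 1000.0,
    metadata: dict | None = None,
) -> list[SweepSet]:
    df = pd.read_csv(path, sep="\t")
    metadata = metadata or {}
    out = []
    for nid, sub in df.groupby("neuron_id", sort=False):
        sweeps: dict[str, list[np.ndarray]] = {}
        for (label, trial_id), tr in sub.groupby(
                ["pattern_label", "trial_id"], sort=False):
            times = tr["spike_time_ms"].dropna().to_numpy()
            sweeps.setdefault(label, [])
            # trial ids are dense per pattern; extend as needed
            while len(sweeps[label]) <= trial_id:
                sweeps[label].append(np.empty(0))
            sweeps[label][trial_id] = np.sort(times)
        meta = metadata.get(str(nid), {})
        out.append(SweepSet(
            neuron_id=str(nid), sweeps=sweeps,
            pretrigger_span=pretrigger_span,
            posttrigger_span=posttrigger_span,
            area_tag=meta.get("area_tag", "S1"),
            depth=meta.get("depth", 500.0),
        ))
    return out


def write_patterns(path, patterns: Sequence[StimulationPattern]) -> None:
    payload = {"patterns": [
        {"label": p.label,
         "channel_pulses": [c.tolist() for c in p.channel_pulses],
         "duration": p.duration}
        for p in patterns
    ]}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_patterns(path) -> list[StimulationPattern]:
    payload = json.loads(Path(path).read_text())
    return [
        StimulationPattern(
            label=p["label"],
            channel_pulses=[np.asarray(c, dtype=float)
                            for c in p["channel_pulses"]],
            duration=p["duration"],
        )
        for p in payload["patterns"]
    ]


def write_trace(path, trace: ContinuousTrace) -> None:
    """Single-column samples plus a `<path>.json` metadata sidecar."""
    path = Path(path)
    np.savetxt(path, trace.values, fmt="%.8g")
    sidecar = {"sampling_rate": trace.sampling_rate,
               "start_time": trace.start_time}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_trace(path) -> ContinuousTrace:
    path = Path(path)
    values = np.loadtxt(path)
    sidecar = json.loads(
        path.with_suffix(path.suffix + ".json").read_text())
    return ContinuousTrace(sidecar["sampling_rate"], sidecar["start_time"],
                           values)


def write_windows(path, windows: TimeWindowSet) -> None:
    Path(path).write_text(json.dumps(windows.to_dict(), indent=1))


def read_windows(path) -> TimeWindowSet:
    return TimeWindowSet.from_dict(json.loads(Path(path).read_text()))


def write_density(path, time_grid: np.ndarray, values: np.ndarray) -> None:
    np.savetxt(path, np.column_stack([time_grid, values]),
               fmt="%.8g", delimiter="\t", header="time_ms\tvalue")


def write_session_bundle(path, sweepsets: Sequence[SweepSet],
                         schedule=None) -> None:
    """JSON bundle of a (possibly co-recorded) session."""
    payload = {
        "neurons": [
            {
                "neuron_id": ss.neuron_id,
                "area_tag": ss.area_tag,
                "depth": ss.depth,
                "pretrigger_span": ss.pretrigger_span,
                "posttrigger_span": ss.posttrigger_span,
                "sweeps": {lab: [t.tolist() for t in trials]
                           for lab, trials in ss.sweeps.items()},
            }
            for ss in sweepsets
        ]
    }
    if schedule is not None:
        payload["schedule"] = {
            "trial_onsets": schedule.trial_onsets.tolist(),
            "trial_labels": list(schedule.trial_labels),
            "inter_trial_interval": schedule.inter_trial_interval,
            "repetitions_per_pattern": schedule.repetitions_per_pattern,
        }
    Path(path).write_text(json.dumps(payload))


def read_session_bundle(path):
    from .synthetic import SessionSchedule
    payload = json.loads(Path(path).read_text())
    sweepsets = [
        SweepSet(
            neuron_id=n["neuron_id"],
            sweeps={lab: [np.asarray(t, dtype=float) for t in trials]
                    for lab, trials in n["sweeps"].items()},
            pretrigger_span=n["pretrigger_span"],
            posttrigger_span=n["posttrigger_span"],
            area_tag=n["area_tag"],
            depth=n["depth"],
        )
        for n in payload["neurons"]
    ]
    schedule = None
    if "schedule" in payload:
        s = payload["schedule"]
        schedule = SessionSchedule(
            np.asarray(s["trial_onsets"], dtype=float),
            list(s["trial_labels"]),
            s["inter_trial_interval"],
            s["repetitions_per_pattern"],
        )
    return sweepsets, schedule
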