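"""Compound density segmentation and neuron qualification.

The eight per-pattern density curves of a neuron are superimposed and their
pointwise maximum (the compound density) is segmented at interior local
minima into contiguous time windows.  Window AUCs (baseline = within-window
minimum) are normalized to the largest window; windows below 2.5% of the
maximum are dropped.  Neurons whose curves lack at least three sufficiently
sharp peaks are excluded from decoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .spike_metrics import DegenerateBaselineError, DensityCurve

__all__ = [
    "CompoundDensity",
    "TimeWindowSet",
    "compound_density",
    "local_minima_boundaries",
    "segment_windows",
    "qualify_neuron",
    "ANALYSIS_SPAN_MS",
    "AUC_FLOOR",
]

ANALYSIS_SPAN_MS = 600.0   # standard integration window for decoding
AUC_FLOOR = 0.025          # windows below 2.5% of the largest AUC are dropped


@dataclass
class CompoundDensity:
    time_grid: np.ndarray
    values: np.ndarray


@dataclass
class TimeWindowSet:
    """Peak-defined segmentation of the analysis span.

    `boundaries` includes both endpoints, so window i is
    [boundaries[i], boundaries[i+1]).  `kept_mask` marks windows surviving
    the normalized-AUC floor; feature dimensionality equals `n_kept`.
    """

    boundaries: np.ndarray
    window_aucs: np.ndarray
    normalized_aucs: np.ndarray
    kept_mask: np.ndarray
    auc_floor: float = AUC_FLOOR

    @property
    def n_windows(self) -> int:
        return len(self.window_aucs)

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def kept_windows(self) -> list[tuple[float, float]]:
        return [
            (float(self.boundaries[i]), float(self.boundaries[i + 1]))
            for i in range(self.n_windows)
            if self.kept_mask[i]
        ]

    def to_dict(self) -> dict:
        return {
            "boundaries": self.boundaries.tolist(),
            "window_aucs": self.window_aucs.tolist(),
            "normalized_aucs": self.normalized_aucs.tolist(),
            "kept_mask": self.kept_mask.astype(bool).tolist(),
            "auc_floor": self.auc_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TimeWindowSet":
        return cls(
            boundaries=np.asarray(d["boundaries"], dtype=float),
            window_aucs=np.asarray(d["window_aucs"], dtype=float),
            normalized_aucs=np.asarray(d["normalized_aucs"], dtype=float),
            kept_mask=np.asarray(d["kept_mask"], dtype=bool),
            auc_floor=float(d.get("auc_floor", AUC_FLOOR)),
        )


def compound_density(
    kdes: Sequence[DensityCurve],
    span_ms: Optional[float] = ANALYSIS_SPAN_MS,
) -> CompoundDensity:
    """Pointwise maximum of the per-pattern density curves.

    When `span_ms` is given, the compound is restricted to the post-trigger
    analysis span [0, span_ms]; pass None to keep the full shared grid.
    """
    if len(kdes) == 0:
        raise ValueError("at least one density curve is required")
    grid = kdes[0].time_grid
    for k in kdes[1:]:
        if k.time_grid.shape != grid.shape or not np.allclose(k.time_grid, grid):
            raise ValueError("density curves must share the time grid")
    values = np.max(np.vstack([k.values for k in kdes]), axis=0)
    if span_ms is not None:
        sel = (grid >= -1e-9) & (grid <= span_ms + 1e-9)
        grid, values = grid[sel], values[sel]
    return CompoundDensity(grid, values)


def local_minima_boundaries(values: np.ndarray) -> np.ndarray:
    """Indices of interior local minima, with the plateau rule.

    A maximal flat run that sits strictly below both neighbours contributes
    a single boundary at its midpoint, which avoids zero-width windows.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    out = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j < n - 1 and v[i - 1] > v[i] and v[j + 1] > v[i]:
            out.append((i + j) // 2)
        i = j + 1
    return np.asarray(out, dtype=int)


def segment_windows(
    compound: CompoundDensity,
    auc_floor: float = AUC_FLOOR,
) -> TimeWindowSet:
    """Segment a compound density at its interior local minima.

    Per-window AUC uses the trapezoidal rule after subtracting the lowest
    value occurring within the window; AUCs are normalized to the largest
    window and windows below `auc_floor` of it are dropped.  An all-zero
    compound yields a degenerate zero-window set.
    """
    grid, v = compound.time_grid, compound.values
    if grid.size == 0:
        raise ValueError("empty compound density")
    if not np.any(v > 0):
        empty = np.empty(0)
        return TimeWindowSet(np.asarray([grid[0], grid[-1]]), empty, empty,
                             np.empty(0, dtype=bool), auc_floor)
    cuts = local_minima_boundaries(v)
    edges = np.concatenate(([0], cuts, [grid.size - 1]))
    aucs = []
    for a, b in zip(edges[:-1], edges[1:]):
        seg = v[a:b + 1]
        aucs.append(np.trapezoid(seg - seg.min(), grid[a:b + 1]))
    aucs = np.asarray(aucs)
    top = aucs.max()
    normalized = aucs / top if top > 0 else aucs
    kept = normalized >= auc_floor
    return TimeWindowSet(grid[edges], aucs, normalized, kept, auc_floor)


def qualify_neuron(
    kdes: Sequence[DensityCurve],
    min_peaks: int = 3,
    amplitude_factor: float = 2.0,
    max_rise_ms: float = 50.0,
    span_ms: float = ANALYSIS_SPAN_MS,
) -> tuple[bool, dict]:
    """Inclusion criterion for the decoding analysis.

    A neuron qualifies when, pooled across its per-pattern density curves,
    at least `min_peaks` peaks exceed ``amplitude_factor`` times the curve's
    pretrigger baseline (100%) and do so within `max_rise_ms` of the last
    upward baseline crossing preceding the peak.  Curves with a zero
    baseline cannot be expressed in percent of baseline and are rejected.
    """
    qualifying = 0
    per_curve = []
    for k in kdes:
        base = k.baseline()
        if base <= 0:
            raise DegenerateBaselineError(
                "zero pretrigger baseline; qualification undefined")
        sel = (k.time_grid >= -1e-9) & (k.time_grid <= span_ms + 1e-9)
        grid, v = k.time_grid[sel], k.values[sel]
        peaks = []
        for i in range(1, v.size - 1):
            if v[i] > v[i - 1] and v[i] >= v[i + 1] \
                    and v[i] > amplitude_factor * base:
                # Last upward crossing of the baseline before the peak.
                below = np.flatnonzero(v[:i] <= base)
                onset_idx = below[-1] if below.size else 0
                if grid[i] - grid[onset_idx] <= max_rise_ms:
                    peaks.append((float(grid[i]), float(v[i])))
        qualifying += len(peaks)
        per_curve.append(peaks)
    return qualifying >= min_peaks, {
        "n_qualifying_peaks": qualifying,
        "peaks_per_curve": per_curve,
    }
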