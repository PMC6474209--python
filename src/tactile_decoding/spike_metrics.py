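"""Per-neuron spike response metrics.

PSTH construction, onset-latency and response-intensity estimation against
the pretrigger baseline, and kernel-density (spike density function)
representation of the average evoked response, one curve per stimulation
pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SweepSet",
    "Psth",
    "DensityCurve",
    "DegenerateBaselineError",
    "compute_psth",
    "response_latency",
    "response_intensity",
    "bandwidth_cost",
    "optimal_bandwidth",
    "default_bandwidth_grid",
    "compute_kde",
]


class DegenerateBaselineError(ValueError):
    """Raised when a baseline statistic needed by a rule is undefined."""


@dataclass
class SweepSet:
    """Spike-time sweeps of one neuron, grouped by stimulation pattern.

    Spike times are in ms relative to stimulus onset; negative times are
    pretrigger activity.
    """

    neuron_id: str
    sweeps: dict[str, list[np.ndarray]]
    pretrigger_span: float = 500.0
    posttrigger_span: float = 1000.0
    area_tag: str = "S1"
    depth: float = 500.0

    def __post_init__(self) -> None:
        clean: dict[str, list[np.ndarray]] = {}
        for label, trials in self.sweeps.items():
            if len(trials) == 0:
                raise ValueError(f"pattern {label!r} has no sweeps")
            rows = [np.asarray(t, dtype=float) for t in trials]
            for t in rows:
                if t.size and (t.min() < -self.pretrigger_span - 1e-9 or
                               t.max() > self.posttrigger_span + 1e-9):
                    raise ValueError("spike time outside sweep span")
            clean[label] = rows
        self.sweeps = clean

    @property
    def labels(self) -> list[str]:
        return list(self.sweeps)

    def n_trials(self, label: str) -> int:
        return len(self.sweeps[label])

    def pooled(self, label: Optional[str] = None) -> np.ndarray:
        """All spike times of one pattern (or of every pattern), pooled."""
        if label is not None:
            parts = self.sweeps[label]
        else:
            parts = [t for trials in self.sweeps.values() for t in trials]
        if not parts:
            return np.empty(0)
        return np.sort(np.concatenate(parts))


@dataclass
class Psth:
    bin_size: float
    bin_edges: np.ndarray
    rates: np.ndarray          # Hz per bin
    baseline_mean: float       # Hz, pretrigger bins only
    baseline_sd: float
    n_sweeps: int

    @property
    def post_mask(self) -> np.ndarray:
        return self.bin_edges[:-1] >= -1e-9


def compute_psth(
    sweeps: Sequence[np.ndarray],
    bin_size: float = 5.0,
    pre_span: float = 500.0,
    post_span: float = 500.0,
) -> Psth:
    """Peristimulus time histogram pooled over sweeps.

    Rate per bin is pooled spike count / (n_sweeps * bin_size).  Baseline
    mean and SD are computed from the pretrigger bins only.
    """
    if len(sweeps) == 0:
        raise ValueError("at least one sweep is required")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_pre = int(round(pre_span / bin_size))
    n_post = int(round(post_span / bin_size))
    if n_pre < 1 or n_post < 1:
        raise ValueError("spans must cover at least one bin each")
    edges = (np.arange(n_pre + n_post + 1) - n_pre) * bin_size
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in sweeps]) \
        if any(len(s) for s in sweeps) else np.empty(0)
    counts, _ = np.histogram(pooled, bins=edges)
    rates = counts / (len(sweeps) * bin_size / 1000.0)
    pre_rates = rates[:n_pre]
    return Psth(
        bin_size=bin_size,
        bin_edges=edges,
        rates=rates,
        baseline_mean=float(pre_rates.mean()),
        baseline_sd=float(pre_rates.std(ddof=0)),
        n_sweeps=len(sweeps),
    )


def response_latency(
    psth: Psth,
    threshold_sd: float = 3.0,
    min_consecutive: int = 2,
) -> Optional[float]:
    """Onset latency: start of the first run of >= `min_consecutive`
    consecutive post-trigger bins exceeding baseline + `threshold_sd` SD.

    Returns None when no qualifying run exists.
    """
    n_pre = int(np.sum(psth.bin_edges[:-1] < -1e-9))
    if n_pre < 2:
        raise DegenerateBaselineError(
            "baseline SD undefined with a single pretrigger bin")
    thr = psth.baseline_mean + threshold_sd * psth.baseline_sd
    post_idx = np.flatnonzero(psth.post_mask)
    above = psth.rates[post_idx] > thr
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_consecutive:
            start = post_idx[i - min_consecutive + 1]
            return float(psth.bin_edges[start])
    return None


def response_intensity(psth: Psth, latency: float) -> float:
    """Maximal rate change from baseline, in baseline-SD units, over
    [latency, end of histogram]."""
    if psth.baseline_sd <= 0:
        raise DegenerateBaselineError("baseline SD is zero")
    sel = psth.bin_edges[:-1] >= latency - 1e-9
    if not sel.any():
        raise ValueError("latency beyond histogram range")
    return float((psth.rates[sel].max() - psth.baseline_mean) / psth.baseline_sd)


# ---------------------------------------------------------------------------
# Kernel density estimation of the evoked response
# ---------------------------------------------------------------------------

@dataclass
class DensityCurve:
    """Spike density function on a uniform 1 ms grid.

    Units are spikes s^-1 per trial (the Gaussian-kernel sum is divided by
    the number of sweeps), so curves from different trial counts are
    comparable.
    """

    time_grid: np.ndarray
    values: np.ndarray
    bandwidth: float
    n_spikes: int
    n_sweeps: int
    is_empty: bool = False
    pretrigger_span: float = 500.0

    def baseline(self) -> float:
        """Mean density over the pretrigger part of the grid."""
        pre = self.time_grid < 0
        if not pre.any():
            raise DegenerateBaselineError("grid has no pretrigger samples")
        return float(self.values[pre].mean())


def _gauss(d: np.ndarray, w: float) -> np.ndarray:
    return np.exp(-0.5 * (d / w) ** 2) / (w * np.sqrt(2.0 * np.pi))


def bandwidth_cost(spike_times: np.ndarray, w: float) -> float:
    """Least-squares cross-validation cost of a Gaussian kernel of SD `w`.

    C(w) = sum_{i,j} phi(d_ij; sqrt(2) w) - 2 sum_{i!=j} phi(d_ij; w),
    where phi is the Gaussian density.  The bandwidth minimizing this cost
    minimizes the mean integrated squared error of the fixed-kernel rate
    estimate.
    """
    x = np.asarray(spike_times, dtype=float)
    d = x[:, None] - x[None, :]
    term1 = _gauss(d, np.sqrt(2.0) * w).sum()
    off = ~np.eye(x.size, dtype=bool)
    term2 = _gauss(d[off], w).sum()
    return float(term1 - 2.0 * term2)


def default_bandwidth_grid(
    low: float = 1.0, high: float = 200.0, num: int = 50
) -> np.ndarray:
    return np.geomspace(low, high, num)


def optimal_bandwidth(
    spike_times: Sequence[float],
    candidates: Optional[np.ndarray] = None,
) -> float:
    """Cost-minimizing Gaussian kernel bandwidth on a candidate grid.

    Ties are broken toward the smallest candidate.  Requires >= 2 spikes.
    """
    x = np.asarray(spike_times, dtype=float)
    if x.size < 2:
        raise ValueError("bandwidth optimization requires at least 2 spikes")
    if candidates is None:
        candidates = default_bandwidth_grid()
    # Upper-triangle distances are reused across candidates; the cost only
    # depends on |x_i - x_j|, so each off-diagonal pair is counted twice.
    iu = np.triu_indices(x.size, k=1)
    u = (x[:, None] - x[None, :])[iu]
    n = x.size
    best_w, best_c = None, np.inf
    for w in candidates:
        term1 = n * _gauss(np.zeros(1), np.sqrt(2.0) * w)[0] \
            + 2.0 * _gauss(u, np.sqrt(2.0) * w).sum()
        term2 = 4.0 * _gauss(u, w).sum()
        c = term1 - term2
        if c < best_c - 1e-12:
            best_c, best_w = c, float(w)
    return best_w


def compute_kde(
    sweeps_for_pattern: Sequence[np.ndarray],
    pretrigger_span: float = 500.0,
    posttrigger_span: float = 1000.0,
    bandwidth: Optional[float] = None,
    fallback_bandwidth: float = 10.0,
    candidates: Optional[np.ndarray] = None,
    truncate: float = 5.0,
) -> DensityCurve:
    """Spike density function of one pattern's pooled sweeps.

    Spikes are pooled over trials before bandwidth optimization; each spike
    contributes a Gaussian kernel truncated at +/- `truncate` bandwidths.
    The curve is evaluated on the 1 ms grid [-pretrigger, posttrigger].
    Zero total spikes yield a flat zero curve flagged `is_empty`.
    """
    grid = np.arange(-pretrigger_span, posttrigger_span + 0.5)
    pooled_parts = [np.asarray(s, dtype=float) for s in sweeps_for_pattern]
    pooled = (np.concatenate(pooled_parts)
              if any(p.size for p in pooled_parts) else np.empty(0))
    n_sweeps = max(len(sweeps_for_pattern), 1)
    if pooled.size == 0:
        return DensityCurve(grid, np.zeros_like(grid), fallback_bandwidth,
                            0, n_sweeps, is_empty=True,
                            pretrigger_span=pretrigger_span)
    if bandwidth is None:
        if pooled.size >= 2:
            bandwidth = optimal_bandwidth(pooled, candidates)
        else:
            bandwidth = fallback_bandwidth
    values = np.zeros_like(grid)
    half = truncate * bandwidth
    norm = 1000.0 / (n_sweeps * bandwidth * np.sqrt(2.0 * np.pi))
    for ts in np.sort(pooled):
        lo = int(np.searchsorted(grid, ts - half, side="left"))
        hi = int(np.searchsorted(grid, ts + half, side="right"))
        seg = grid[lo:hi]
        values[lo:hi] += norm * np.exp(-0.5 * ((seg - ts) / bandwidth) ** 2)
    return DensityCurve(grid, values, float(bandwidth), int(pooled.size),
                        n_sweeps, pretrigger_span=pretrigger_span)


def kdes_by_pattern(
    sweepset: SweepSet,
    **kwargs,
) -> dict[str, DensityCurve]:
    """One density curve per stimulation pattern of a neuron."""
    return {
        label: compute_kde(
            trials,
            pretrigger_span=sweepset.pretrigger_span,
            posttrigger_span=sweepset.posttrigger_span,
            **kwargs,
        )
        for label, trials in sweepset.sweeps.items()
    }
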