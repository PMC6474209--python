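"""Bootstrap kNN decoding of stimulation patterns from spike responses.

The decoding loop, run for `n_iterations` independent iterations:

1. (shuffled control only) permute the pattern labels across trials;
2. split each pattern's sweeps 50/50 into training and test sets;
3. within each set, combine `group_size` distinct sweeps at a time
   (continuous exponential-kernel signals, summed) into up to
   `target_combinations` bootstrapped responses, every sweep covered;
4. compute the AUC of each combined response in each kept time window and
   normalize per window to the set-wide maximum (features in [0, 1]);
5. classify every test response by its 9 nearest training responses
   (Euclidean distance in window space) and tally a confusion matrix.

The mean decoding performance is the mean of the diagonal of the
iteration-averaged confusion matrix; chance is 100/K % for K classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .segmentation import (ANALYSIS_SPAN_MS, AUC_FLOOR, TimeWindowSet,
                           compound_density, segment_windows)
from .spike_metrics import SweepSet, kdes_by_pattern

logger = logging.getLogger(__name__)

__all__ = [
    "DecoderParams",
    "ConfusionMatrix",
    "DecodingResult",
    "BootstrapError",
    "sweep_to_signal",
    "signals_on_grid",
    "bootstrap_combine",
    "featurize",
    "normalize_per_window",
    "knn_classify",
    "shuffle_assignment",
    "ChannelData",
    "run_decoding",
    "decode_neuron",
    "shuffled_control",
    "time_window_evolution",
    "derive_windows",
]


class BootstrapError(RuntimeError):
    """Fewer non-empty sweeps than the bootstrap group size."""


@dataclass
class DecoderParams:
    """Decoding-analysis constants.

    kernel_tau: exponential-kernel time constant (ms) for the spike-to-
        signal conversion.
    group_size: sweeps summed per bootstrap combination (10; 3 in the
        ECoG-state-conditioned analysis).
    target_combinations: bootstrapped responses per set and pattern.
    k_neighbors: kNN neighbourhood size.
    n_iterations: independent split/bootstrap repetitions averaged.
    analysis_span: post-trigger integration window (ms).
    """

    kernel_tau: float = 5.0
    group_size: int = 10
    target_combinations: int = 200
    k_neighbors: int = 9
    n_iterations: int = 50
    auc_floor: float = AUC_FLOOR
    split_fraction: float = 0.5
    analysis_span: float = ANALYSIS_SPAN_MS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kernel_tau", "group_size", "target_combinations",
                     "k_neighbors", "n_iterations", "analysis_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")


@dataclass
class ConfusionMatrix:
    labels: list[str]
    percentages: np.ndarray      # rows: true pattern, columns: assigned

    def diagonal_mean(self) -> float:
        return float(np.nanmean(np.diag(self.percentages)))


@dataclass
class DecodingResult:
    labels: list[str]
    mean_confusion: ConfusionMatrix
    per_iteration_performance: list[float]
    mean_decoding_performance: float
    shuffled: bool = False
    degenerate: bool = False      # e.g. zero usable windows


# ---------------------------------------------------------------------------
# Signal conversion and featurization
# ---------------------------------------------------------------------------

def sweep_to_signal(
    spike_times: Sequence[float],
    tau: float,
    grid: np.ndarray,
) -> np.ndarray:
    """Convolve spikes with a causal exponential kernel on a 1 ms grid:
    each spike at t_s adds exp(-(t - t_s)/tau) for t >= t_s."""
    signal = np.zeros(grid.size)
    spikes = np.asarray(spike_times, dtype=float)
    spikes = spikes[spikes <= grid[-1]]
    for ts in spikes:
        lo = int(np.searchsorted(grid, ts, side="left"))
        signal[lo:] += np.exp(-(grid[lo:] - ts) / tau)
    return signal


def signals_on_grid(
    sweeps: Sequence[np.ndarray],
    tau: float,
    grid: np.ndarray,
) -> np.ndarray:
    """(n_sweeps, n_grid) signal matrix; rows of spike-free sweeps are zero.

    Only spikes inside the analysis grid contribute (pretrigger activity is
    not part of the decoded response)."""
    out = np.zeros((len(sweeps), grid.size))
    t0, t1 = grid[0], grid[-1]
    for i, sw in enumerate(sweeps):
        sw = np.asarray(sw, dtype=float)
        sw = sw[(sw >= t0) & (sw <= t1)]
        if sw.size:
            out[i] = sweep_to_signal(sw, tau, grid)
    return out


def featurize(
    combined: np.ndarray,
    windows: TimeWindowSet,
    grid: np.ndarray,
) -> np.ndarray:
    """Raw per-kept-window trapezoidal AUCs of combined responses.

    `combined` may be a single signal (1-D) or a stack (n, n_grid); the
    result has one column per kept window.  Normalization to the set-wide
    window maxima is a separate step (`normalize_per_window`).
    """
    arr = np.atleast_2d(np.asarray(combined, dtype=float))
    # Cumulative trapezoid lets every window AUC be a difference of two
    # values.
    mids = 0.5 * (arr[:, 1:] + arr[:, :-1]) * np.diff(grid)
    cum = np.concatenate([np.zeros((arr.shape[0], 1)), np.cumsum(mids, axis=1)],
                         axis=1)
    cols = []
    for lo, hi in windows.kept_windows():
        a = int(np.searchsorted(grid, lo, side="left"))
        b = int(np.searchsorted(grid, hi, side="left"))
        cols.append(cum[:, b] - cum[:, a])
    feats = np.column_stack(cols) if cols else np.zeros((arr.shape[0], 0))
    return feats[0] if np.asarray(combined).ndim == 1 else feats


def normalize_per_window(feature_matrix: np.ndarray) -> np.ndarray:
    """Divide each column by its maximum over the whole set; all-zero
    columns stay zero."""
    out = np.array(feature_matrix, dtype=float)
    maxima = out.max(axis=0)
    zero = maxima <= 0
    if zero.any():
        logger.warning("window with zero AUC across the set; dimension "
                       "left at 0")
    maxima[zero] = 1.0
    return out / maxima


# ---------------------------------------------------------------------------
# Bootstrapping
# ---------------------------------------------------------------------------

def bootstrap_combine(
    signals: np.ndarray,
    group_size: int,
    target: int,
    rng: np.random.Generator,
    return_indices: bool = False,
):
    """Sum distinct `group_size`-subsets of the non-empty signal rows.

    Rows that are identically zero (spike-free sweeps) are excluded first.
    When the number of distinct subsets is at most `target`, all of them
    are used; otherwise `target` distinct subsets are sampled and, if any
    non-empty sweep ends up uncovered, one sampled subset is replaced by a
    fresh subset containing it, preserving both the target count and the
    guarantee that every sweep appears in at least one combination.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    nonempty = np.flatnonzero(signals.any(axis=1))
    if nonempty.size < group_size:
        raise BootstrapError(
            f"{nonempty.size} non-empty sweeps < group size {group_size}")
    subsets = _draw_subsets(nonempty.size, group_size, target, rng)
    idx = nonempty[subsets]
    combined = signals[idx].sum(axis=1)
    if return_indices:
        return combined, idx
    return combined


# ---------------------------------------------------------------------------
# kNN classification
# ---------------------------------------------------------------------------

def _knn_predict(
    test: np.ndarray,
    train: np.ndarray,
    train_labels: np.ndarray,
    k: int,
) -> np.ndarray:
    """Plurality vote among the k nearest training points (Euclidean).

    Vote ties are broken by the single nearest neighbour's label; exact
    distance ties resolve by training-set index (stable order), so the
    prediction is deterministic.
    """
    if train.shape[0] < k:
        raise ValueError("fewer training points than k")
    d = cdist(np.atleast_2d(test), train)
    n_labels = int(train_labels.max()) + 1
    n_train = train.shape[0]
    # Candidate pre-selection with a tie margin, then a stable
    # (distance, index) order among candidates: equal distances resolve
    # by training-set index.
    margin = min(k + 10, n_train)
    if margin < n_train:
        cand = np.argpartition(d, margin - 1, axis=1)[:, :margin]
        cand.sort(axis=1)
        cd = np.take_along_axis(d, cand, axis=1)
        sub = np.argsort(cd, axis=1, kind="stable")[:, :k]
        order = np.take_along_axis(cand, sub, axis=1)
    else:
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
    preds = np.empty(order.shape[0], dtype=int)
    for i, nbrs in enumerate(order):
        labs = train_labels[nbrs]
        counts = np.bincount(labs, minlength=n_labels)
        best = counts.max()
        winners = np.flatnonzero(counts == best)
        if winners.size == 1:
            preds[i] = winners[0]
        else:
            preds[i] = labs[0]        # neighbours are ordered nearest-first
    return preds


def knn_classify(
    test_feature: np.ndarray,
    training_features: np.ndarray,
    training_labels: Sequence,
    k: int = 9,
):
    """Classify one feature vector against a labeled training set."""
    labels = list(dict.fromkeys(training_labels))
    lab_to_int = {lab: i for i, lab in enumerate(labels)}
    y = np.asarray([lab_to_int[lab] for lab in training_labels])
    pred = _knn_predict(np.atleast_2d(test_feature), training_features, y, k)
    return labels[pred[0]]


# ---------------------------------------------------------------------------
# Decoding loop
# ---------------------------------------------------------------------------

@dataclass
class ChannelData:
    """One feature channel: per-class signal matrices sharing trial
    alignment, plus the window set defining the channel's dimensions."""

    signals: dict[str, np.ndarray]       # class -> (n_trials, n_grid)
    windows: TimeWindowSet
    grid: np.ndarray


def _split_indices(n: int, split_fraction: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified split; with odd counts the extra sweep trains."""
    perm = rng.permutation(n)
    n_test = int(np.floor(n * (1.0 - split_fraction)))
    return perm[n_test:], perm[:n_test]


def shuffle_assignment(
    n_trials: dict[str, int],
    rng: np.random.Generator,
) -> dict[str, list[tuple[str, int]]]:
    """Uniform random permutation of pattern labels across all trials.

    Returns, per class label, the list of (source_label, source_index)
    trials assigned to it; per-label trial counts are preserved.
    """
    flat = [(lab, i) for lab, n in n_trials.items() for i in range(n)]
    perm = rng.permutation(len(flat))
    out: dict[str, list[tuple[str, int]]] = {}
    pos = 0
    for lab, n in n_trials.items():
        out[lab] = [flat[j] for j in perm[pos:pos + n]]
        pos += n
    return out


def run_decoding(
    channels: Sequence[ChannelData],
    params: DecoderParams,
    shuffle_labels: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> DecodingResult:
    """Iterated split/bootstrap/kNN decoding over one or more channels.

    Channels must share class labels and per-class trial counts (trials are
    index-aligned, as for co-recorded neurons); features of all channels are
    concatenated.  Classes whose bootstrap fails in an iteration are dropped
    from that iteration's confusion matrix with a logged warning.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    labels = list(channels[0].signals)
    for ch in channels[1:]:
        if list(ch.signals) != labels:
            raise ValueError("channels must share class labels")
        for lab in labels:
            if ch.signals[lab].shape[0] != channels[0].signals[lab].shape[0]:
                raise ValueError("channels must share per-class trial counts")
    k_classes = len(labels)
    n_trials = {lab: channels[0].signals[lab].shape[0] for lab in labels}

    conf_sum = np.zeros((k_classes, k_classes))
    row_hits = np.zeros(k_classes)
    per_iter_perf: list[float] = []

    for _ in range(params.n_iterations):
        # Per-channel signal stacks for this iteration's class assignment.
        # In the shuffled control, pattern labels are permuted across all
        # trials before the split; the same permutation applies to every
        # channel since trials are index-aligned.
        if shuffle_labels:
            assignment = shuffle_assignment(n_trials, rng)
            iter_signals: dict[str, list[np.ndarray]] = {
                lab: [np.vstack([ch.signals[sl][si]
                                 for sl, si in assignment[lab]])
                      for ch in channels]
                for lab in labels
            }
        else:
            iter_signals = {lab: [ch.signals[lab] for ch in channels]
                            for lab in labels}

        train_feats, train_y = [], []
        test_feats, test_y = [], []
        present = []
        for ci, lab in enumerate(labels):
            stacks = iter_signals[lab]
            n = stacks[0].shape[0]
            # Split first (over all sweeps), then exclude spike-free sweeps
            # within each set before bootstrapping.
            tr, te = _split_indices(n, params.split_fraction, rng)
            nonzero = np.any([s.any(axis=1) for s in stacks], axis=0)
            tr_idx = tr[nonzero[tr]]
            te_idx = te[nonzero[te]]
            try:
                # Shared subset indices across channels: draw on trial
                # indices once, then sum each channel's rows.
                tr_sub = _draw_subsets(len(tr_idx), params.group_size,
                                       params.target_combinations, rng)
                te_sub = _draw_subsets(len(te_idx), params.group_size,
                                       params.target_combinations, rng)
            except BootstrapError:
                logger.warning("bootstrap failed for pattern %s", lab)
                continue
            tr_rows = [s[tr_idx][tr_sub].sum(axis=1) for s in stacks]
            te_rows = [s[te_idx][te_sub].sum(axis=1) for s in stacks]
            tr_f = np.column_stack([
                featurize(rows, ch.windows, ch.grid)
                for rows, ch in zip(tr_rows, channels)])
            te_f = np.column_stack([
                featurize(rows, ch.windows, ch.grid)
                for rows, ch in zip(te_rows, channels)])
            train_feats.append(tr_f)
            test_feats.append(te_f)
            train_y.append(np.full(tr_f.shape[0], ci))
            test_y.append(np.full(te_f.shape[0], ci))
            present.append(ci)

        if not present:
            raise BootstrapError("bootstrap failed for every class")
        X_tr = normalize_per_window(np.vstack(train_feats))
        X_te = normalize_per_window(np.vstack(test_feats))
        y_tr = np.concatenate(train_y)
        y_te = np.concatenate(test_y)
        pred = _knn_predict(X_te, X_tr, y_tr, params.k_neighbors)
        conf = np.zeros((k_classes, k_classes))
        for ci in present:
            sel = y_te == ci
            row = np.bincount(pred[sel], minlength=k_classes).astype(float)
            conf[ci] = row / row.sum() * 100.0
            row_hits[ci] += 1
        conf_sum += conf
        diag = [conf[ci, ci] for ci in present]
        per_iter_perf.append(float(np.mean(diag)))

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_conf = conf_sum / row_hits[:, None]
    mean_conf[row_hits == 0] = np.nan
    cm = ConfusionMatrix(labels, mean_conf)
    return DecodingResult(
        labels=labels,
        mean_confusion=cm,
        per_iteration_performance=per_iter_perf,
        mean_decoding_performance=cm.diagonal_mean(),
        shuffled=shuffle_labels,
    )


def _draw_subsets(n: int, group_size: int, target: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Distinct group_size-subsets of range(n) with full coverage, as an
    (m, group_size) index array.  Raises BootstrapError when n < group_size.
    """
    if n < group_size:
        raise BootstrapError(f"{n} sweeps < group size {group_size}")
    total = math.comb(n, group_size)
    if total <= target:
        return np.asarray(list(combinations(range(n), group_size)))
    chosen: dict[bytes, np.ndarray] = {}
    while len(chosen) < target:
        need = target - len(chosen)
        block = np.argsort(rng.random((need, n)), axis=1)[:, :group_size]
        block.sort(axis=1)
        for row in block:
            if len(chosen) >= target:
                break
            chosen.setdefault(row.tobytes(), row.copy())
    subsets = list(chosen.values())
    counts = np.zeros(n, dtype=int)
    for s in subsets:
        counts[s] += 1
    missing = list(np.flatnonzero(counts == 0))
    pos = 0
    while missing:
        m = missing.pop()
        others = np.delete(np.arange(n), m)
        extra = np.sort(np.concatenate(
            [[m], rng.choice(others, group_size - 1, replace=False)]))
        if extra.tobytes() in chosen:
            missing.append(m)
            continue
        # Replace a subset whose members all stay covered.
        while pos < len(subsets) and np.any(counts[subsets[pos]] <= 1):
            pos += 1
        if pos >= len(subsets):     # pragma: no cover - cannot happen for
            subsets.append(extra)   # target >= n / group_size
            counts[extra] += 1
            continue
        old = subsets[pos]
        counts[old] -= 1
        counts[extra] += 1
        del chosen[old.tobytes()]
        chosen[extra.tobytes()] = extra
        subsets[pos] = extra
        pos += 1
    return np.vstack(subsets)


# ---------------------------------------------------------------------------
# Per-neuron entry points
# ---------------------------------------------------------------------------

def derive_windows(
    sweepset: SweepSet,
    span_ms: float = ANALYSIS_SPAN_MS,
    auc_floor: float = AUC_FLOOR,
    kdes=None,
) -> TimeWindowSet:
    """Neuron-specific time windows from the compound of its per-pattern
    density curves over [0, span_ms]."""
    if kdes is None:
        kdes = kdes_by_pattern(sweepset)
    comp = compound_density(list(kdes.values()), span_ms=span_ms)
    return segment_windows(comp, auc_floor=auc_floor)


def _channel_for(sweepset: SweepSet, windows: TimeWindowSet,
                 params: DecoderParams) -> ChannelData:
    grid = np.arange(0.0, params.analysis_span + 0.5)
    signals = {
        lab: signals_on_grid(trials, params.kernel_tau, grid)
        for lab, trials in sweepset.sweeps.items()
    }
    return ChannelData(signals=signals, windows=windows, grid=grid)


def decode_neuron(
    sweepset: SweepSet,
    windows: TimeWindowSet,
    params: DecoderParams,
    rng: Optional[np.random.Generator] = None,
) -> DecodingResult:
    """Full single-neuron decoding of the stimulation patterns."""
    if windows.n_kept == 0:
        raise ValueError("no kept time windows; neuron cannot be decoded")
    return run_decoding([_channel_for(sweepset, windows, params)], params,
                        shuffle_labels=False, rng=rng)


def shuffled_control(
    sweepset: SweepSet,
    windows: TimeWindowSet,
    params: DecoderParams,
    rng: Optional[np.random.Generator] = None,
) -> DecodingResult:
    """Chance-level control: identical loop with pattern labels permuted
    across trials before each split."""
    if windows.n_kept == 0:
        raise ValueError("no kept time windows; neuron cannot be decoded")
    return run_decoding([_channel_for(sweepset, windows, params)], params,
                        shuffle_labels=True, rng=rng)


def time_window_evolution(
    sweepset: SweepSet,
    params: DecoderParams,
    durations: Sequence[float] = tuple(range(100, 1001, 100)),
    rng: Optional[np.random.Generator] = None,
) -> dict[float, DecodingResult]:
    """Decoding performance across growing integration windows.

    Windows are re-derived per truncated span.  A duration with zero kept
    windows yields a chance-level placeholder flagged `degenerate`.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    kdes = kdes_by_pattern(sweepset)
    out: dict[float, DecodingResult] = {}
    for dur in durations:
        windows = derive_windows(sweepset, span_ms=dur,
                                 auc_floor=params.auc_floor, kdes=kdes)
        p = replace(params, analysis_span=float(dur))
        if windows.n_kept == 0:
            labels = sweepset.labels
            k = len(labels)
            chance = np.full((k, k), 100.0 / k)
            out[dur] = DecodingResult(
                labels=labels,
                mean_confusion=ConfusionMatrix(labels, chance),
                per_iteration_performance=[],
                mean_decoding_performance=100.0 / k,
                degenerate=True,
            )
            continue
        out[dur] = run_decoding([_channel_for(sweepset, windows, p)], p,
                                rng=rng)
    return out
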