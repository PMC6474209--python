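# Methods

This note documents the models, numerical choices and limitations of the
`tactile_decoding` package in enough detail to reproduce or audit any step.

## Synthetic data model

The generator emulates the statistical structure of an anesthetized-rodent
tactile stimulation experiment; it is the ground-truth source for every
test in the package.

**Stimulation patterns.**  A pattern is a labeled set of four channels of
strictly increasing pulse times within < 350 ms.  Generic patterns draw
3–12 pulses per channel uniformly over the duration with a 2 ms refractory
spacing; distinctness is checked on the 1 ms binary raster.  A bundled
fixture (`data/canonical_patterns_synthetic.json`) provides eight labeled
patterns shaped like fast-adapting (dense onset bursts) versus slowly
adapting (sustained ~40 Hz trains) sensor output; these are illustrative
event lists written for this package — no published pulse-time tables
exist — and all quantitative tests use generated patterns instead.

**Sessions.**  Trials are blocks of shuffled label sets (every pattern
once per block, so counts stay balanced), separated by the inter-trial
interval (default 1800 ms, repetitions default 100; cohort analyses here
use 60, inside the 50–100 range the analysis assumes).

**Spiking neurons.**  A neuron is a baseline rate (default 5 Hz) plus, per
pattern, Gaussian rate bumps (peak time, peak rate, width); each bump is
expressed per trial with probability `reliability`.  Sweeps are drawn by
thinning, which is exact for an inhomogeneous Poisson process: candidates
at the ceiling rate `baseline + Σ peak_rates` are kept with probability
`λ(t)/λ_max`.  Consequences used by the tests: counts are Poisson (Fano
factor 1), a bump's spikes lie within its Gaussian support, and
`reliability = 0` makes all patterns statistically identical.  Cohort
neurons get 3 bumps per pattern at uniformly random times in [10, 500] ms,
peak rates 40–90 Hz, widths 4–12 ms, reliability 0.85 — deliberately
well-separated responses, so synthetic decoding performance is near
ceiling rather than at the modest levels real cortical neurons show.
Populations are "co-recorded": all neurons share one schedule, so trial
indices align across neurons.

**LFP traces.**  Gaussian noise plus, after each trial onset, a
negative-going alpha-shaped deflection `−A·x·e^(1−x)`,
`x = (t − onset − latency)/width`, which starts abruptly at the nominal
latency (default 8 ms) — this makes onset-latency recovery well-defined.
Synthetic traces are sampled at 10 kHz and the detector's decimation
factor rescales accordingly; the chain is otherwise identical to the
100 kHz case.

**ECoG.**  1 kHz traces; synchronized epochs add a large (amplitude 60)
slow oscillation around 2.5 Hz to the broadband noise floor (SD 8), so
summed 0–12 Hz power differs by well over an order of magnitude between
states.

What the generator does **not** emulate: bursting and refractory spike
statistics, correlated trial-to-trial variability, 1/f LFP background,
movement or electrode artifacts, and realistic effect sizes.  Passing
tests therefore demonstrate correctness and calibration of the analysis,
not expected performance on real recordings.

## Response metrics

PSTHs use 5 ms bins over 500 ms pre/post spans; rate = pooled count /
(n_sweeps × bin width).  Baseline statistics come from pretrigger bins
only.  Onset latency is the start of the first run of ≥ 2 consecutive
post-trigger bins above baseline + 3 SD; response intensity is the
maximal rate excess after that latency, in baseline-SD units.

KDE bandwidth minimizes the Gaussian-kernel least-squares cross-validation
cost on 50 log-spaced candidates in [1, 200] ms (ties → smallest).  Spikes
are pooled across trials before optimization; per-trial optimization would
starve the estimator at low rates.  Curves are evaluated on the 1 ms grid
spanning pretrigger and post-trigger; kernels are truncated at ±5
bandwidths and no boundary correction is applied — windows are defined
relative to within-grid peaks, so edge bias is shared across patterns.
Densities are expressed as spikes·s⁻¹ per trial (kernel sum divided by the
number of sweeps) so curves from different trial counts are comparable.
Fewer than 2 spikes falls back to a configured default bandwidth (10 ms);
zero spikes yields a flagged flat curve.

## Segmentation and qualification

The compound density is the pointwise maximum of the eight curves over the
analysis span (default [0, 600] ms, configurable 100–1000 ms).  Boundaries
are interior strict local minima; a flat run that is a local minimum
contributes one boundary at its midpoint, avoiding zero-width windows.
Window AUC is trapezoidal after subtracting the within-window minimum;
normalized AUCs below 0.025 of the maximum are dropped before any window
counting.  Qualification requires ≥ 3 peaks, pooled over the eight curves,
exceeding 200 % of that curve's pretrigger-mean baseline within 50 ms of
the last upward baseline crossing preceding the peak.  "Deviation from
baseline" is operationalized as that last crossing; because kernels are
truncated, KDE curves genuinely return to baseline between well-separated
peaks, which keeps the rule well-defined.  Zero-baseline curves cannot be
expressed in percent of baseline and raise a degenerate-baseline error.

## Decoding

Signals: causal exponential kernel, τ = 5 ms, on the 1 ms analysis grid;
only spikes inside the analysis window contribute, and a sweep with no
such spikes counts as spike-free.  Per iteration (default 50): a 50/50
random split per pattern (odd counts send the extra sweep to training),
then per set, distinct N-subsets (N = 10; 3 in the state-conditioned mode)
of the non-spike-free sweeps are summed into bootstrapped responses, up to
200 per set; when fewer distinct subsets exist, all are used.  Coverage is
enforced by replacing sampled subsets with subsets containing any missed
sweep (only replacing subsets whose members remain covered elsewhere), so
both the target count and the every-sweep-covered guarantee hold.  A
pattern whose usable sweeps fall below N in either set is dropped from
that iteration's confusion matrix with a logged warning; its row is
averaged only over iterations where it was present.

Features are per-window trapezoidal AUCs, normalized per window to the
maximum over all combined responses of that set (training and test
normalized independently — faithful to the procedure even though it leaks
no labels).  Classification is kNN with k = 9 under Euclidean distance;
the plurality label wins, vote ties go to the single nearest neighbour's
label, and exact distance ties order by training-set index, so predictions
are deterministic.  (Strict majority of 9 among 8 classes would leave most
queries unclassifiable, hence plurality.)  Windows are derived once per
neuron from the full data, not re-derived per split.  The shuffled control
permutes pattern labels uniformly across all trials before each split.

Cooperative decoding greedily adds the neuron maximizing joint performance
on concatenated per-neuron window features (normalization stays per neuron
per window per set).  Within a scan step all candidates are evaluated with
identical derived seeds, so splits and trial-subset draws are paired
across candidates; performance ties keep the lower neuron index.
Combined responses for an ensemble are built from the same trial subsets
in every member (co-recorded trials), and a trial counts as usable if any
member fired on it.  Inter-neuron confusion matrices reuse the same
machinery with classes = neuron identities and windows derived from the
pooled compound of the compared neurons' curves for the one pattern.

## LFP detectors

SE-LFP: per time point the most extreme 50 % of sweep values are trimmed
(symmetric: the central half is kept) and averaged; baseline mean/SD come
from 100 ms of pretrigger of that trimmed average; detection requires the
average to drop below −5 SD within 100 ms post-trigger.  Latency, duration
and amplitude are read from the filtered average — a running median of
window 10 samples by default, with a moving-average switch (the method's
name and its parenthetical disagree in the source description; the median
reading was kept primary) — at the −2 SD crossings, amplitude as the
minimum inside the response.

Pattern-evoked LFPs: 10 ms rolling boxcar mean, decimation to 1 kHz,
first-order Butterworth band-pass 50–499 Hz applied forward-backward
(zero-phase, so onsets are unbiased — a choice, not a given), pretrigger-
median DC removal; events are runs of ≥ 10 ms below baseline − 2 SD
(baseline from the 400 ms pre epoch); an event starting before the trigger
is tagged "pre" even when it crosses it.  Event AUC is reconstructed as
|amplitude| × duration (boxcar).  Note the 10 ms boxcar widens brief dips:
an 8 ms raw deflection can still produce a ≥ 10 ms filtered excursion, so
the duration gate is a statement about the filtered signal, and the unit
tests exercise it at that level.  Pre/post comparisons use the Wilcoxon
signed-rank test on paired per-sweep values.

## Brain states

Segments of 1000 ms with 125 ms overlap (hop 875 ms), mean-detrended, no
taper; compound power is the periodogram sum over the closed band
[0, 12] Hz.  Desynchronized epochs are runs of ≥ 2 consecutive segments
strictly below the recording-wide median.  For interval tiling, segment k
owns [k·hop, (k+1)·hop) with the last segment owning through the trace
end; "start within a desynchronized segment" is read as within such a
merged interval, and a presentation is desynchronized only when more than
350 ms of the interval remains after its onset.  State-conditioned
decoding reruns the standard decoder per state with N = 3; patterns with
too few usable sweeps in a state are dropped with warnings.

## Cohort statistics

Layers from depth with half-open bins [lower, upper) at 157, 575, 900,
1411, 1973 µm (the boundary-membership convention is not prescribed
anywhere; half-open was chosen and is asserted in tests).  Group
comparisons wrap scipy.stats (rank-sum, Mann-Whitney, signed-rank,
Kruskal-Wallis, Pearson).  Raw p-values are reported by default; a Holm
step-down option exists for users who want multiplicity control.

## Problem sizes and seeds

Every random step takes a `numpy` Generator or an integer seed; derived
seeds come from `SeedSequence.spawn`, and identical (data, seed) pairs
reproduce results bit-for-bit.  The packaged analyses run at desk scale:
cohorts of 12–20 neurons, 24–60 trials per pattern, and reduced iteration
counts in unit tests (the calibration suite runs the full 50-iteration,
N = 10, 200-combination configuration on a 20-neuron cohort).  Chance-
level simulations use 20 iterations; property tests use 5–30 seeded
instances per rule.

## Known limitations

- The qualification rule's "deviation from baseline" depends on the curve
  actually returning to baseline; extremely high sustained firing could
  push rise times past 50 ms and exclude otherwise responsive neurons.
- Exhaustive enumeration of bootstrap subsets is only attempted when the
  binomial count is at or below the target, so memory stays bounded; the
  sampled regime relies on collision-free sampling, which is essentially
  guaranteed at the default sizes.
- The cooperative search is greedy and therefore not guaranteed to find
  the best subset of a given size; it reproduces the forward-selection
  procedure exactly, including its path dependence.
- The ECoG segmenter assumes a stationary median; long nonstationary
  recordings would need a rolling reference.
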