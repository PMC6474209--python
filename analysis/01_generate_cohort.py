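#!/usr/bin/env python
"""Generate the synthetic experiment this analysis runs on.

Eight 4-channel spatiotemporal stimulation patterns, a pseudo-random
session schedule (60 presentations per pattern, 1.8 s apart), and a
co-recorded cohort of 12 pattern-selective neurons (5 Hz baseline, three
pattern-specific Gaussian response bumps each, reliability 0.85, half
tagged S1 / half non-S1).  Writes the session bundle, patterns and tidy
sweep table under results/data/.
"""

import sys
from pathlib import Path

from tactile_decoding import io
from tactile_decoding.synthetic import (generate_population_sweeps,
                                        generate_patterns, make_cohort_specs,
                                        make_schedule)

SEED = 7
N_NEURONS = 12
TRIALS = 60

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    patterns = generate_patterns(SEED, n_patterns=8)
    labels = [p.label for p in patterns]
    schedule = make_schedule(labels, repetitions_per_pattern=TRIALS,
                             seed=SEED + 1)
    specs = make_cohort_specs(N_NEURONS, labels, SEED + 2)
    sweepsets = generate_population_sweeps(specs, schedule, SEED + 3)

    io.write_patterns(OUT / "patterns.json", patterns)
    io.write_session_bundle(OUT / "session.json", sweepsets, schedule)
    io.write_sweeps(OUT / "sweeps.tsv", sweepsets)

    n_spikes = sum(len(t) for ss in sweepsets
                   for trials in ss.sweeps.values() for t in trials)
    print(f"generated {len(patterns)} patterns, "
          f"{len(schedule.trial_labels)} trials, "
          f"{N_NEURONS} neurons, {n_spikes} spikes")
    print(f"wrote {OUT}/patterns.json, session.json, sweeps.tsv")


if __name__ == "__main__":
    sys.exit(main())
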