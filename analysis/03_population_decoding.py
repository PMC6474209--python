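#!/usr/bin/env python
"""Population analyses: inter-neuron discrimination and cooperative decoding.

First, the five best-decoding neurons are compared against each other on a
single stimulation pattern (classes = neuron identities, chance 20%).
Second, greedy cooperative decoding over the cohort at response durations
of 200-600 ms: at each duration the best single neuron is found and
neurons are added greedily while the concatenated window features improve
kNN decoding.  Reads results/decoding/neurons.json; writes results/population/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from tactile_decoding import io
from tactile_decoding.decoder import DecoderParams
from tactile_decoding.population import (cooperative_decode,
                                         inter_neuron_confusion)

SEED = 29
ROOT = Path(__file__).resolve().parent.parent / "results"
DURATIONS = [200.0, 400.0, 600.0]


def main() -> None:
    sweepsets, _ = io.read_session_bundle(ROOT / "data" / "session.json")
    records = json.loads((ROOT / "decoding" / "neurons.json").read_text())
    out = ROOT / "population"
    out.mkdir(parents=True, exist_ok=True)
    by_perf = sorted(records, key=lambda r: -r["mean_decoding_performance"])
    top5_ids = [r["neuron_id"] for r in by_perf[:5]]
    by_id = {ss.neuron_id: ss for ss in sweepsets}
    top5 = [by_id[i] for i in top5_ids]
    params = DecoderParams(n_iterations=20, seed=SEED)

    pattern = top5[0].labels[0]
    res = inter_neuron_confusion(top5, pattern, params)
    np.savetxt(out / f"inter_neuron_confusion_{pattern}.tsv",
               res.mean_confusion.percentages, delimiter="\t", fmt="%.4f",
               header="\t".join(res.labels))
    print(f"inter-neuron discrimination on {pattern} "
          f"({len(top5)} neurons, chance 20%): "
          f"{res.mean_decoding_performance:.1f}%")

    coop = cooperative_decode(top5, params, durations=DURATIONS,
                              max_neurons=5)
    payload = []
    for c in coop:
        payload.append({
            "duration": c.duration,
            "selected_neurons": c.selected_neurons,
            "performance_per_step": c.performance_per_step,
            "dimensionality_per_step": c.dimensionality_per_step,
        })
        best_single = c.performance_per_step[0] if c.performance_per_step \
            else float("nan")
        best_coop = max(c.performance_per_step) if c.performance_per_step \
            else float("nan")
        print(f"{c.duration:.0f} ms: best single {best_single:.1f}%, "
              f"best cooperative {best_coop:.1f}% "
              f"({c.selected_neurons})")
    (out / "cooperative.json").write_text(json.dumps(payload, indent=1))


if __name__ == "__main__":
    sys.exit(main())
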