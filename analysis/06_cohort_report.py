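#!/usr/bin/env python
"""Cohort summary: laminar grouping, time evolution and report tables.

Assigns each decoded neuron a cortical layer from its recording depth,
tests layer dependence of decoding per area (Kruskal-Wallis), computes the
time evolution of decoding for one example neuron over integration windows
of 100-1000 ms, and writes the combined report tables.  Reads
results/decoding/neurons.json; writes results/report/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from tactile_decoding import io
from tactile_decoding.cohort import build_report
from tactile_decoding.decoder import DecoderParams, time_window_evolution

SEED = 71
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = json.loads((ROOT / "decoding" / "neurons.json").read_text())
    sweepsets, _ = io.read_session_bundle(ROOT / "data" / "session.json")
    out = ROOT / "report"
    out.mkdir(parents=True, exist_ok=True)

    # time evolution for the best-decoding neuron, reduced iteration count
    best = max(records, key=lambda r: r["mean_decoding_performance"])
    ss = next(s for s in sweepsets if s.neuron_id == best["neuron_id"])
    params = DecoderParams(n_iterations=10, seed=SEED)
    evo = time_window_evolution(ss, params)
    best["time_evolution"] = {d: r.mean_decoding_performance
                              for d, r in evo.items()}
    print(f"time evolution for {best['neuron_id']}:")
    for d, perf in best["time_evolution"].items():
        print(f"  0-{d:.0f} ms: {perf:.1f}%")

    tables = build_report(records)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    print("\nper-(area, layer) decoding:")
    print(tables["by_area_layer"].to_string(index=False))
    if not tables["layer_tests"].empty:
        print("\nlayer dependence (Kruskal-Wallis):")
        print(tables["layer_tests"].to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
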