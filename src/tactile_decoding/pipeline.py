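"""End-to-end synthetic experiment runner.

generate -> qualify -> segment -> decode (+ shuffled control) ->
cooperative -> LFP -> ECoG states -> report.  Each stage writes JSON
metadata and delimited tables to its own directory under the configured
output directory, and a manifest records the seed and per-stage timings,
so two runs with the same (config, seed) produce identical bundles.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io
from .brain_state import (classify_stimulus_state, segment_states,
                          state_conditioned_decoding)
from .cohort import build_report
from .config import RunConfig
from .decoder import (BootstrapError, decode_neuron, derive_windows,
                      shuffled_control)
from .lfp import compare_pre_post, detect_pattern_lfps
from .population import cooperative_decode
from .segmentation import qualify_neuron
from .spike_metrics import kdes_by_pattern
from .synthetic import (extract_trace_sweeps, generate_ecog_trace,
                        generate_lfp_trace, generate_patterns,
                        generate_population_sweeps, make_cohort_specs,
                        make_schedule)

logger = logging.getLogger(__name__)

__all__ = ["run_experiment"]


def _subseed(root: np.random.SeedSequence, i: int) -> int:
    return int(root.spawn(i + 1)[i].generate_state(1)[0] % (2 ** 31))


def run_experiment(config: RunConfig) -> dict:
    """Run the full synthetic pipeline and return the results bundle."""
    if config.generator.n_neurons < 1:
        raise ValueError("config must request at least one neuron")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    timings: dict[str, float] = {}
    bundle: dict = {"seed": config.seed}

    t0 = time.perf_counter()
    patterns = generate_patterns(
        _subseed(root, 0),
        n_patterns=config.generator.n_patterns,
        n_channels=config.generator.n_channels,
        duration_ms=config.generator.pattern_duration_ms,
    )
    labels = [p.label for p in patterns]
    schedule = make_schedule(
        labels,
        repetitions_per_pattern=config.generator.repetitions_per_pattern,
        inter_trial_interval=config.generator.inter_trial_interval_ms,
        seed=_subseed(root, 1),
    )
    specs = make_cohort_specs(
        config.generator.n_neurons, labels, _subseed(root, 2),
        baseline_rate=config.generator.baseline_rate_hz,
        n_bumps=config.generator.n_bumps,
        reliability=config.generator.reliability,
    )
    sweepsets = generate_population_sweeps(
        specs, schedule, _subseed(root, 3),
        pretrigger_ms=config.generator.pretrigger_ms,
        posttrigger_ms=config.generator.posttrigger_ms,
    )
    gen_dir = out_dir / "generate"
    gen_dir.mkdir(exist_ok=True)
    io.write_patterns(gen_dir / "patterns.json", patterns)
    io.write_session_bundle(gen_dir / "session.json", sweepsets, schedule)
    timings["generate"] = time.perf_counter() - t0

    # Qualification and windows
    t0 = time.perf_counter()
    qualified = []
    windows_by_neuron = {}
    for ss in sweepsets:
        kdes = kdes_by_pattern(ss)
        ok, diag = qualify_neuron(list(kdes.values()))
        if not ok:
            logger.info("neuron %s excluded (%d qualifying peaks)",
                        ss.neuron_id, diag["n_qualifying_peaks"])
            continue
        windows = derive_windows(ss, span_ms=config.decoder.analysis_span,
                                 auc_floor=config.decoder.auc_floor,
                                 kdes=kdes)
        if windows.n_kept == 0:
            continue
        qualified.append(ss)
        windows_by_neuron[ss.neuron_id] = windows
    qual_dir = out_dir / "qualify"
    qual_dir.mkdir(exist_ok=True)
    (qual_dir / "qualified.json").write_text(json.dumps(
        [ss.neuron_id for ss in qualified]))
    for ss in qualified:
        io.write_windows(qual_dir / f"windows_{ss.neuron_id}.json",
                         windows_by_neuron[ss.neuron_id])
    timings["qualify"] = time.perf_counter() - t0
    bundle["n_qualified"] = len(qualified)

    # Single-neuron decoding and shuffled control
    t0 = time.perf_counter()
    neuron_records = []
    dec_dir = out_dir / "decode"
    dec_dir.mkdir(exist_ok=True)
    for i, ss in enumerate(qualified):
        rng = np.random.default_rng(_subseed(root, 100 + i))
        windows = windows_by_neuron[ss.neuron_id]
        res = decode_neuron(ss, windows, config.decoder, rng=rng)
        rec = {
            "neuron_id": ss.neuron_id,
            "area_tag": ss.area_tag,
            "depth": ss.depth,
            "n_windows": windows.n_kept,
            "mean_decoding_performance": res.mean_decoding_performance,
        }
        np.savetxt(dec_dir / f"confusion_{ss.neuron_id}.tsv",
                   res.mean_confusion.percentages, delimiter="\t", fmt="%.4f",
                   header="\t".join(res.labels))
        if config.run_shuffled_control:
            sh_rng = np.random.default_rng(_subseed(root, 200 + i))
            sh = shuffled_control(ss, windows, config.decoder, rng=sh_rng)
            rec["shuffled_performance"] = sh.mean_decoding_performance
        neuron_records.append(rec)
    (dec_dir / "neurons.json").write_text(json.dumps(neuron_records, indent=1))
    timings["decode"] = time.perf_counter() - t0
    bundle["neuron_records"] = neuron_records

    # Cooperative decoding on a leading subset of qualified neurons
    if config.run_cooperative and len(qualified) >= 2:
        t0 = time.perf_counter()
        coop = cooperative_decode(
            qualified[:config.cooperative_n_neurons], config.decoder,
            durations=config.cooperative_durations,
            max_neurons=min(10, config.cooperative_n_neurons),
        )
        coop_dir = out_dir / "coop"
        coop_dir.mkdir(exist_ok=True)
        (coop_dir / "cooperative.json").write_text(json.dumps([
            {"duration": c.duration,
             "selected_neurons": c.selected_neurons,
             "performance_per_step": c.performance_per_step,
             "dimensionality_per_step": c.dimensionality_per_step}
            for c in coop
        ], indent=1))
        timings["cooperative"] = time.perf_counter() - t0
        bundle["cooperative"] = [c.__dict__ for c in coop]

    # Pattern-evoked LFP events
    t0 = time.perf_counter()
    lfp_trace = generate_lfp_trace(
        schedule, config.lfp.response_amplitude, config.lfp.noise_sd,
        _subseed(root, 4), sampling_rate_hz=config.lfp.sampling_rate_hz,
    )
    segs = extract_trace_sweeps(lfp_trace, schedule.trial_onsets,
                                config.lfp.pretrigger_ms,
                                config.lfp.posttrigger_ms)
    pre_counts, post_counts = [], []
    for seg in segs:
        events = detect_pattern_lfps(
            seg, config.lfp.sampling_rate_hz,
            pre_ms=config.lfp.pretrigger_ms,
            post_ms=config.lfp.posttrigger_ms,
            boxcar_ms=config.lfp.boxcar_ms,
            resample_to_hz=config.lfp.resample_to_hz,
            band_hz=tuple(config.lfp.band_hz),
        )
        pre_counts.append(sum(e.epoch_tag == "pre" for e in events))
        post_counts.append(sum(e.epoch_tag == "post" for e in events))
    lfp_dir = out_dir / "lfp"
    lfp_dir.mkdir(exist_ok=True)
    lfp_summary = {"mean_pre_events": float(np.mean(pre_counts)),
                   "mean_post_events": float(np.mean(post_counts))}
    try:
        lfp_summary["count_test"] = compare_pre_post(pre_counts, post_counts)
    except Exception as exc:   # degenerate comparisons on tiny runs
        lfp_summary["count_test"] = {"error": str(exc)}
    (lfp_dir / "summary.json").write_text(json.dumps(lfp_summary, indent=1))
    timings["lfp"] = time.perf_counter() - t0
    bundle["lfp"] = lfp_summary

    # ECoG state segmentation over the session span
    t0 = time.perf_counter()
    session_ms = float(schedule.trial_onsets[-1]) + 2000.0
    epoch = config.ecog.state_epoch_ms
    state_sched, cursor, state = [], 0.0, "synchronized"
    while cursor < session_ms:
        end = min(cursor + epoch, session_ms)
        state_sched.append((cursor, end, state))
        state = ("desynchronized" if state == "synchronized"
                 else "synchronized")
        cursor = end
    ecog = generate_ecog_trace(session_ms, state_sched, _subseed(root, 5),
                               sampling_rate_hz=config.ecog.sampling_rate_hz)
    seg = segment_states(ecog, segment_ms=config.ecog.segment_ms,
                         overlap_ms=config.ecog.overlap_ms,
                         band_hz=tuple(config.ecog.band_hz))
    trial_states_list = [classify_stimulus_state(o, seg)
                         for o in schedule.trial_onsets]
    states_dir = out_dir / "states"
    states_dir.mkdir(exist_ok=True)
    with open(states_dir / "intervals.tsv", "w") as fh:
        fh.write("start_ms\tend_ms\tlabel\n")
        for a, b, s in seg.state_intervals:
            fh.write(f"{a:.1f}\t{b:.1f}\t{s}\n")
    bundle["desync_fraction"] = float(np.mean(
        [s == "desynchronized" for s in trial_states_list]))

    # State-conditioned decoding for the first qualified neuron
    if qualified:
        ss = qualified[0]
        trial_states = {
            lab: [trial_states_list[i] for i in schedule.trials_for(lab)]
            for lab in ss.sweeps
        }
        try:
            state_res = state_conditioned_decoding(
                ss, trial_states, windows_by_neuron[ss.neuron_id],
                config.decoder,
                rng=np.random.default_rng(_subseed(root, 6)))
            bundle["state_decoding"] = {
                st: r.mean_decoding_performance
                for st, r in state_res.items()}
        except BootstrapError as exc:
            logger.warning("state-conditioned decoding failed: %s", exc)
            bundle["state_decoding"] = {}
    timings["states"] = time.perf_counter() - t0

    # Report
    t0 = time.perf_counter()
    if neuron_records:
        report = build_report(neuron_records)
        rep_dir = out_dir / "report"
        rep_dir.mkdir(exist_ok=True)
        for name, df in report.items():
            df.to_csv(rep_dir / f"{name}.tsv", sep="\t", index=False)
        bundle["report"] = {k: v.to_dict(orient="records")
                            for k, v in report.items()}
    timings["report"] = time.perf_counter() - t0

    manifest = {"seed": config.seed, "timings_s": timings,
                "config": config.to_dict()}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return bundle
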