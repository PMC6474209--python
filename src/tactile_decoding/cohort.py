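"""Cohort-level reporting: laminar assignment, group comparisons and
summary tables across decoded neurons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LayerBoundaries",
    "DEFAULT_LAYER_BOUNDARIES",
    "assign_layer",
    "group_compare",
    "build_report",
]


@dataclass(frozen=True)
class LayerBoundaries:
    """Cortical-depth cut points (um from the pia) between laminae."""

    l1_l23: float = 157.0
    l23_l4: float = 575.0
    l4_l5: float = 900.0
    l5_l6: float = 1411.0
    l6_wm: float = 1973.0

    def cut_points(self) -> list[float]:
        pts = [self.l1_l23, self.l23_l4, self.l4_l5, self.l5_l6, self.l6_wm]
        if not all(a < b for a, b in zip(pts, pts[1:])):
            raise ValueError("layer boundaries must be strictly increasing")
        return pts


DEFAULT_LAYER_BOUNDARIES = LayerBoundaries()
_LAYER_NAMES = ["L1", "L2/3", "L4", "L5", "L6", "WM"]


def assign_layer(
    depth_um: float,
    boundaries: LayerBoundaries = DEFAULT_LAYER_BOUNDARIES,
) -> str:
    """Layer label from recording depth, half-open bins [lower, upper)."""
    if depth_um < 0:
        raise ValueError("depth must be non-negative")
    pts = boundaries.cut_points()
    idx = int(np.searchsorted(pts, depth_um, side="right"))
    return _LAYER_NAMES[idx]


_TESTS = {
    "rank-sum": lambda groups: stats.ranksums(*groups),
    "mann-whitney": lambda groups: stats.mannwhitneyu(
        *groups, alternative="two-sided"),
    "signed-rank": lambda groups: stats.wilcoxon(*groups),
    "kruskal-wallis": lambda groups: stats.kruskal(*groups),
    "pearson": lambda groups: stats.pearsonr(*groups),
}


def group_compare(groups: Sequence[Sequence[float]], test: str) -> dict:
    """Named two-sided test on value groups; thin wrapper over scipy.stats.

    rank-sum / mann-whitney / kruskal-wallis take independent groups,
    signed-rank takes two paired groups, pearson takes (x, y).
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if test == "pearson":
        if len(arrays) != 2:
            raise ValueError("pearson requires exactly two value vectors")
        if np.std(arrays[0]) == 0 or np.std(arrays[1]) == 0:
            raise ValueError("constant input: correlation undefined")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    res = _TESTS[test](arrays)
    return {"test": test, "statistic": float(res[0]), "p_value": float(res[1])}


def build_report(
    neuron_results: Sequence[Mapping],
    holm_correction: bool = False,
) -> dict[str, pd.DataFrame]:
    """Summary tables over per-neuron decoding records.

    Each record needs: neuron_id, area_tag, depth, mean_decoding_performance;
    optional: shuffled_performance, state_performance (dict state -> %),
    time_evolution (dict duration -> %).  Returns per-(area, layer) decoding
    tables, state-conditioned box-plot data and time-evolution curves with
    standard errors.  Raw p-values are reported by default; `holm_correction`
    applies a Holm step-down adjustment to the per-area layer comparisons.
    """
    if len(neuron_results) == 0:
        raise ValueError("at least one decoded neuron is required")
    rows = []
    for rec in neuron_results:
        rows.append({
            "neuron_id": rec["neuron_id"],
            "area": rec["area_tag"],
            "depth_um": rec["depth"],
            "layer": assign_layer(rec["depth"]),
            "decoding_pct": rec["mean_decoding_performance"],
            "shuffled_pct": rec.get("shuffled_performance", np.nan),
        })
    df = pd.DataFrame(rows)
    by_group = (
        df.groupby(["area", "layer"], sort=True)["decoding_pct"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )

    layer_tests = []
    for area, sub in df.groupby("area"):
        layer_groups = [g["decoding_pct"].to_numpy()
                        for _, g in sub.groupby("layer") if len(g) >= 2]
        if len(layer_groups) >= 2:
            out = group_compare(layer_groups, "kruskal-wallis")
            layer_tests.append({"area": area, **out})
    tests = pd.DataFrame(layer_tests)
    if holm_correction and not tests.empty:
        order = np.argsort(tests["p_value"].to_numpy())
        m = len(tests)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * tests["p_value"].iloc[idx])
            adj[idx] = min(running, 1.0)
        tests["p_value_holm"] = adj

    state_rows = []
    for rec in neuron_results:
        for state, perf in rec.get("state_performance", {}).items():
            state_rows.append({
                "neuron_id": rec["neuron_id"],
                "area": rec["area_tag"],
                "state": state,
                "decoding_pct": perf,
            })
    evo_rows = []
    for rec in neuron_results:
        for dur, perf in rec.get("time_evolution", {}).items():
            evo_rows.append({
                "neuron_id": rec["neuron_id"],
                "area": rec["area_tag"],
                "duration_ms": dur,
                "decoding_pct": perf,
            })
    evo = pd.DataFrame(evo_rows)
    if not evo.empty:
        evo = (
            evo.groupby(["area", "duration_ms"])["decoding_pct"]
            .agg(n="count", mean="mean",
                 sem=lambda v: v.std(ddof=1) / np.sqrt(len(v))
                 if len(v) > 1 else np.nan)
            .reset_index()
        )
    return {
        "neurons": df,
        "by_area_layer": by_group,
        "layer_tests": tests,
        "by_state": pd.DataFrame(state_rows),
        "time_evolution": evo,
    }
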