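"""Shared fixtures: tiny rendered videos and the full validation-suite
evaluation (10 synthetic videos per maze, rendered once per session)."""

from __future__ import annotations

import numpy as np
import pytest

from mazetrack.pipeline import RunConfig, analyze_stack
from mazetrack.report_viz import make_heat_map
from mazetrack.synthfix import render, suite_scripts

SUITE_SEED = 1
SUITE_N = 10


def _count(events, kind):
    return sum(1 for e in events if e.kind == kind)


def evaluate_scenario(maze_type: str, script):
    """Run the full pipeline on one rendered scenario and distill the
    comparison against ground truth into a small dict."""
    stack, gt = render(script)
    cfg = RunConfig(input="<synthetic>", maze_type=maze_type,
                    geometry=script.maze, output_stem="<unused>")
    res, traj, occ, names, blobs, threshold = analyze_stack(stack, cfg)
    err = np.hypot(
        traj.x_px - gt.centroids_px[:, 0], traj.y_px - gt.centroids_px[:, 1]
    )
    hm = make_heat_map(traj, script.maze)
    entry_pairs = {}
    balance_ok = True
    for region, evs in res.events.items():
        n_in, n_out = _count(evs, "entry"), _count(evs, "exit")
        if evs and evs[0].kind == "exit":  # track started inside the region
            balance_ok &= n_out - n_in in (0, 1)
        else:
            balance_ok &= n_in - n_out in (0, 1)
        entry_pairs[region] = (n_in, _count(gt.events.get(region, []), "entry"))
    time_sum = sum(
        v for k, v in res.metrics.items()
        if k.startswith("time_") and k != "time_wall_band_s"
        and isinstance(v, (int, float))
    )
    # OF/EPM report aggregated region times; MWM quadrant times partition
    if maze_type == "YM":
        covered = [f"time_{a}_s" for a in script.maze.meta["arms"]]
        il = res.labels[:-1]
        time_sum = sum(res.metrics[k] for k in covered)
        time_sum += float(np.sum(il == "center") / script.fps)
    return {
        "name": script.name,
        "fps": script.fps,
        "n_frames": traj.n_frames,
        "n_err_gt_1px": int(np.sum(err > 1.0)),
        "path_cm": traj.total_distance_cm,
        "gt_path_cm": gt.path_length_cm,
        "metrics": res.metrics,
        "gt_metrics": gt.result.metrics,
        "entry_pairs": entry_pairs,
        "events_balance_ok": balance_ok,
        "time_partition_sum_s": time_sum,
        "duration_s": traj.duration_s,
        "heat_total": hm.total,
        "n_detected": int(traj.detected.sum()),
    }


@pytest.fixture(scope="session")
def suite_eval():
    """Pipeline-vs-ground-truth comparison over the whole validation suite."""
    out = {}
    for maze_type in ("OF", "EPM", "YM", "MWM"):
        out[maze_type] = [
            evaluate_scenario(maze_type, script)
            for script in suite_scripts(maze_type, SUITE_N, SUITE_SEED)
        ]
    return out


@pytest.fixture(scope="session")
def of_run():
    """One small rendered open-field scenario plus its pipeline outputs."""
    script = suite_scripts("OF", 4, SUITE_SEED)[3]
    stack, gt = render(script)
    cfg = RunConfig(input="<synthetic>", maze_type="OF",
                    geometry=script.maze, output_stem="<unused>")
    res, traj, occ, names, blobs, threshold = analyze_stack(stack, cfg)
    return {
        "script": script, "stack": stack, "gt": gt, "result": res,
        "traj": traj, "occ": occ, "names": names, "blobs": blobs,
        "threshold": threshold,
    }
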