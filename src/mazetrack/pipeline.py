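"""End-to-end orchestration: load -> preprocess -> detect -> track ->
score -> report, with a replayable parameters file.

The pipeline mirrors the preferences-then-analyze workflow: a
:class:`RunConfig` collects every preference, the stages run in a fixed
order with per-stage logging, and all outputs land next to the configured
output stem:

``<stem>_framewise.csv``, ``<stem>_summary.csv``, ``<stem>_params.yaml``,
``<stem>_rois.json``, ``<stem>_heatmap.png``, ``<stem>_track.png``.

Re-running from a saved parameters file reproduces byte-identical tables.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .detect import DetectionConfig, detect_stack
from .errors import StageError
from .geometry import (
    MazeGeometry,
    centroid_occupancy_series,
    perimeter_occupancy_series,
)
from .preprocess import compute_background, difference_stack, gaussian_blur
from .report_viz import (
    load_parameters,
    make_heat_map,
    make_trajectory_map,
    save_parameters,
    write_framewise_table,
    write_rois,
    write_summary,
)
from .scoring import (
    DEFAULT_RULES,
    RegionRuleSet,
    TestResult,
    score_epm,
    score_mwm,
    score_open_field,
    score_ymaze,
)
from .track import TrackingConfig, Trajectory, build_trajectory
from .video_io import FrameStack, load_stack

log = logging.getLogger("mazetrack")


@dataclass
class RunConfig:
    """Everything one analysis run depends on."""

    input: str
    maze_type: str
    geometry: MazeGeometry
    output_stem: str
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    rules: RegionRuleSet | None = None
    blur_radius_px: float = 0.0
    background_method: str = "mean"
    fps_override: float | None = None
    accept_default_fps: bool = False
    crop: tuple[int, int, int, int] | None = None
    platform_min_dwell_frames: int = 0
    head_dip_min_overlap_px2: int = 20
    head_dip_min_gap_frames: int = 5
    write_xlsx: bool = False
    write_maps: bool = True

    def __post_init__(self):
        if self.maze_type not in ("OF", "EPM", "YM", "MWM"):
            raise ValueError("maze_type must be one of OF, EPM, YM, MWM")
        if self.rules is None:
            self.rules = DEFAULT_RULES[self.maze_type]


@dataclass
class RunResult:
    config: RunConfig
    result: TestResult
    trajectory: Trajectory
    occupancy: np.ndarray
    occupancy_names: list[str]
    threshold_used: int
    outputs: dict[str, Path]


def params_document(cfg: RunConfig, threshold_used: int | None = None) -> dict:
    doc = {
        "version": __version__,
        "input": str(cfg.input),
        "maze_type": cfg.maze_type,
        "geometry": cfg.geometry.to_dict(),
        "detection": asdict(cfg.detection),
        "tracking": asdict(cfg.tracking),
        "rules": asdict(cfg.rules),
        "preprocess": {
            "blur_radius_px": cfg.blur_radius_px,
            "background_method": cfg.background_method,
        },
        "video": {
            "fps_override": cfg.fps_override,
            "accept_default_fps": cfg.accept_default_fps,
            "crop": list(cfg.crop) if cfg.crop else None,
        },
        "scoring": {
            "platform_min_dwell_frames": cfg.platform_min_dwell_frames,
            "head_dip_min_overlap_px2": cfg.head_dip_min_overlap_px2,
            "head_dip_min_gap_frames": cfg.head_dip_min_gap_frames,
        },
        "output_stem": str(cfg.output_stem),
        "write_xlsx": cfg.write_xlsx,
    }
    if threshold_used is not None:
        doc["threshold_used"] = threshold_used
    return doc


def config_from_params(params: dict, output_stem: str | None = None) -> RunConfig:
    video = params.get("video", {})
    scoring_p = params.get("scoring", {})
    return RunConfig(
        input=params["input"],
        maze_type=params["maze_type"],
        geometry=MazeGeometry.from_dict(params["geometry"]),
        output_stem=output_stem or params["output_stem"],
        detection=DetectionConfig(**params["detection"]),
        tracking=TrackingConfig(**params["tracking"]),
        rules=RegionRuleSet(**params["rules"]),
        blur_radius_px=params["preprocess"]["blur_radius_px"],
        background_method=params["preprocess"]["background_method"],
        fps_override=video.get("fps_override"),
        accept_default_fps=video.get("accept_default_fps", False),
        crop=tuple(video["crop"]) if video.get("crop") else None,
        platform_min_dwell_frames=scoring_p.get("platform_min_dwell_frames", 0),
        head_dip_min_overlap_px2=scoring_p.get("head_dip_min_overlap_px2", 20),
        head_dip_min_gap_frames=scoring_p.get("head_dip_min_gap_frames", 5),
        write_xlsx=params.get("write_xlsx", False),
    )


def analyze_stack(stack: FrameStack, cfg: RunConfig):
    """Run preprocessing, detection, tracking and scoring on a loaded
    stack; returns ``(result, traj, occupancy, names, blobs, threshold)``.

    This is the file-free core used by :func:`run_analysis` and by tests.
    """
    geometry = cfg.geometry
    if stack.pixel_size != geometry.pixel_size:
        from dataclasses import replace

        stack = replace(stack, pixel_size=geometry.pixel_size)
    if cfg.blur_radius_px > 0:
        stack = gaussian_blur(stack, cfg.blur_radius_px)
    bg = compute_background(stack, cfg.background_method)
    diff = difference_stack(stack, bg)
    blobs, threshold = detect_stack(
        diff, cfg.detection, keep_masks=(cfg.maze_type == "EPM")
    )
    traj = build_trajectory(blobs, stack, cfg.tracking)
    names = list(geometry.partition)
    if cfg.maze_type == "MWM":
        pos = traj.positions_px()
        occ = centroid_occupancy_series(pos, geometry)
        platform = geometry.region("platform").covers_points(pos)
        wall = geometry.region("wall_band").covers_points(pos)
        result = score_mwm(
            traj, geometry, occ, platform, wall, cfg.rules, cfg.tracking,
            cfg.platform_min_dwell_frames,
        )
    else:
        occ = perimeter_occupancy_series(blobs, geometry)
        if cfg.maze_type == "OF":
            result = score_open_field(traj, geometry, occ, cfg.rules, cfg.tracking)
        elif cfg.maze_type == "EPM":
            masks = [b.mask if b is not None else None for b in blobs]
            result = score_epm(
                traj, geometry, occ, masks, cfg.rules, cfg.tracking,
                cfg.head_dip_min_overlap_px2, cfg.head_dip_min_gap_frames,
            )
        else:
            result = score_ymaze(traj, geometry, occ, cfg.rules, cfg.tracking)
    return result, traj, occ, names, blobs, threshold


def run_analysis(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline and write the six output files.

    On failure every partial output is removed and a :class:`StageError`
    naming the failing stage propagates.
    """
    stem = Path(cfg.output_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    t0 = time.perf_counter()

    def stage(name, fn):
        t = time.perf_counter()
        try:
            out = fn()
        except StageError:
            raise
        except Exception as exc:
            for p in outputs.values():
                p.unlink(missing_ok=True)
            raise StageError(name, exc) from exc
        log.info("stage %-10s %6.2f s", name, time.perf_counter() - t)
        return out

    stack = stage("load", lambda: load_stack(
        cfg.input,
        fps_override=cfg.fps_override,
        crop=cfg.crop,
        accept_default_fps=cfg.accept_default_fps,
    ))
    result, traj, occ, names, blobs, threshold = stage(
        "analyze", lambda: analyze_stack(stack, cfg)
    )

    def report():
        outputs["framewise"] = write_framewise_table(
            traj, occ, names, result.labels, f"{stem}_framewise.csv", cfg.write_xlsx
        )
        outputs["summary"] = write_summary(result, f"{stem}_summary.csv", cfg.write_xlsx)
        outputs["params"] = save_parameters(
            params_document(cfg, threshold), f"{stem}_params.yaml"
        )
        outputs["rois"] = write_rois(cfg.geometry, f"{stem}_rois.json")
        if cfg.write_maps:
            make_heat_map(traj, cfg.geometry, path=f"{stem}_heatmap.png")
            outputs["heatmap"] = Path(f"{stem}_heatmap.png")
            make_trajectory_map(traj, cfg.geometry, path=f"{stem}_track.png")
            outputs["track"] = Path(f"{stem}_track.png")

    stage("report", report)
    log.info("run complete in %.2f s", time.perf_counter() - t0)
    return RunResult(
        config=cfg,
        result=result,
        trajectory=traj,
        occupancy=occ,
        occupancy_names=names,
        threshold_used=threshold,
        outputs=outputs,
    )


def replay(params_path, output_stem: str | None = None) -> RunResult:
    """Repeat an analysis exactly from its saved parameters file."""
    params = load_parameters(params_path)
    cfg = config_from_params(params, output_stem)
    return run_analysis(cfg)
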