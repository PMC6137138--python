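"""Synthetic maze videos with exhaustive analytic ground truth.

Every stage of the pipeline is validated against scripted videos: a
bright (or dark) elliptical blob follows a waypoint trajectory over a
static textured background with per-frame Gaussian noise.  Ground truth —
centroids, path length, region occupancy, entry/exit events, freezing,
head dips, platform latency — is computed analytically from the script
(waypoints and the exact ellipse boundary), never from rendered pixels, so
detection error and rule logic are testable separately.  Fraction-based
events use the same :class:`~mazetrack.scoring.RegionRuleSet` state
machine as the analysis itself, which makes the ground truth internally
consistent with the rules being validated.

Occupancy ground truth uses the perimeter of the exact ellipse raster (the
noise-free shape discretized to the pixel grid): it is what a perfect
detector would feed the perimeter-fraction rule, so differences from the
pipeline reflect detection error alone, not grid-sampling artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from . import scoring
from .detect import mask_perimeter
from .geometry import (
    MazeGeometry,
    centroid_occupancy_series,
    make_epm,
    make_mwm,
    make_open_field,
    make_ymaze,
    partition_fractions,
)
from .scoring import DEFAULT_RULES, RegionRuleSet, TestResult
from .track import TrackingConfig, Trajectory, apply_movement_threshold, freezing_intervals
from .video_io import FrameStack

@dataclass(frozen=True)
class MotionScript:
    """Scripted scenario: where the animal is at every moment.

    ``waypoints`` are ``(time_s, x_cm, y_cm)`` in the image frame (cm =
    px * pixel_size); position is linearly interpolated between waypoints
    and held beyond the last one.  ``contrast`` is the foreground minus
    background intensity (negative for a dark animal).
    """

    waypoints: tuple
    maze: MazeGeometry
    blob_semi_axes_cm: tuple[float, float] = (3.0, 1.5)
    blob_angle_deg: float = 0.0
    contrast: float = 80.0
    noise_sd: float = 6.0
    background_level: float = 100.0
    texture_sd: float = 3.0
    fps: float = 25.0
    duration_s: float | None = None
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        wp = tuple((float(t), float(x), float(y)) for t, x, y in self.waypoints)
        if len(wp) < 1:
            raise ValueError("need at least one waypoint")
        times = [t for t, _, _ in wp]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("waypoints must be time-ordered")
        if self.contrast == 0:
            raise ValueError("contrast must be nonzero")
        dur = self.duration_s if self.duration_s is not None else times[-1] + 1.0
        if dur < times[-1]:
            raise ValueError("duration must cover the last waypoint")
        object.__setattr__(self, "waypoints", wp)
        object.__setattr__(self, "duration_s", float(dur))
        px = self.maze.pixel_size
        H, W = self.maze.image_shape
        a = max(self.blob_semi_axes_cm) / px
        for t, x, y in wp:
            xp, yp = x / px, y / px
            if not (a <= xp <= W - 1 - a and a <= yp <= H - 1 - a):
                raise ValueError(
                    f"waypoint ({x}, {y}) cm leaves no room for the blob in the arena"
                )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps)) + 1

    def positions_px(self) -> np.ndarray:
        """(T, 2) true blob center per frame, in pixels."""
        t = np.arange(self.n_frames) / self.fps
        wt = np.array([w[0] for w in self.waypoints])
        wx = np.array([w[1] for w in self.waypoints])
        wy = np.array([w[2] for w in self.waypoints])
        x = np.interp(t, wt, wx) / self.maze.pixel_size
        y = np.interp(t, wt, wy) / self.maze.pixel_size
        return np.column_stack([x, y])

    def semi_axes_px(self) -> tuple[float, float]:
        px = self.maze.pixel_size
        return self.blob_semi_axes_cm[0] / px, self.blob_semi_axes_cm[1] / px


@dataclass
class GroundTruth:
    """Analytic truth for one scripted video."""

    centroids_px: np.ndarray
    path_length_cm: float
    occupancy: np.ndarray
    occupancy_names: list[str]
    labels: np.ndarray
    events: dict
    freezing_total_s: float
    freezing_episodes: list
    result: TestResult
    extras: dict = field(default_factory=dict)

    def entry_count(self, region: str) -> int:
        return sum(1 for e in self.events.get(region, []) if e.kind == "entry")


def ellipse_mask_patch(center, a, b, angle_rad, shape):
    """Exact (non-antialiased) ellipse raster as (mask_patch, (y0, x0))."""
    H, W = shape
    r = int(np.ceil(max(a, b))) + 2
    x0 = max(0, int(center[0]) - r)
    x1 = min(W, int(center[0]) + r + 1)
    y0 = max(0, int(center[1]) - r)
    y1 = min(H, int(center[1]) + r + 1)
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    dx, dy = xs - center[0], ys - center[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = (dx * ca + dy * sa) / a
    v = (-dx * sa + dy * ca) / b
    return (u * u + v * v) <= 1.0, (y0, x0)


def _true_trajectory(script: MotionScript, tracking: TrackingConfig) -> Trajectory:
    pos = script.positions_px()
    dd = np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1]))
    T = len(pos)
    traj = Trajectory(
        x_px=pos[:, 0],
        y_px=pos[:, 1],
        detected=np.ones(T, bool),
        fps=script.fps,
        pixel_size=script.maze.pixel_size,
        movement_threshold_px=tracking.movement_threshold_px,
        dd_px_raw=dd,
        dd_px=dd.copy(),
        stationary=np.zeros(T - 1, bool),
        imputed=np.zeros(T - 1, bool),
    )
    return apply_movement_threshold(traj, tracking)


def compute_ground_truth(
    script: MotionScript,
    tracking: TrackingConfig | None = None,
    rules: RegionRuleSet | None = None,
) -> GroundTruth:
    """Evaluate the script analytically: no pixels are rendered."""
    tracking = tracking or TrackingConfig()
    maze = script.maze
    rules = rules or DEFAULT_RULES[maze.maze_type]
    pos = script.positions_px()
    a, b = script.semi_axes_px()
    ang = np.radians(script.blob_angle_deg)
    traj = _true_trajectory(script, tracking)
    path_cm = float(np.sum(np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1])))) * maze.pixel_size

    if rules.mode == "center_of_mass":
        occ = centroid_occupancy_series(pos, maze)
    else:
        # perimeter of the exact (noise-free) ellipse raster: what a perfect
        # detector would hand to the perimeter-fraction rule
        occ = np.empty((len(pos), len(maze.partition)))
        for i in range(len(pos)):
            m, (y0, x0) = ellipse_mask_patch(pos[i], a, b, ang, maze.image_shape)
            pts = mask_perimeter(m, origin=(x0, y0))
            occ[i] = partition_fractions(pts, maze)

    if maze.maze_type == "OF":
        result = scoring.score_open_field(traj, maze, occ, rules, tracking)
    elif maze.maze_type == "EPM":
        zone = np.zeros(maze.image_shape, bool)
        for zn in maze.edge_zones:
            zone |= maze.region(zn).rasterize(maze.image_shape)
        overlap = np.zeros(len(pos), dtype=int)
        for i in range(len(pos)):
            m, (y0, x0) = ellipse_mask_patch(pos[i], a, b, ang, maze.image_shape)
            overlap[i] = int(
                np.sum(m & zone[y0 : y0 + m.shape[0], x0 : x0 + m.shape[1]])
            )
        result = scoring.score_epm(traj, maze, occ, masks=None, rules=rules, tracking=tracking)
        labels = result.labels
        in_open = np.isin(labels, maze.meta["open_arms"])
        n_dips, runs = scoring.detect_head_dips(overlap, in_open)
        result.add("head_dips", n_dips, "count")
        result.extras["head_dip_runs"] = runs
        result.extras["edge_overlap"] = overlap
    elif maze.maze_type == "YM":
        result = scoring.score_ymaze(traj, maze, occ, rules, tracking)
    elif maze.maze_type == "MWM":
        platform = maze.region("platform").covers_points(pos)
        wall = maze.region("wall_band").covers_points(pos)
        result = scoring.score_mwm(traj, maze, occ, platform, wall, rules, tracking)
    else:  # pragma: no cover
        raise ValueError(maze.maze_type)

    episodes, freezing_total = freezing_intervals(traj, tracking)
    return GroundTruth(
        centroids_px=pos,
        path_length_cm=path_cm,
        occupancy=occ,
        occupancy_names=list(maze.partition),
        labels=result.labels,
        events=result.events,
        freezing_total_s=freezing_total,
        freezing_episodes=episodes,
        result=result,
    )


def render(
    script: MotionScript,
    tracking: TrackingConfig | None = None,
    rules: RegionRuleSet | None = None,
) -> tuple[FrameStack, GroundTruth]:
    """Render the scripted video and return it with its ground truth.

    The background is a fixed low-amplitude noise texture (so the
    background model has structure to learn); the blob is an anti-aliased
    ellipse; independent Gaussian noise is added to every frame.  Fully
    deterministic for a given seed.
    """
    maze = script.maze
    H, W = maze.image_shape
    T = script.n_frames
    pos = script.positions_px()
    a, b = script.semi_axes_px()
    ang = np.radians(script.blob_angle_deg)
    ca, sa = np.cos(ang), np.sin(ang)
    rng_bg = np.random.default_rng(script.seed)
    background = script.background_level + script.texture_sd * rng_bg.standard_normal((H, W))
    rng = np.random.default_rng(script.seed + 1)
    frames = np.empty((T, H, W), np.uint8)
    feather = min(a, b)
    pad = int(np.ceil(max(a, b))) + 3
    for i in range(T):
        img = background + script.noise_sd * rng.standard_normal((H, W))
        cx, cy = pos[i]
        x0, x1 = max(0, int(cx) - pad), min(W, int(cx) + pad + 1)
        y0, y1 = max(0, int(cy) - pad), min(H, int(cy) + pad + 1)
        xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
        dx, dy = xs - cx, ys - cy
        u = (dx * ca + dy * sa) / a
        v = (-dx * sa + dy * ca) / b
        f = np.sqrt(u * u + v * v)
        coverage = np.clip(0.5 + (1.0 - f) * feather, 0.0, 1.0)
        img[y0:y1, x0:x1] += script.contrast * coverage
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    stack = FrameStack(frames=frames, fps=script.fps, pixel_size=maze.pixel_size)
    return stack, compute_ground_truth(script, tracking, rules)


# ---------------------------------------------------------------------------
# scripted validation suites


class _Path:
    """Waypoint accumulator: moves at a given speed, holds in place."""

    def __init__(self, start_xy):
        self.wp = [(0.0, float(start_xy[0]), float(start_xy[1]))]

    @property
    def t(self):
        return self.wp[-1][0]

    @property
    def xy(self):
        return self.wp[-1][1], self.wp[-1][2]

    def move_to(self, x, y, speed_cms):
        x0, y0 = self.xy
        d = float(np.hypot(x - x0, y - y0))
        self.wp.append((self.t + d / speed_cms, float(x), float(y)))
        return self

    def hold(self, duration_s):
        x0, y0 = self.xy
        self.wp.append((self.t + float(duration_s), x0, y0))
        return self


def _of_script(i: int, maze: MazeGeometry, rng: np.random.Generator, seed: int) -> MotionScript:
    m = maze.meta
    ox, oy = np.array(m["arena_origin_px"]) * maze.pixel_size
    F = m["field_cm"]
    inset = 5.0
    ring = [
        (ox + inset, oy + inset),
        (ox + F - inset, oy + inset),
        (ox + F - inset, oy + F - inset),
        (ox + inset, oy + F - inset),
    ]
    cx, cy = ox + F / 2, oy + F / 2
    mids = [  # outer side midpoints: entries cross the center edges head-on
        (cx, oy + inset),
        (ox + F - inset, cy),
        (cx, oy + F - inset),
        (ox + inset, cy),
    ]
    p = _Path(mids[1] if i > 0 else ring[0])
    speed = rng.uniform(14, 24)
    n_freezes = i % 3
    freeze_sites = set(rng.choice(max(i, 1) + 2, size=n_freezes, replace=False)) if n_freezes else set()
    center_freeze = i % 2 == 1 and i > 0
    for k in range(i):  # i entries into the center block
        p.move_to(*mids[(k + 1) % 4], speed_cms=speed)
        if k in freeze_sites:
            p.hold(rng.uniform(0.9, 2.2))
        else:
            p.hold(rng.uniform(0.15, 0.3))
        jx = rng.uniform(-3, 3)
        p.move_to(cx + jx, cy, speed_cms=speed)
        if center_freeze and k == 0:
            p.hold(rng.uniform(0.9, 1.8))
        else:
            p.hold(rng.uniform(0.15, 0.3))
        p.move_to(*mids[(k + 2) % 4], speed_cms=speed)
    if i == 0:  # thigmotaxis tour, never entering the center
        for k in range(1, 6):
            p.move_to(*ring[k % 4], speed_cms=speed)
            if k in (2, 4):
                p.hold(rng.uniform(0.9, 1.6))
    p.hold(0.3)
    return MotionScript(
        waypoints=p.wp, maze=maze, seed=seed, name=f"of_{i:02d}",
        contrast=80.0 if i % 2 == 0 else -80.0,
    )


def _epm_script(i: int, maze: MazeGeometry, rng: np.random.Generator, seed: int) -> MotionScript:
    m = maze.meta
    px = maze.pixel_size
    cx, cy = np.array(m["center_px"]) * px
    L, c = m["arm_length_cm"], m["center_side_cm"]
    deep = c / 2 + L - 6.0
    targets = {
        "open_arm_1": (cx - deep, cy),
        "open_arm_2": (cx + deep, cy),
        "closed_arm_1": (cx, cy - deep),
        "closed_arm_2": (cx, cy + deep),
    }
    speed = rng.uniform(14, 22)
    if i == 0:  # confined to one closed arm, pacing its whole length
        x, y = targets["closed_arm_1"]
        y_far, y_near = y, cy - (c / 2 + 5)
        p = _Path((x, y_far))
        for k in range(3):
            wob = rng.uniform(-1.0, 1.0)
            p.move_to(x + wob, y_near, speed_cms=speed).hold(0.2)
            p.move_to(x - wob, y_far, speed_cms=speed).hold(0.2)
        p.hold(0.3)
        return MotionScript(waypoints=p.wp, maze=maze, seed=seed, name=f"epm_{i:02d}")
    n_open = i % 4
    n_closed = 1 + i % 3
    visits = [("open_arm_1" if k % 2 == 0 else "open_arm_2") for k in range(n_open)]
    visits += [("closed_arm_1" if k % 2 == 0 else "closed_arm_2") for k in range(n_closed)]
    rng.shuffle(visits)
    n_dips = i % 3 if n_open else 0
    dips_left = n_dips
    p = _Path((cx, cy))
    for arm in visits:
        tx, ty = targets[arm]
        p.move_to(tx, ty, speed_cms=speed).hold(rng.uniform(0.15, 0.3))
        if arm.startswith("open") and dips_left > 0:
            # lateral protrusion over the arm edge, twice at most per visit
            k_d = min(dips_left, 2)
            for d in range(k_d):
                p.move_to(tx, ty + 2.5, speed_cms=10).hold(0.3)
                p.move_to(tx, ty, speed_cms=10).hold(0.4)
            dips_left -= k_d
        p.move_to(cx, cy, speed_cms=speed).hold(rng.uniform(0.15, 0.25))
    p.hold(0.3)
    return MotionScript(waypoints=p.wp, maze=maze, seed=seed, name=f"epm_{i:02d}")


def _ym_script(i: int, maze: MazeGeometry, rng: np.random.Generator, seed: int) -> MotionScript:
    m = maze.meta
    px = maze.pixel_size
    cx, cy = np.array(m["center_px"]) * px
    arms = m["arms"]
    L, w = m["arm_length_cm"], m["arm_width_cm"]
    r = w / (2 * np.sqrt(3))
    deep = r + L - 7.0
    targets = {}
    for k, arm in enumerate(arms):
        th = np.radians(m["base_angle_deg"] + 120 * k)
        targets[arm] = (cx + deep * np.cos(th), cy + deep * np.sin(th))
    speed = rng.uniform(14, 22)
    p = _Path((cx, cy))
    if i == 0:  # paces one arm it started in: zero entry events
        th = np.radians(m["base_angle_deg"])
        far = (cx + deep * np.cos(th), cy + deep * np.sin(th))
        near = (cx + (r + 6) * np.cos(th), cy + (r + 6) * np.sin(th))
        p = _Path(far)
        for _ in range(3):
            p.move_to(*near, speed_cms=speed).hold(0.2)
            p.move_to(*far, speed_cms=speed).hold(0.2)
        p.hold(0.3)
        return MotionScript(waypoints=p.wp, maze=maze, seed=seed, name=f"ym_{i:02d}")
    seq = []
    prev = None
    for _ in range(i + 2):
        choices = [a for a in arms if a != prev]
        nxt = choices[rng.integers(len(choices))]
        seq.append(nxt)
        prev = nxt
    for arm in seq:
        p.move_to(*targets[arm], speed_cms=speed).hold(rng.uniform(0.15, 0.3))
        p.move_to(cx, cy, speed_cms=speed)
    p.hold(0.3)
    return MotionScript(
        waypoints=p.wp, maze=maze, seed=seed, name=f"ym_{i:02d}",
        contrast=-80.0 if i % 3 == 0 else 80.0,
    )


def _mwm_script(i: int, maze: MazeGeometry, rng: np.random.Generator, seed: int) -> MotionScript:
    m = maze.meta
    px = maze.pixel_size
    cx, cy = np.array(m["pool_center_px"]) * px
    R = m["pool_diameter_cm"] / 2
    plat = (cx + m["platform_center_cm"][0], cy + m["platform_center_cm"][1])

    def rim(theta, radius=R - 6):
        return cx + radius * np.cos(theta), cy + radius * np.sin(theta)

    speed = rng.uniform(14, 20)
    th0 = rng.uniform(0, 2 * np.pi)
    p = _Path(rim(th0))
    if i == 0:  # wall hugging, never finds the platform
        for k in range(1, 25):
            p.move_to(*rim(th0 + k * np.pi / 6), speed_cms=speed)
        p.hold(0.3)
        return MotionScript(
            waypoints=p.wp, maze=maze, seed=seed, name=f"mwm_{i:02d}",
            blob_semi_axes_cm=(4.0, 2.5),
        )
    hug = (i % 4) * 0.9  # seconds of initial thigmotaxis
    if hug:
        p.move_to(*rim(th0 + hug * speed / (R - 6)), speed_cms=speed)
    for _ in range(2 + i % 4):
        th = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(15, 0.6 * R)
        p.move_to(cx + rad * np.cos(th), cy + rad * np.sin(th), speed_cms=speed)
    p.move_to(*plat, speed_cms=speed)
    p.hold(0.4)  # brief sit on the platform; the trial ends on escape
    return MotionScript(
        waypoints=p.wp, maze=maze, seed=seed, name=f"mwm_{i:02d}",
        blob_semi_axes_cm=(4.0, 2.5),
        contrast=-80.0 if i % 2 == 0 else 80.0,
    )


_BUILDERS = {
    "OF": (make_open_field, _of_script),
    "EPM": (make_epm, _epm_script),
    "YM": (make_ymaze, _ym_script),
    "MWM": (make_mwm, _mwm_script),
}


def default_geometry(maze_type: str) -> MazeGeometry:
    """The standard maze of each test at its default dimensions."""
    return _BUILDERS[maze_type][0]()


def suite_scripts(maze_type: str, n_videos: int = 10, seed: int = 0) -> list[MotionScript]:
    """The scripts of the validation suite, without rendering anything.

    Scenario ``i`` of the open-field suite makes exactly ``i`` center
    entries; every suite covers never-enter, always-inside/boundary-hugging
    and multi-visit cases with varied speeds, dwell times and freezes.
    """
    if n_videos < 1:
        raise ValueError("n_videos must be >= 1")
    maze = default_geometry(maze_type)
    builder = _BUILDERS[maze_type][1]
    out = []
    for i in range(n_videos):
        rng = np.random.default_rng((seed * 1000 + i) % (2**31 - 1))
        out.append(builder(i, maze, rng, seed=(seed * 1000 + i) % (2**31 - 1)))
    return out


def standard_suite(maze_type: str, n_videos: int = 10, seed: int = 0):
    """Yield ``(MotionScript, FrameStack, GroundTruth)`` per scenario.

    Lazily rendered: one video is in memory at a time.
    """
    for script in suite_scripts(maze_type, n_videos, seed):
        stack, truth = render(script)
        yield script, stack, truth


def write_fixture(script: MotionScript, outdir, stem: str | None = None):
    """Write a scenario as TIFF stack + ground-truth JSON (regression use)."""
    import json
    from pathlib import Path

    from .video_io import save_stack

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or (script.name or "scenario")
    stack, truth = render(script)
    tiff = save_stack(stack, outdir / f"{stem}.tif")
    gt = {
        "name": script.name,
        "path_length_cm": truth.path_length_cm,
        "freezing_total_s": truth.freezing_total_s,
        "metrics": {
            k: v for k, v in truth.result.metrics.items() if not isinstance(v, np.ndarray)
        },
        "entry_counts": {r: truth.entry_count(r) for r in truth.occupancy_names},
        "waypoints": [list(w) for w in script.waypoints],
        "seed": script.seed,
    }
    jpath = outdir / f"{stem}_truth.json"
    jpath.write_text(json.dumps(gt, indent=1, default=float))
    return tiff, jpath
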