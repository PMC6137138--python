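"""Region entry/exit events and per-test behavioral metrics.

Entries and exits follow a hysteresis state machine on the per-frame
occupancy of each region.  The animal enters a region when at least a set
fraction of its body (perimeter points) is inside — 70% for the open
field, 80% for the elevated plus maze, 90% for the Y-maze — and leaves
when at most ``1 - exit_fraction`` of the body remains (the Y-maze rule is
explicit: out when 90% of the body has left, i.e. occupancy <= 0.1; the
other mazes default to the symmetric complement of their entry fraction).
The water maze instead uses the center of mass: the animal is in whichever
quadrant contains the blob centroid.

The scorers turn the event streams plus the trajectory into the standard
metric set of each test: distances, region times, entry/visit counts,
freezing times, average speed, head dips (EPM), spontaneous alternation
(YM) and platform latency / wall-band time (MWM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import MazeGeometry
from .track import Trajectory, TrackingConfig, freezing_intervals

NOT_FOUND_SENTINEL = "Did not find platform"


@dataclass(frozen=True)
class RegionRuleSet:
    """How occupancy becomes entry/exit events.

    mode ``"fraction"``: enter at occupancy >= entry_fraction, leave at
    occupancy <= 1 - exit_fraction (exit_fraction defaults to the entry
    fraction).  mode ``"center_of_mass"``: binary occupancy of the blob
    centroid decides directly.
    """

    mode: str = "fraction"
    entry_fraction: float = 0.7
    exit_fraction: float | None = None

    def __post_init__(self):
        if self.mode not in ("fraction", "center_of_mass"):
            raise ValueError("mode must be 'fraction' or 'center_of_mass'")
        if self.mode == "fraction" and not 0 < self.entry_fraction <= 1:
            raise ValueError("entry_fraction must lie in (0, 1]")
        if self.exit_fraction is not None and not 0 < self.exit_fraction <= 1:
            raise ValueError("exit_fraction must lie in (0, 1]")

    @property
    def entry_at(self) -> float:
        return 1.0 if self.mode == "center_of_mass" else self.entry_fraction

    @property
    def exit_at(self) -> float:
        """Occupancy at or below which the animal has left."""
        if self.mode == "center_of_mass":
            return 0.0
        ef = self.exit_fraction if self.exit_fraction is not None else self.entry_fraction
        return 1.0 - ef


DEFAULT_RULES = {
    "OF": RegionRuleSet("fraction", 0.7),
    "EPM": RegionRuleSet("fraction", 0.8),
    "YM": RegionRuleSet("fraction", 0.9, 0.9),
    "MWM": RegionRuleSet("center_of_mass"),
}


@dataclass(frozen=True)
class RegionEvent:
    region: str
    kind: str  # "entry" | "exit"
    frame: int
    time_s: float


@dataclass
class TestResult:
    """Scored metrics of one video for one test."""

    maze_type: str
    metrics: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)
    labels: np.ndarray | None = None
    flags: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def add(self, name: str, value, unit: str = "") -> None:
        self.metrics[name] = value
        self.units[name] = unit


def detect_region_events(
    occupancy: np.ndarray, rules: RegionRuleSet, fps: float, region: str = ""
) -> list[RegionEvent]:
    """Hysteresis entry/exit events for one region's occupancy series.

    The first event is an entry unless the series starts inside (occupancy
    already at or above the entry level at frame 0), in which case the
    first event is the eventual exit.
    """
    occ = np.asarray(occupancy, dtype=float)
    if occ.min() < 0 or occ.max() > 1:
        raise ValueError("occupancy fractions must lie in [0, 1]")
    events: list[RegionEvent] = []
    inside = occ[0] >= rules.entry_at
    for i in range(1, len(occ)):
        if not inside and occ[i] >= rules.entry_at:
            inside = True
            events.append(RegionEvent(region, "entry", i, i / fps))
        elif inside and occ[i] <= rules.exit_at:
            inside = False
            events.append(RegionEvent(region, "exit", i, i / fps))
    return events


def build_region_timeline(
    occupancy: np.ndarray,
    names: list[str],
    rules: RegionRuleSet,
    fps: float,
    transition: str | None,
) -> tuple[np.ndarray, dict[str, list[RegionEvent]]]:
    """Joint state machine over a partition: per-frame region label plus
    per-region event streams.

    At most one region can satisfy the entry condition at a time (entry
    fractions are > 0.5 over a partition); between an exit and the next
    entry the animal is labelled with the transition region (or keeps the
    previous label when no transition region exists, as in the water maze
    where centroid occupancy is exhaustive).
    """
    occ = np.asarray(occupancy, dtype=float)
    T, R = occ.shape
    if R != len(names):
        raise ValueError("occupancy columns must match region names")
    if occ.min() < 0 or occ.max() > 1:
        raise ValueError("occupancy fractions must lie in [0, 1]")
    events = {n: [] for n in names}
    labels = np.empty(T, dtype=object)
    current: str | None = None
    for k, n in enumerate(names):
        if occ[0, k] >= rules.entry_at:
            current = n
            break
    labels[0] = current if current is not None else transition
    for i in range(1, T):
        if current is not None and occ[i, names.index(current)] <= rules.exit_at:
            events[current].append(RegionEvent(current, "exit", i, i / fps))
            current = None
        if current is None:
            for k, n in enumerate(names):
                if occ[i, k] >= rules.entry_at:
                    current = n
                    events[n].append(RegionEvent(n, "entry", i, i / fps))
                    break
        labels[i] = current if current is not None else (transition or labels[i - 1])
    return labels, events


def _interval_labels(labels: np.ndarray) -> np.ndarray:
    """Label of each inter-frame interval: the region at the interval start."""
    return labels[:-1]


def _time_in(labels: np.ndarray, name_or_names, fps: float) -> float:
    names = (name_or_names,) if isinstance(name_or_names, str) else tuple(name_or_names)
    il = _interval_labels(labels)
    return float(np.sum(np.isin(il, names)) / fps)


def _distance_in(labels: np.ndarray, name_or_names, traj: Trajectory) -> float:
    names = (name_or_names,) if isinstance(name_or_names, str) else tuple(name_or_names)
    il = _interval_labels(labels)
    return float(np.sum(traj.dd_cm[np.isin(il, names)]))


def _entry_count(events: dict, name: str) -> int:
    return sum(1 for e in events.get(name, []) if e.kind == "entry")


def _freezing_by_region(
    traj: Trajectory, cfg: TrackingConfig, labels: np.ndarray
) -> tuple[float, dict[str, float], list[tuple[int, int]]]:
    """Total freezing time and per-region attribution.

    Each freezing episode is attributed to the region occupied at its
    first frame.
    """
    episodes, total = freezing_intervals(traj, cfg)
    per: dict[str, float] = {}
    for a, b in episodes:
        dur = (b - a) / traj.fps
        per[labels[a]] = per.get(labels[a], 0.0) + dur
    return total, per, episodes


def alternation_percent(entry_sequence, allow_repeats: bool = False):
    """Spontaneous alternation: % of consecutive entry triplets visiting
    three different arms, out of all ``n - 2`` sliding triplets.

    Returns None when fewer than 3 entries were made.  A well-formed
    hysteresis event stream has no two consecutive identical labels;
    by default such a stream raises, while ``allow_repeats=True`` scores
    repeat-containing triplets as simply non-alternating.
    """
    seq = list(entry_sequence)
    if not allow_repeats:
        for a, b in zip(seq, seq[1:]):
            if a == b:
                raise ValueError(
                    "consecutive duplicate arm entries: malformed event stream"
                )
    n = len(seq)
    if n < 3:
        return None
    hits = sum(1 for i in range(n - 2) if len(set(seq[i : i + 3])) == 3)
    return 100.0 * hits / (n - 2)


# ---------------------------------------------------------------------------
# per-test scorers


def _common_kinematics(result: TestResult, traj: Trajectory) -> None:
    result.add("distance_total_cm", traj.total_distance_cm, "cm")
    dur = traj.duration_s
    result.add("speed_avg_cms", traj.total_distance_cm / dur if dur else 0.0, "cm/s")


def score_open_field(
    traj: Trajectory,
    geometry: MazeGeometry,
    occupancy: np.ndarray,
    rules: RegionRuleSet | None = None,
    tracking: TrackingConfig | None = None,
) -> TestResult:
    """Open-field metrics: distance/time in center vs outer region, center
    entries, freezing (total and per region), average speed."""
    if geometry.maze_type != "OF":
        raise ValueError("geometry is not an open field")
    rules = rules or DEFAULT_RULES["OF"]
    tracking = tracking or TrackingConfig()
    labels, events = build_region_timeline(
        occupancy, geometry.partition, rules, traj.fps, geometry.transition_region
    )
    res = TestResult("OF", events=events, labels=labels)
    _common_kinematics(res, traj)
    res.add("distance_center_cm", _distance_in(labels, "center", traj), "cm")
    res.add("distance_outer_cm", _distance_in(labels, "outer", traj), "cm")
    res.add("time_center_s", _time_in(labels, "center", traj.fps), "s")
    res.add("time_outer_s", _time_in(labels, "outer", traj.fps), "s")
    res.add("entries_center", _entry_count(events, "center"), "count")
    total, per, _ = _freezing_by_region(traj, tracking, labels)
    res.add("freezing_total_s", total, "s")
    res.add("freezing_center_s", per.get("center", 0.0), "s")
    res.add("freezing_outer_s", per.get("outer", 0.0), "s")
    return res


def edge_overlap_series(masks: list, zone_raster: np.ndarray) -> np.ndarray:
    """Per-frame count of blob pixels overlapping the edge zones.

    ``masks`` holds one boolean mask (or None) per frame; None contributes
    zero overlap.
    """
    out = np.zeros(len(masks), dtype=int)
    for i, m in enumerate(masks):
        if m is not None:
            out[i] = int(np.sum(m & zone_raster))
    return out


def detect_head_dips(
    overlap_px2: np.ndarray,
    in_open_arm: np.ndarray,
    min_overlap_px2: int = 20,
    min_gap_frames: int = 5,
) -> tuple[int, list[tuple[int, int]]]:
    """Count head-dip events over the open-arm edges.

    An event is a maximal run of frames where the animal is in an open arm
    and its mask overlaps an edge zone by at least ``min_overlap_px2``;
    runs separated by fewer than ``min_gap_frames`` frames merge into one.
    """
    active = (np.asarray(overlap_px2) >= min_overlap_px2) & np.asarray(in_open_arm)
    runs = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(active) - 1])
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < min_gap_frames:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return len(merged), [tuple(r) for r in merged]


def score_epm(
    traj: Trajectory,
    geometry: MazeGeometry,
    occupancy: np.ndarray,
    masks: list | None = None,
    rules: RegionRuleSet | None = None,
    tracking: TrackingConfig | None = None,
    min_overlap_px2: int = 20,
    min_gap_frames: int = 5,
) -> TestResult:
    """Elevated-plus-maze metrics: entries and time in open/closed arms
    and center, per-class distance, head dips, average speed."""
    if geometry.maze_type != "EPM":
        raise ValueError("geometry is not an elevated plus maze")
    rules = rules or DEFAULT_RULES["EPM"]
    tracking = tracking or TrackingConfig()
    labels, events = build_region_timeline(
        occupancy, geometry.partition, rules, traj.fps, geometry.transition_region
    )
    open_arms = geometry.meta["open_arms"]
    closed_arms = geometry.meta["closed_arms"]
    res = TestResult("EPM", events=events, labels=labels)
    _common_kinematics(res, traj)
    res.add("entries_open", sum(_entry_count(events, a) for a in open_arms), "count")
    res.add("entries_closed", sum(_entry_count(events, a) for a in closed_arms), "count")
    res.add("time_open_s", _time_in(labels, open_arms, traj.fps), "s")
    res.add("time_closed_s", _time_in(labels, closed_arms, traj.fps), "s")
    res.add("time_center_s", _time_in(labels, "center", traj.fps), "s")
    res.add("distance_open_cm", _distance_in(labels, open_arms, traj), "cm")
    res.add("distance_closed_cm", _distance_in(labels, closed_arms, traj), "cm")
    res.add("distance_center_cm", _distance_in(labels, "center", traj), "cm")
    if masks is not None:
        zone = np.zeros(geometry.image_shape, bool)
        for zn in geometry.edge_zones:
            zone |= geometry.region(zn).rasterize(geometry.image_shape)
        overlap = edge_overlap_series(masks, zone)
        in_open = np.isin(labels, open_arms)
        n_dips, dip_runs = detect_head_dips(
            overlap, in_open, min_overlap_px2, min_gap_frames
        )
        res.add("head_dips", n_dips, "count")
        res.extras["head_dip_runs"] = dip_runs
    return res


def score_ymaze(
    traj: Trajectory,
    geometry: MazeGeometry,
    occupancy: np.ndarray,
    rules: RegionRuleSet | None = None,
    tracking: TrackingConfig | None = None,
) -> TestResult:
    """Y-maze metrics: per-arm visits, times, first-visit latencies, entry
    order, spontaneous alternation, distance and speed."""
    if geometry.maze_type != "YM":
        raise ValueError("geometry is not a Y-maze")
    rules = rules or DEFAULT_RULES["YM"]
    tracking = tracking or TrackingConfig()
    arms = geometry.meta["arms"]
    # the central triangle is a transition zone, not a scored region: visits
    # are defined for the three arms only
    cols = [geometry.partition.index(a) for a in arms]
    labels, events = build_region_timeline(
        np.asarray(occupancy)[:, cols], arms, rules, traj.fps,
        geometry.transition_region,
    )
    res = TestResult("YM", events=events, labels=labels)
    _common_kinematics(res, traj)
    entry_events = sorted(
        (e for a in arms for e in events[a] if e.kind == "entry"),
        key=lambda e: e.frame,
    )
    seq = [e.region for e in entry_events]
    res.extras["entry_sequence"] = seq
    for arm in arms:
        res.add(f"visits_{arm}", _entry_count(events, arm), "count")
        res.add(f"time_{arm}_s", _time_in(labels, arm, traj.fps), "s")
        first = next((e for e in events[arm] if e.kind == "entry"), None)
        res.add(f"latency_{arm}_s", first.time_s if first else None, "s")
    alt = alternation_percent(seq, allow_repeats=True)
    res.add("alternation_pct", alt if alt is not None else "n/a", "%")
    return res


def score_mwm(
    traj: Trajectory,
    geometry: MazeGeometry,
    occupancy: np.ndarray,
    platform_series: np.ndarray,
    wall_band_series: np.ndarray,
    rules: RegionRuleSet | None = None,
    tracking: TrackingConfig | None = None,
    platform_min_dwell_frames: int = 0,
) -> TestResult:
    """Water-maze metrics: platform latency (or the "Did not find
    platform" sentinel), per-quadrant time and distance, wall-band time,
    distance and average speed.

    ``occupancy`` is the one-hot centroid occupancy of the quadrants;
    ``platform_series`` / ``wall_band_series`` are per-frame booleans for
    the centroid being on the platform disc / in the wall band.
    """
    if geometry.maze_type != "MWM":
        raise ValueError("geometry is not a water maze")
    rules = rules or DEFAULT_RULES["MWM"]
    tracking = tracking or TrackingConfig()
    labels, events = build_region_timeline(
        occupancy, geometry.partition, rules, traj.fps, geometry.transition_region
    )
    res = TestResult("MWM", events=events, labels=labels)
    _common_kinematics(res, traj)
    platform = np.asarray(platform_series, dtype=bool)
    latency_frame = None
    if platform_min_dwell_frames <= 0:
        hits = np.nonzero(platform)[0]
        latency_frame = int(hits[0]) if len(hits) else None
    else:
        run = 0
        for i, p in enumerate(platform):
            run = run + 1 if p else 0
            if run >= platform_min_dwell_frames:
                latency_frame = i - platform_min_dwell_frames + 1
                break
    found = latency_frame is not None
    res.flags["platform_found"] = found
    res.add(
        "latency_platform_s",
        latency_frame / traj.fps if found else NOT_FOUND_SENTINEL,
        "s",
    )
    for q in geometry.partition:
        res.add(f"time_{q}_s", _time_in(labels, q, traj.fps), "s")
        res.add(f"distance_{q}_cm", _distance_in(labels, q, traj), "cm")
    wall = np.asarray(wall_band_series, dtype=bool)
    res.add("time_wall_band_s", float(np.sum(wall[:-1]) / traj.fps), "s")
    return res
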