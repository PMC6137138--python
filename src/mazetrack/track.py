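"""Trajectory construction: displacement, speed, distance, freezing.

Per-frame centroids become a trajectory with per-interval Euclidean
displacement ``dd(i, i+1) = sqrt((x_{i+1}-x_i)^2 + (y_{i+1}-y_i)^2)`` and
speed ``s = dd / dt`` where ``dt = 1/fps``.  Intervals whose displacement
falls below a settable movement threshold are treated as "did not move":
they contribute zero to distance and to the speed numerator (elapsed time
always counts).  This absorbs the sub-pixel centroid jitter caused by
frame-to-frame threshold variance.

Freezing — the complete absence of locomotion — is a maximal run of
consecutive stationary intervals lasting at least a minimum duration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detect import BlobDetection
from .errors import EmptyTrackError
from .video_io import FrameStack


@dataclass(frozen=True)
class TrackingConfig:
    """movement_threshold_px: displacements below this count as no movement.
    freeze_min_duration_s: shortest stationary run reported as freezing."""

    movement_threshold_px: float = 1.0
    freeze_min_duration_s: float = 0.5

    def __post_init__(self):
        if self.movement_threshold_px < 0 or self.freeze_min_duration_s < 0:
            raise ValueError("tracking thresholds must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """Centroid track plus derived per-interval series.

    Arrays ``dd_px_raw``, ``dd_px``, ``stationary``, ``imputed`` have length
    T - 1 (one entry per inter-frame interval); position arrays have length
    T.  ``dd_px`` is the effective displacement after movement-threshold
    suppression; ``imputed`` marks intervals touching an undetected frame,
    which carry dd = 0 so tracking dropouts add no phantom distance.
    """

    x_px: np.ndarray
    y_px: np.ndarray
    detected: np.ndarray
    fps: float
    pixel_size: float
    movement_threshold_px: float
    dd_px_raw: np.ndarray
    dd_px: np.ndarray
    stationary: np.ndarray
    imputed: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.x_px)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) / self.fps

    @property
    def dd_cm(self) -> np.ndarray:
        """Effective per-interval displacement in cm."""
        return self.dd_px * self.pixel_size

    @property
    def speed_cms(self) -> np.ndarray:
        """Per-interval speed s = dd/dt in cm/s (after suppression)."""
        return self.dd_cm * self.fps

    @property
    def total_distance_cm(self) -> float:
        return float(np.sum(self.dd_cm))

    def positions_px(self) -> np.ndarray:
        return np.column_stack([self.x_px, self.y_px])


def build_trajectory(
    detections: list[BlobDetection | None],
    stack: FrameStack,
    cfg: TrackingConfig,
) -> Trajectory:
    """Assemble the trajectory from per-frame detections.

    Undetected frames carry the last known centroid forward (the first
    known centroid backward at the start of the video); every interval
    touching such a frame is flagged imputed and contributes dd = 0.
    """
    if len(detections) != stack.n_frames:
        raise ValueError("one detection slot per frame required")
    det = np.array([d is not None for d in detections], dtype=bool)
    if not det.any():
        raise EmptyTrackError("no frame produced a detection")
    T = len(detections)
    x = np.empty(T)
    y = np.empty(T)
    first = int(np.argmax(det))
    last_xy = detections[first].centroid
    for i in range(T):
        if det[i]:
            last_xy = detections[i].centroid
        x[i], y[i] = last_xy
    dd_raw = np.hypot(np.diff(x), np.diff(y))
    imputed = ~(det[:-1] & det[1:])
    dd_raw = np.where(imputed, 0.0, dd_raw)
    traj = Trajectory(
        x_px=x,
        y_px=y,
        detected=det,
        fps=stack.fps,
        pixel_size=stack.pixel_size,
        movement_threshold_px=cfg.movement_threshold_px,
        dd_px_raw=dd_raw,
        dd_px=dd_raw.copy(),
        stationary=np.zeros(T - 1, bool),
        imputed=imputed,
    )
    return apply_movement_threshold(traj, cfg)


def apply_movement_threshold(traj: Trajectory, cfg: TrackingConfig) -> Trajectory:
    """Suppress sub-threshold displacements: dd -> 0, stationary -> True.

    With threshold 0 nothing is suppressed and no interval is stationary
    (the threshold is disabled); imputed intervals are always stationary.
    """
    thr = cfg.movement_threshold_px
    stationary = (traj.dd_px_raw < thr) | traj.imputed
    dd = np.where(stationary, 0.0, traj.dd_px_raw)
    return replace(
        traj, dd_px=dd, stationary=stationary, movement_threshold_px=thr
    )


def stationary_runs(stationary: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (first_interval, last_interval) index pairs."""
    runs = []
    start = None
    for i, s in enumerate(stationary):
        if s and start is None:
            start = i
        elif not s and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(stationary) - 1))
    return runs


def freezing_intervals(
    traj: Trajectory, cfg: TrackingConfig
) -> tuple[list[tuple[int, int]], float]:
    """Freezing episodes and total freezing time.

    An episode is a maximal run of stationary intervals whose duration
    (number of intervals / fps) is at least ``freeze_min_duration_s``.
    Returned as (start_frame, end_frame) pairs; the episode spans frames
    ``start_frame .. end_frame`` inclusive.
    """
    episodes = []
    total = 0.0
    for a, b in stationary_runs(traj.stationary):
        dur = (b - a + 1) / traj.fps
        if dur >= cfg.freeze_min_duration_s:
            episodes.append((a, b + 1))
            total += dur
    return episodes, total


def average_speed(traj: Trajectory) -> float:
    """Total distance (after suppression) over total elapsed time, cm/s."""
    if traj.duration_s == 0:
        return 0.0
    return traj.total_distance_cm / traj.duration_s
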