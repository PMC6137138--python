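"""Result tables, saved ROIs, parameters file, heat map and trajectory map.

Each analysis run produces two tables — a frame-by-frame table and an
overall summary — plus the maze geometry (the "ROIs" of the analysis), a
parameters file sufficient to repeat the analysis, and the two track maps
(occupancy heat map and trajectory polyline).  CSV (UTF-8, '.' decimal) is
the canonical, byte-reproducible format; xlsx twins are optional.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .geometry import MazeGeometry
from .scoring import TestResult
from .track import Trajectory

REQUIRED_PARAM_KEYS = (
    "version",
    "input",
    "maze_type",
    "geometry",
    "detection",
    "tracking",
    "rules",
    "preprocess",
    "output_stem",
)


@dataclass
class HeatMap:
    """2-D occupancy histogram of centroid positions.

    The sum over all bins equals the number of detected frames: each
    detected frame deposits one count in the bin under its centroid.
    """

    bins: np.ndarray
    bin_size_px: float
    extent: tuple[float, float, float, float]  # (x0, x1, y0, y1)

    @property
    def total(self) -> int:
        return int(self.bins.sum())


def framewise_dataframe(
    traj: Trajectory,
    occupancy: np.ndarray | None = None,
    occupancy_names: list[str] | None = None,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """One row per frame; interval quantities (displacement, speed,
    stationary) are written on the row of the interval's end frame, with
    zeros on frame 0."""
    T = traj.n_frames
    pad = lambda a, v=0.0: np.concatenate([[v], a])
    data = {
        "frame": np.arange(T),
        "time_s": traj.times_s,
        "x_px": traj.x_px,
        "y_px": traj.y_px,
        "x_cm": traj.x_px * traj.pixel_size,
        "y_cm": traj.y_px * traj.pixel_size,
        "dd_cm": pad(traj.dd_cm),
        "speed_cms": pad(traj.speed_cms),
        "stationary": pad(traj.stationary, False).astype(bool),
        "detected": traj.detected.astype(bool),
        "imputed": pad(traj.imputed, False).astype(bool),
    }
    df = pd.DataFrame(data)
    if occupancy is not None and occupancy_names:
        for k, name in enumerate(occupancy_names):
            df[f"occ_{name}"] = occupancy[:, k]
    if labels is not None:
        df["region"] = labels
    return df


def write_framewise_table(
    traj: Trajectory,
    occupancy: np.ndarray | None,
    occupancy_names: list[str] | None,
    labels: np.ndarray | None,
    path,
    xlsx: bool = False,
) -> Path:
    path = Path(path)
    df = framewise_dataframe(traj, occupancy, occupancy_names, labels)
    df.to_csv(path, index=False, lineterminator="\n")
    if xlsx:
        df.to_excel(path.with_suffix(".xlsx"), index=False)
    return path


def write_summary(result: TestResult, path, xlsx: bool = False) -> Path:
    """Summary table: one row per metric (name, value, unit).

    Sentinel strings (e.g. "Did not find platform") pass through verbatim;
    boolean flags are appended as their own rows.
    """
    path = Path(path)
    rows = [
        {"metric": k, "value": v, "unit": result.units.get(k, "")}
        for k, v in result.metrics.items()
    ]
    rows += [{"metric": k, "value": v, "unit": "flag"} for k, v in result.flags.items()]
    df = pd.DataFrame(rows, columns=["metric", "value", "unit"])
    df.to_csv(path, index=False, lineterminator="\n")
    if xlsx:
        df.to_excel(path.with_suffix(".xlsx"), index=False)
    return path


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_parameters(params: dict, path) -> Path:
    """Persist every preference/parameter of a run as YAML.

    The file is a complete, replayable description: feeding it back
    through the pipeline reproduces identical outputs.
    """
    path = Path(path)
    missing = [k for k in REQUIRED_PARAM_KEYS if k not in params]
    if missing:
        raise ConfigError(f"parameters document missing keys: {missing}")
    path.write_text(yaml.safe_dump(params, sort_keys=False))
    return path


def load_parameters(path) -> dict:
    params = yaml.safe_load(Path(path).read_text())
    if not isinstance(params, dict):
        raise ConfigError("parameters file does not contain a mapping")
    for key in REQUIRED_PARAM_KEYS:
        if key not in params:
            raise ConfigError(f"parameters file missing required key '{key}'")
    return params


def write_rois(geometry: MazeGeometry, path) -> Path:
    return geometry.save(path)


def write_mask_stack(blobs: list, image_shape: tuple[int, int], path) -> Path:
    """Per-frame animal masks as a labeled multi-page TIFF (255 = animal).

    Frames without a detection (or whose mask was dropped) are blank.
    """
    import tifffile

    out = np.zeros((len(blobs), *image_shape), np.uint8)
    for i, b in enumerate(blobs):
        if b is not None and b.mask is not None:
            out[i][b.mask] = 255
    path = Path(path)
    tifffile.imwrite(path, out)
    return path


def write_perimeters_csv(blobs: list, path) -> Path:
    """Selected-animal perimeter points as (frame, point_index, x, y)."""
    rows = []
    for i, b in enumerate(blobs):
        if b is None:
            continue
        for j, (x, y) in enumerate(b.perimeter_points):
            rows.append((i, j, x, y))
    df = pd.DataFrame(rows, columns=["frame", "point_index", "x", "y"])
    path = Path(path)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def make_heat_map(
    traj: Trajectory,
    geometry: MazeGeometry,
    bin_size_px: float = 10.0,
    path=None,
) -> HeatMap:
    """Centroid occupancy histogram over the arena; optionally rendered.

    Default bin size of 10 px is about the animal's minor axis at typical
    calibrations.
    """
    if bin_size_px <= 0:
        raise ValueError("bin size must be > 0")
    H, W = geometry.image_shape
    xe = np.arange(0, W + bin_size_px, bin_size_px)
    ye = np.arange(0, H + bin_size_px, bin_size_px)
    det = traj.detected
    bins, _, _ = np.histogram2d(traj.x_px[det], traj.y_px[det], bins=[xe, ye])
    hm = HeatMap(bins=bins.T, bin_size_px=bin_size_px, extent=(0, W, 0, H))
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(W / 100, H / 100), dpi=100)
        ax.imshow(hm.bins, cmap="inferno", extent=(0, W, H, 0), aspect="equal")
        ax.set_axis_off()
        fig.subplots_adjust(0, 0, 1, 1)
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return hm


@dataclass
class TrajectoryMap:
    """Polyline of centroids plus the segments hidden by dropouts."""

    polyline: np.ndarray  # (T, 2) centroid positions
    gap_segments: list  # [(i, i+1), ...] intervals with an undetected end
    image_size: tuple[int, int]  # (W, H)


def make_trajectory_map(traj: Trajectory, geometry: MazeGeometry, path=None) -> TrajectoryMap:
    """Pathway map: centroid polyline over the maze outline.

    Intervals touching an undetected frame are rendered dashed-grey so
    tracking dropouts are visible.  The written image has exactly the
    frame dimensions.
    """
    H, W = geometry.image_shape
    poly = traj.positions_px()
    gaps = [(i, i + 1) for i in range(traj.n_frames - 1) if traj.imputed[i]]
    tm = TrajectoryMap(polyline=poly, gap_segments=gaps, image_size=(W, H))
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(W / 100, H / 100), dpi=100)
        for region in geometry.regions.values():
            g = region.geom
            boundaries = [g.exterior] if hasattr(g, "exterior") else []
            if hasattr(g, "geoms"):
                boundaries = [p.exterior for p in g.geoms]
            for b in boundaries:
                bx, by = np.asarray(b.coords).T
                ax.plot(bx, by, color="0.7", lw=0.8)
        ok = ~traj.imputed
        segs = np.stack([poly[:-1], poly[1:]], axis=1)
        for seg in segs[ok]:
            ax.plot(seg[:, 0], seg[:, 1], color="tab:blue", lw=0.9)
        for seg in segs[~ok]:
            ax.plot(seg[:, 0], seg[:, 1], color="0.5", lw=0.9, ls="--")
        ax.set_xlim(0, W)
        ax.set_ylim(H, 0)
        ax.set_axis_off()
        fig.subplots_adjust(0, 0, 1, 1)
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return tm
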