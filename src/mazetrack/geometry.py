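"""Maze geometry: named regions and per-frame occupancy.

Regions live in pixel coordinates (x=column, y=row, origin top-left) with
the cm-per-pixel factor attached to the :class:`MazeGeometry`, so scored
quantities can be reported in cm without re-rasterizing.  Shapes are
shapely geometries; a point on a region boundary counts as inside
(``covers`` semantics), and wherever a single assignment is needed the tie
goes to the lower-index region of the geometry's partition.

The animal's position inside a region is quantified two ways, matching the
two rule families used by the scoring layer:

* perimeter fraction — the fraction of the blob's perimeter points that
  fall inside the region (used with the 70%/80%/90% entry rules);
* center of mass — whether the blob centroid is inside (the water-maze
  rule).

Parametric builders construct the four standard mazes; arbitrary
user-drawn polygons can be loaded from the same JSON serialization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, box

_QUAD_SEGS = 96  # circle rasterization fineness; area error < 1e-4


def _geom_from_spec(spec: dict):
    t = spec["type"]
    if t == "polygon":
        return Polygon(spec["vertices"], holes=spec.get("holes"))
    if t == "circle":
        return Point(spec["center"]).buffer(spec["radius"], quad_segs=_QUAD_SEGS)
    if t == "annulus":
        outer = Point(spec["center"]).buffer(spec["r_outer"], quad_segs=_QUAD_SEGS)
        inner = Point(spec["center"]).buffer(spec["r_inner"], quad_segs=_QUAD_SEGS)
        return outer.difference(inner)
    if t == "circle_box":
        circ = Point(spec["center"]).buffer(spec["radius"], quad_segs=_QUAD_SEGS)
        return circ.intersection(box(*spec["bbox"]))
    raise ValueError(f"unknown region spec type '{t}'")


@dataclass
class Region:
    """A named maze region; ``spec`` is the serializable descriptor the
    shapely geometry is (re)built from, so saved geometry reloads
    identically."""

    name: str
    spec: dict
    geom: object = None

    def __post_init__(self):
        if self.geom is None:
            self.geom = _geom_from_spec(self.spec)
        if self.geom.area <= 0:
            raise ValueError(f"region '{self.name}' has zero area")
        if not self.geom.is_valid:
            raise ValueError(f"region '{self.name}' is not a simple geometry")
        shapely.prepare(self.geom)

    @classmethod
    def from_polygon(cls, name: str, vertices, holes=None) -> "Region":
        spec = {"type": "polygon", "vertices": [list(map(float, v)) for v in vertices]}
        if holes:
            spec["holes"] = [[list(map(float, v)) for v in h] for h in holes]
        return cls(name, spec)

    @classmethod
    def from_circle(cls, name, center, radius) -> "Region":
        return cls(name, {"type": "circle", "center": list(map(float, center)),
                          "radius": float(radius)})

    @classmethod
    def from_annulus(cls, name, center, r_inner, r_outer) -> "Region":
        return cls(name, {"type": "annulus", "center": list(map(float, center)),
                          "r_inner": float(r_inner), "r_outer": float(r_outer)})

    @classmethod
    def from_circle_box(cls, name, center, radius, bbox) -> "Region":
        return cls(name, {"type": "circle_box", "center": list(map(float, center)),
                          "radius": float(radius), "bbox": list(map(float, bbox))})

    def covers_points(self, pts: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership of an (N, 2) array of (x, y)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return shapely.covers(self.geom, shapely.points(pts))

    def covers_point(self, pt) -> bool:
        return bool(self.covers_points(np.asarray(pt))[0])

    def rasterize(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centers the region covers."""
        H, W = image_shape
        minx, miny, maxx, maxy = self.geom.bounds
        x0, x1 = max(0, int(minx)), min(W - 1, int(math.ceil(maxx)))
        y0, y1 = max(0, int(miny)), min(H - 1, int(math.ceil(maxy)))
        out = np.zeros((H, W), bool)
        if x1 < x0 or y1 < y0:
            return out
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        out[y0 : y1 + 1, x0 : x1 + 1] = self.covers_points(pts).reshape(xs.shape)
        return out


@dataclass
class MazeGeometry:
    """Named regions of one maze plus calibration and image extent.

    ``partition`` lists the region names that exhaustively tile the arena
    (OF: center/outer; EPM: four arms + center; YM: three arms + center
    triangle; MWM: four quadrants); its order is the tie-break order for
    boundary points.  ``transition_region`` is where the animal is deemed
    to be between a region exit and the next entry.
    """

    maze_type: str
    regions: dict[str, Region]
    partition: list[str]
    pixel_size: float
    image_shape: tuple[int, int]
    transition_region: str | None = None
    edge_zones: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.maze_type not in ("OF", "EPM", "YM", "MWM"):
            raise ValueError("maze_type must be one of OF, EPM, YM, MWM")
        for name in self.partition:
            if name not in self.regions:
                raise ValueError(f"partition names unknown region '{name}'")

    def region(self, name: str) -> Region:
        return self.regions[name]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "maze_type": self.maze_type,
            "pixel_size": self.pixel_size,
            "image_shape": list(self.image_shape),
            "partition": list(self.partition),
            "transition_region": self.transition_region,
            "edge_zones": list(self.edge_zones),
            "meta": self.meta,
            "regions": [{"name": r.name, "spec": r.spec} for r in self.regions.values()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MazeGeometry":
        regions = {e["name"]: Region(e["name"], e["spec"]) for e in d["regions"]}
        return cls(
            maze_type=d["maze_type"],
            regions=regions,
            partition=list(d["partition"]),
            pixel_size=float(d["pixel_size"]),
            image_shape=tuple(d["image_shape"]),
            transition_region=d.get("transition_region"),
            edge_zones=list(d.get("edge_zones", [])),
            meta=d.get("meta", {}),
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path) -> "MazeGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# occupancy


def occupancy_fraction(blob, region: Region) -> float:
    """Fraction of the blob's perimeter points inside one region
    (boundary-inclusive, independent of any partition)."""
    pts = np.asarray(blob.perimeter_points, dtype=float)
    if len(pts) == 0:
        return 0.0
    return float(region.covers_points(pts).mean())


def center_of_mass_in(blob, region: Region) -> bool:
    """Whether the blob centroid lies inside the region (boundary counts)."""
    return region.covers_point(blob.centroid)


def partition_fractions(
    pts: np.ndarray, geometry: MazeGeometry, names: list[str] | None = None
) -> np.ndarray:
    """Fractions of points assigned to each partition region.

    Each point goes to the first (lowest-index) region that covers it, so
    shared boundary pixels are counted once and fractions over an
    exhaustive partition sum to exactly 1.
    """
    names = names if names is not None else geometry.partition
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    n = len(pts)
    out = np.zeros(len(names))
    unassigned = np.ones(n, bool)
    for k, name in enumerate(names):
        if not unassigned.any():
            break
        cov = geometry.region(name).covers_points(pts[unassigned])
        out[k] = cov.sum() / n
        idx = np.nonzero(unassigned)[0][cov]
        unassigned[idx] = False
    return out


def assign_point(pt, geometry: MazeGeometry, names: list[str] | None = None) -> str | None:
    """First partition region covering the point, or None."""
    names = names if names is not None else geometry.partition
    for name in names:
        if geometry.region(name).covers_point(pt):
            return name
    return None


def perimeter_occupancy_series(
    blobs: list, geometry: MazeGeometry, names: list[str] | None = None
) -> np.ndarray:
    """(T, R) matrix of perimeter-fraction occupancy for each frame.

    Undetected frames repeat the previous frame's row (the centroid is
    carried forward by the tracker in the same way); leading undetected
    frames copy the first detection.
    """
    names = names if names is not None else geometry.partition
    T = len(blobs)
    out = np.zeros((T, len(names)))
    first = next((i for i, b in enumerate(blobs) if b is not None), None)
    if first is None:
        return out
    row = partition_fractions(blobs[first].perimeter_points, geometry, names)
    for i in range(T):
        if blobs[i] is not None:
            row = partition_fractions(blobs[i].perimeter_points, geometry, names)
        out[i] = row
    return out


def centroid_occupancy_series(
    positions: np.ndarray, geometry: MazeGeometry, names: list[str] | None = None
) -> np.ndarray:
    """(T, R) one-hot occupancy by the center-of-mass rule."""
    names = names if names is not None else geometry.partition
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    out = np.zeros((len(pts), len(names)))
    unassigned = np.ones(len(pts), bool)
    for k, name in enumerate(names):
        cov = geometry.region(name).covers_points(pts[unassigned])
        idx = np.nonzero(unassigned)[0][cov]
        out[idx, k] = 1.0
        unassigned[idx] = False
    return out


# ---------------------------------------------------------------------------
# parametric builders


def make_open_field(
    field_cm: float = 38.0,
    grid_n: int = 5,
    center_n: int = 3,
    pixel_size: float = 0.2,
    arena_origin_px: tuple[float, float] | None = None,
    margin_px: float = 10.5,
) -> MazeGeometry:
    """Square open-field arena split into a grid with a central block.

    The floor is divided into ``grid_n`` x ``grid_n`` cells (default 5x5 of
    a 38 cm field: 7.6 cm cells) and the center region is the middle
    ``center_n`` x ``center_n`` block (default 3x3: 22.8 cm); the outer
    region is its complement within the arena.  The default margin places
    region edges between pixel centers, which keeps boundary-pixel
    membership unbiased.
    """
    if not 0 < center_n < grid_n:
        raise ValueError("require 0 < center_n < grid_n")
    if field_cm <= 0 or pixel_size <= 0:
        raise ValueError("field_cm and pixel_size must be > 0")
    F = field_cm / pixel_size
    ox, oy = arena_origin_px if arena_origin_px is not None else (margin_px, margin_px)
    cell = F / grid_n
    off = (grid_n - center_n) / 2 * cell
    cx0, cy0 = ox + off, oy + off
    side = center_n * cell
    arena = [(ox, oy), (ox + F, oy), (ox + F, oy + F), (ox, oy + F)]
    center_v = [(cx0, cy0), (cx0 + side, cy0), (cx0 + side, cy0 + side), (cx0, cy0 + side)]
    regions = {
        "center": Region.from_polygon("center", center_v),
        "outer": Region.from_polygon("outer", arena, holes=[center_v]),
    }
    H = W = int(math.ceil(F + 2 * margin_px))
    return MazeGeometry(
        maze_type="OF",
        regions=regions,
        partition=["center", "outer"],
        pixel_size=pixel_size,
        image_shape=(H, W),
        transition_region="outer",
        meta={
            "field_cm": field_cm,
            "grid_n": grid_n,
            "center_n": center_n,
            "cell_side_cm": field_cm / grid_n,
            "center_side_cm": field_cm / grid_n * center_n,
            "arena_origin_px": [ox, oy],
        },
    )


def make_epm(
    arm_length_cm: float = 25.0,
    arm_width_cm: float = 7.0,
    center_side_cm: float = 8.0,
    orientation: str = "open-horizontal",
    pixel_size: float = 0.2,
    center_px: tuple[float, float] | None = None,
    edge_zone_cm: float = 1.5,
    margin_px: float = 12.5,
) -> MazeGeometry:
    """Elevated plus maze: two open and two closed arms around a center.

    Default dimensions: 25 x 7 cm arms, 8 x 8 cm central area.  Open arms
    lie on the horizontal axis (or vertical for ``orientation="open-
    vertical"``); thin edge zones of width ``edge_zone_cm`` flank the long
    sides of each open arm for head-dip detection and never intersect any
    arm interior.
    """
    if min(arm_length_cm, arm_width_cm, center_side_cm, pixel_size) <= 0:
        raise ValueError("all maze dimensions must be > 0")
    L = arm_length_cm / pixel_size
    w = arm_width_cm / pixel_size
    c = center_side_cm / pixel_size
    ez = edge_zone_cm / pixel_size
    half = c / 2 + L
    if center_px is None:
        center_px = (half + margin_px, half + margin_px)
    cx, cy = center_px

    def rect(x0, y0, x1, y1):
        return [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]

    horiz = orientation != "open-vertical"

    def oriented(x0, y0, x1, y1):
        # coordinates given for open arms on the horizontal axis
        if horiz:
            return rect(cx + x0, cy + y0, cx + x1, cy + y1)
        return rect(cx + y0, cy + x0, cx + y1, cy + x1)

    regions = {}
    regions["open_arm_1"] = Region.from_polygon(
        "open_arm_1", oriented(-c / 2 - L, -w / 2, -c / 2, w / 2)
    )
    regions["open_arm_2"] = Region.from_polygon(
        "open_arm_2", oriented(c / 2, -w / 2, c / 2 + L, w / 2)
    )
    # closed arms are perpendicular to the open arms
    if horiz:
        regions["closed_arm_1"] = Region.from_polygon(
            "closed_arm_1", rect(cx - w / 2, cy - c / 2 - L, cx + w / 2, cy - c / 2)
        )
        regions["closed_arm_2"] = Region.from_polygon(
            "closed_arm_2", rect(cx - w / 2, cy + c / 2, cx + w / 2, cy + c / 2 + L)
        )
    else:
        regions["closed_arm_1"] = Region.from_polygon(
            "closed_arm_1", rect(cx - c / 2 - L, cy - w / 2, cx - c / 2, cy + w / 2)
        )
        regions["closed_arm_2"] = Region.from_polygon(
            "closed_arm_2", rect(cx + c / 2, cy - w / 2, cx + c / 2 + L, cy + w / 2)
        )
    regions["center"] = Region.from_polygon(
        "center", rect(cx - c / 2, cy - c / 2, cx + c / 2, cy + c / 2)
    )
    edge_zones = []
    for arm, (x0, x1) in (("open_arm_1", (-c / 2 - L, -c / 2)), ("open_arm_2", (c / 2, c / 2 + L))):
        for side, (y0, y1) in (("a", (-w / 2 - ez, -w / 2)), ("b", (w / 2, w / 2 + ez))):
            name = f"edge_{arm}_{side}"
            regions[name] = Region.from_polygon(name, oriented(x0, y0, x1, y1))
            edge_zones.append(name)
    H = W = int(math.ceil(2 * half + 2 * margin_px))
    return MazeGeometry(
        maze_type="EPM",
        regions=regions,
        partition=["open_arm_1", "open_arm_2", "closed_arm_1", "closed_arm_2", "center"],
        pixel_size=pixel_size,
        image_shape=(H, W),
        transition_region="center",
        edge_zones=edge_zones,
        meta={
            "arm_length_cm": arm_length_cm,
            "arm_width_cm": arm_width_cm,
            "center_side_cm": center_side_cm,
            "edge_zone_cm": edge_zone_cm,
            "orientation": orientation,
            "center_px": [cx, cy],
            "open_arms": ["open_arm_1", "open_arm_2"],
            "closed_arms": ["closed_arm_1", "closed_arm_2"],
        },
    )


def make_ymaze(
    arm_length_cm: float = 35.0,
    arm_width_cm: float = 7.0,
    pixel_size: float = 0.25,
    center_px: tuple[float, float] | None = None,
    base_angle_deg: float = 90.0,
    margin_px: float = 12.0,
) -> MazeGeometry:
    """Y-maze: three rectangular arms at 120 degrees around a central
    triangle.

    The central region is the equilateral triangle (side = arm width)
    bounded by the three arm mouths; arm ``arm_center`` points along
    ``base_angle_deg`` (degrees, image convention: 90 points down), with
    ``arm_left`` and ``arm_right`` at +120 and +240 degrees.
    """
    if min(arm_length_cm, arm_width_cm, pixel_size) <= 0:
        raise ValueError("all maze dimensions must be > 0")
    L = arm_length_cm / pixel_size
    w = arm_width_cm / pixel_size
    r = w / (2 * math.sqrt(3))  # incircle radius of the central triangle
    if center_px is None:
        side = 2 * (r + L) + 2 * margin_px
        center_px = (side / 2, side / 2)
    cx, cy = center_px
    names = ["arm_center", "arm_left", "arm_right"]
    regions = {}
    angles = []
    for k, name in enumerate(names):
        th = math.radians(base_angle_deg + 120 * k)
        angles.append(th)
        ux, uy = math.cos(th), math.sin(th)
        nx, ny = -uy, ux
        p_in = (cx + r * ux, cy + r * uy)
        p_out = (cx + (r + L) * ux, cy + (r + L) * uy)
        verts = [
            (p_in[0] + w / 2 * nx, p_in[1] + w / 2 * ny),
            (p_out[0] + w / 2 * nx, p_out[1] + w / 2 * ny),
            (p_out[0] - w / 2 * nx, p_out[1] - w / 2 * ny),
            (p_in[0] - w / 2 * nx, p_in[1] - w / 2 * ny),
        ]
        regions[name] = Region.from_polygon(name, verts)
    tri = [
        (cx + 2 * r * math.cos(th + math.pi / 3), cy + 2 * r * math.sin(th + math.pi / 3))
        for th in angles
    ]
    regions["center"] = Region.from_polygon("center", tri)
    side = int(math.ceil(2 * (r + L) + 2 * margin_px))
    return MazeGeometry(
        maze_type="YM",
        regions=regions,
        partition=names + ["center"],
        pixel_size=pixel_size,
        image_shape=(side, side),
        transition_region="center",
        meta={
            "arm_length_cm": arm_length_cm,
            "arm_width_cm": arm_width_cm,
            "base_angle_deg": base_angle_deg,
            "center_px": [cx, cy],
            "arms": names,
        },
    )


def make_mwm(
    pool_diameter_cm: float = 125.0,
    platform_center_cm: tuple[float, float] = (-15.6, -15.6),
    platform_diameter_cm: float = 10.0,
    wall_band_cm: float = 10.0,
    pixel_size: float = 0.3,
    pool_center_px: tuple[float, float] | None = None,
    margin_px: float = 10.0,
) -> MazeGeometry:
    """Morris water maze: circular pool, four quadrants, platform disc and
    a 10 cm wall band.

    ``platform_center_cm`` is the platform offset from the pool center in
    cm (default: center of the upper-left quadrant).  Quadrants are
    numbered 1..4 counterclockwise in arena terms starting at upper-right
    in image coordinates; the wall band is the annulus of width
    ``wall_band_cm`` just inside the pool wall.
    """
    if min(pool_diameter_cm, platform_diameter_cm, pixel_size) <= 0:
        raise ValueError("all maze dimensions must be > 0")
    R = pool_diameter_cm / 2 / pixel_size
    if not 0 < wall_band_cm / pixel_size < R:
        raise ValueError("wall band must be thinner than the pool radius")
    if pool_center_px is None:
        pool_center_px = (R + margin_px, R + margin_px)
    cx, cy = pool_center_px
    rp = platform_diameter_cm / 2 / pixel_size
    px = cx + platform_center_cm[0] / pixel_size
    py = cy + platform_center_cm[1] / pixel_size
    if math.hypot(px - cx, py - cy) + rp > R:
        raise ValueError("platform must lie entirely inside the pool")
    big = R + 10
    quads = {
        "quadrant_1": (cx, cy - big, cx + big, cy),  # upper-right
        "quadrant_2": (cx - big, cy - big, cx, cy),  # upper-left
        "quadrant_3": (cx - big, cy, cx, cy + big),  # lower-left
        "quadrant_4": (cx, cy, cx + big, cy + big),  # lower-right
    }
    regions = {
        name: Region.from_circle_box(name, (cx, cy), R, bbox)
        for name, bbox in quads.items()
    }
    regions["platform"] = Region.from_circle("platform", (px, py), rp)
    band = wall_band_cm / pixel_size
    regions["wall_band"] = Region.from_annulus("wall_band", (cx, cy), R - band, R)
    H = W = int(math.ceil(2 * R + 2 * margin_px))
    return MazeGeometry(
        maze_type="MWM",
        regions=regions,
        partition=list(quads),
        pixel_size=pixel_size,
        image_shape=(H, W),
        transition_region=None,
        meta={
            "pool_diameter_cm": pool_diameter_cm,
            "platform_center_cm": list(platform_center_cm),
            "platform_diameter_cm": platform_diameter_cm,
            "wall_band_cm": wall_band_cm,
            "pool_center_px": [cx, cy],
            "pool_radius_px": R,
        },
    )
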