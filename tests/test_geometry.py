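import numpy as np
import pytest
import shapely
from shapely import affinity

from mazetrack.detect import BlobDetection
from mazetrack.geometry import (
    MazeGeometry,
    Region,
    assign_point,
    center_of_mass_in,
    centroid_occupancy_series,
    make_epm,
    make_mwm,
    make_open_field,
    make_ymaze,
    occupancy_fraction,
    partition_fractions,
)


def _blob_from_mask(mask):
    from mazetrack.detect import _make_blob

    return _make_blob(0, mask)


class TestOpenField:
    def test_grid_cell_and_center_block_sides(self):
        g = make_open_field(field_cm=38.0, grid_n=5, center_n=3)
        assert g.meta["cell_side_cm"] == pytest.approx(7.6)
        assert g.meta["center_side_cm"] == pytest.approx(22.8)

    def test_center_and_outer_partition_the_arena(self):
        g = make_open_field(pixel_size=0.1)
        field_px2 = (38.0 / 0.1) ** 2
        total = g.region("center").geom.area + g.region("outer").geom.area
        assert total == pytest.approx(field_px2, rel=1e-9)

    def test_center_block_is_centered_fraction_of_field(self):
        g = make_open_field()
        assert g.region("center").geom.area / (
            g.region("center").geom.area + g.region("outer").geom.area
        ) == pytest.approx((3 / 5) ** 2)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            make_open_field(grid_n=5, center_n=5)


class TestEpm:
    def test_open_arm_rectangle_dimensions_in_px(self):
        g = make_epm(arm_length_cm=25, arm_width_cm=7, center_side_cm=8,
                     pixel_size=0.1)
        minx, miny, maxx, maxy = g.region("open_arm_1").geom.bounds
        assert (maxx - minx, maxy - miny) == pytest.approx((250.0, 70.0))

    def test_arms_and_center_tile_without_overlap(self):
        g = make_epm()
        parts = [g.region(n).geom for n in g.partition]
        union_area = shapely.union_all(parts).area
        assert union_area == pytest.approx(sum(p.area for p in parts), rel=1e-9)

    def test_edge_zones_do_not_intersect_arm_interiors(self):
        g = make_epm()
        for zn in g.edge_zones:
            zone = g.region(zn).geom
            for arm in g.partition:
                assert zone.intersection(g.region(arm).geom).area < 1e-9


class TestYmaze:
    def test_arm_axes_pairwise_120_degrees(self):
        g = make_ymaze()
        c = np.array(g.meta["center_px"])
        dirs = []
        for arm in g.meta["arms"]:
            centroid = np.array(g.region(arm).geom.centroid.coords[0])
            v = centroid - c
            dirs.append(np.arctan2(v[1], v[0]))
        for i in range(3):
            d = np.degrees((dirs[(i + 1) % 3] - dirs[i]) % (2 * np.pi))
            assert d == pytest.approx(120.0, abs=1e-9)

    def test_rotating_by_120_maps_arm_set_onto_itself(self):
        g = make_ymaze()
        c = g.meta["center_px"]
        arms = [g.region(a).geom for a in g.meta["arms"]]
        for i, arm in enumerate(arms):
            rotated = affinity.rotate(arm, 120, origin=tuple(c))
            target = arms[(i + 1) % 3]
            mismatch = rotated.symmetric_difference(target).area
            assert mismatch / target.area < 1e-9

    def test_arm_area_is_length_times_width(self):
        g = make_ymaze(arm_length_cm=35, arm_width_cm=7, pixel_size=0.25)
        expected = (35 / 0.25) * (7 / 0.25)
        for arm in g.meta["arms"]:
            assert g.region(arm).geom.area == pytest.approx(expected, rel=0.01)


class TestMwm:
    def test_quadrants_have_equal_area(self):
        g = make_mwm()
        areas = [g.region(q).geom.area for q in g.partition]
        assert max(areas) / min(areas) < 1.01

    def test_wall_band_area_matches_closed_form_annulus_ratio(self):
        g = make_mwm(pool_diameter_cm=125, wall_band_cm=10)
        pool_area = sum(g.region(q).geom.area for q in g.partition)
        ratio = g.region("wall_band").geom.area / pool_area
        R = 62.5
        assert ratio == pytest.approx(1 - ((R - 10) / R) ** 2, rel=0.01)

    def test_pool_center_assigned_to_exactly_one_quadrant(self):
        g = make_mwm()
        c = g.meta["pool_center_px"]
        hits = [q for q in g.partition if g.region(q).covers_point(c)]
        assert len(hits) >= 1
        assert assign_point(c, g) == g.partition[0]
        assert not g.region("wall_band").covers_point(c)

    def test_platform_must_fit_inside_pool(self):
        with pytest.raises(ValueError):
            make_mwm(platform_center_cm=(60.0, 0.0))


class TestOccupancy:
    def _square_blob(self, x0, y0, side=10):
        mask = np.zeros((120, 120), bool)
        mask[y0 : y0 + side, x0 : x0 + side] = True
        return _blob_from_mask(mask)

    def test_blob_entirely_inside_region_scores_one(self):
        region = Region.from_polygon("r", [(0, 0), (100, 0), (100, 100), (0, 100)])
        assert occupancy_fraction(self._square_blob(30, 30), region) == 1.0

    def test_blob_entirely_outside_region_scores_zero(self):
        region = Region.from_polygon("r", [(0, 0), (20, 0), (20, 20), (0, 20)])
        assert occupancy_fraction(self._square_blob(60, 60), region) == 0.0

    def test_bisected_blob_scores_about_half(self):
        # oracle: a straight boundary through the blob middle classifies
        # half the perimeter points
        region = Region.from_polygon("r", [(0, 0), (55.5, 0), (55.5, 120), (0, 120)])
        blob = self._square_blob(46, 40, side=20)  # spans x 46..65
        assert occupancy_fraction(blob, region) == pytest.approx(0.5, abs=0.05)

    def test_partition_fractions_sum_to_one(self):
        g = make_open_field()
        rng = np.random.default_rng(3)
        for _ in range(5):
            x0, y0 = rng.integers(60, 120, 2)
            blob = self._square_blob(int(x0), int(y0))
            fr = partition_fractions(blob.perimeter_points, g)
            assert fr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_occupancy_invariant_under_joint_translation(self):
        region = Region.from_polygon("r", [(40, 40), (70, 40), (70, 70), (40, 70)])
        shifted = Region.from_polygon("r", [(60, 55), (90, 55), (90, 85), (60, 85)])
        blob = self._square_blob(35, 35)
        blob2 = self._square_blob(55, 50)
        assert occupancy_fraction(blob, region) == pytest.approx(
            occupancy_fraction(blob2, shifted)
        )

    def test_center_of_mass_rule(self):
        region = Region.from_circle("r", (50, 50), 10)
        inside = BlobDetection(0, None, 10, (50.0, 50.0), np.empty((0, 2)))
        outside = BlobDetection(0, None, 10, (80.0, 80.0), np.empty((0, 2)))
        assert center_of_mass_in(inside, region)
        assert not center_of_mass_in(outside, region)

    def test_centroid_series_is_one_hot_over_partition(self):
        g = make_mwm()
        c = np.array(g.meta["pool_center_px"])
        pts = c + np.array([[30, -20], [-40, -5], [-10, 55], [25, 35], [0, 0]])
        occ = centroid_occupancy_series(pts, g)
        np.testing.assert_array_equal(occ.sum(axis=1), np.ones(len(pts)))


def test_geometry_json_round_trip(tmp_path):
    for g in (make_open_field(), make_epm(), make_ymaze(), make_mwm()):
        p = g.save(tmp_path / f"{g.maze_type}.json")
        h = MazeGeometry.load(p)
        assert h.maze_type == g.maze_type
        assert h.partition == g.partition
        assert h.pixel_size == g.pixel_size
        assert tuple(h.image_shape) == tuple(g.image_shape)
        for name, region in g.regions.items():
            assert h.region(name).geom.equals_exact(region.geom, 1e-9)
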