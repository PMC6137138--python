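import numpy as np
import pandas as pd
import pytest

from mazetrack.errors import ConfigError
from mazetrack.geometry import make_open_field
from mazetrack.report_viz import (
    framewise_dataframe,
    load_parameters,
    make_heat_map,
    make_trajectory_map,
    save_parameters,
    write_framewise_table,
    write_summary,
)
from mazetrack.scoring import NOT_FOUND_SENTINEL, TestResult
from mazetrack.track import TrackingConfig, Trajectory, apply_movement_threshold


def _traj(pos, fps=25.0, pixel_size=0.2, detected=None):
    pos = np.asarray(pos, float)
    T = len(pos)
    det = np.ones(T, bool) if detected is None else np.asarray(detected)
    dd = np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1]))
    imputed = ~(det[:-1] & det[1:])
    dd = np.where(imputed, 0.0, dd)
    t = Trajectory(
        x_px=pos[:, 0], y_px=pos[:, 1], detected=det, fps=fps,
        pixel_size=pixel_size, movement_threshold_px=1.0,
        dd_px_raw=dd, dd_px=dd.copy(), stationary=np.zeros(T - 1, bool),
        imputed=imputed,
    )
    return apply_movement_threshold(t, TrackingConfig())


class TestFramewiseTable:
    def test_one_row_per_frame(self, tmp_path):
        traj = _traj([(10 + 3 * i, 20.0) for i in range(57)])
        path = write_framewise_table(traj, None, None, None, tmp_path / "f.csv")
        df = pd.read_csv(path)
        assert len(df) == 57

    def test_total_distance_rederivable_from_csv_exactly(self, tmp_path):
        rng = np.random.default_rng(6)
        pos = np.cumsum(rng.uniform(-3, 3, (200, 2)), axis=0) + 100
        traj = _traj(pos)
        path = write_framewise_table(traj, None, None, None, tmp_path / "f.csv")
        df = pd.read_csv(path)
        # round-trip oracle: the same sum over the parsed column
        assert float(np.sum(df["dd_cm"].to_numpy()[1:])) == traj.total_distance_cm

    def test_stationary_video_has_all_zero_speeds(self, tmp_path):
        traj = _traj([(50.0, 50.0)] * 30)
        path = write_framewise_table(traj, None, None, None, tmp_path / "f.csv")
        df = pd.read_csv(path)
        assert (df["speed_cms"] == 0).all()

    def test_occupancy_and_labels_columns_present(self):
        traj = _traj([(10.0, 10.0)] * 5)
        occ = np.zeros((5, 2))
        labels = np.array(["outer"] * 5, dtype=object)
        df = framewise_dataframe(traj, occ, ["center", "outer"], labels)
        assert "occ_center" in df.columns and df["region"].iloc[0] == "outer"


class TestSummary:
    def _result(self):
        res = TestResult("OF")
        for name, unit in [
            ("distance_total_cm", "cm"), ("distance_center_cm", "cm"),
            ("distance_outer_cm", "cm"), ("time_center_s", "s"),
            ("time_outer_s", "s"), ("entries_center", "count"),
            ("freezing_total_s", "s"), ("freezing_center_s", "s"),
            ("freezing_outer_s", "s"), ("speed_avg_cms", "cm/s"),
        ]:
            res.add(name, 1.2345678901234567, unit)
        return res

    def test_open_field_summary_covers_the_standard_metric_set(self, tmp_path):
        path = write_summary(self._result(), tmp_path / "s.csv")
        df = pd.read_csv(path)
        names = set(df["metric"])
        # the distance/time/entries/freezing/speed families of the test
        for needed in ["distance_center_cm", "time_center_s", "time_outer_s",
                       "entries_center", "freezing_center_s", "speed_avg_cms"]:
            assert needed in names

    def test_sentinel_text_passes_through_verbatim(self, tmp_path):
        res = TestResult("MWM")
        res.add("latency_platform_s", NOT_FOUND_SENTINEL, "s")
        path = write_summary(res, tmp_path / "s.csv")
        assert NOT_FOUND_SENTINEL in path.read_text()

    def test_values_round_trip_bit_exactly(self, tmp_path):
        res = self._result()
        path = write_summary(res, tmp_path / "s.csv")
        df = pd.read_csv(path)
        val = float(df.loc[df["metric"] == "speed_avg_cms", "value"].iloc[0])
        assert val == res.metrics["speed_avg_cms"]


class TestParameters:
    def _params(self):
        return {
            "version": "0.1.0", "input": "v.tif", "maze_type": "OF",
            "geometry": make_open_field().to_dict(),
            "detection": {"min_area_px2": 50},
            "tracking": {"movement_threshold_px": 1.0},
            "rules": {"mode": "fraction", "entry_fraction": 0.7},
            "preprocess": {"blur_radius_px": 0.0, "background_method": "mean"},
            "output_stem": "out/run1",
        }

    def test_round_trip(self, tmp_path):
        p = save_parameters(self._params(), tmp_path / "p.yaml")
        loaded = load_parameters(p)
        assert loaded["maze_type"] == "OF"
        assert loaded["rules"]["entry_fraction"] == 0.7

    def test_missing_key_is_named_in_the_error(self, tmp_path):
        params = self._params()
        del params["tracking"]
        p = tmp_path / "p.yaml"
        import yaml

        p.write_text(yaml.safe_dump(params))
        with pytest.raises(ConfigError, match="tracking"):
            load_parameters(p)


class TestRoiExports:
    def test_mask_stack_and_perimeter_csv_round_trip(self, tmp_path):
        import tifffile

        from mazetrack.detect import DetectionConfig, segment_frame
        from mazetrack.report_viz import write_mask_stack, write_perimeters_csv

        frame = np.zeros((30, 30))
        frame[10:16, 12:18] = 200
        (blob,) = segment_frame(frame, 50, DetectionConfig(min_area_px2=4))
        mask_path = write_mask_stack([blob, None], (30, 30), tmp_path / "m.tif")
        arr = tifffile.imread(mask_path)
        assert arr.shape == (2, 30, 30)
        np.testing.assert_array_equal(arr[0] > 0, blob.mask)
        assert arr[1].max() == 0
        csv_path = write_perimeters_csv([blob, None], tmp_path / "p.csv")
        df = pd.read_csv(csv_path)
        assert set(df.columns) == {"frame", "point_index", "x", "y"}
        assert len(df) == len(blob.perimeter_points)


class TestHeatMap:
    geometry = make_open_field()

    def test_stationary_track_fills_a_single_bin(self):
        traj = _traj([(55.0, 83.0)] * 40)
        hm = make_heat_map(traj, self.geometry)
        assert hm.total == 40
        assert (hm.bins > 0).sum() == 1

    def test_mass_equals_detected_frame_count(self):
        rng = np.random.default_rng(12)
        pos = rng.uniform(30, 170, (300, 2))
        det = rng.random(300) > 0.1
        traj = _traj(pos, detected=det)
        hm = make_heat_map(traj, self.geometry)
        assert hm.total == int(det.sum())

    def test_uniform_raster_scan_is_roughly_flat(self):
        # scan pattern visits each 40 px bin the same number of times
        xs = np.arange(20, 200, 40, dtype=float)
        ys = np.arange(20, 200, 40, dtype=float)
        pos = [(x, y) for y in ys for x in xs] * 3
        hm = make_heat_map(_traj(pos), self.geometry, bin_size_px=40.0)
        nonzero = hm.bins[hm.bins > 0]
        assert nonzero.max() / nonzero.min() <= 2

    def test_non_positive_bin_size_rejected(self):
        with pytest.raises(ValueError):
            make_heat_map(_traj([(50.0, 50.0)] * 3), self.geometry, bin_size_px=0)


class TestTrajectoryMap:
    geometry = make_open_field()

    def test_polyline_equals_centroid_list(self, tmp_path):
        pos = [(30.0, 30.0), (30.0, 120.0), (150.0, 120.0)]  # L-shaped
        tm = make_trajectory_map(_traj(pos), self.geometry, tmp_path / "t.png")
        np.testing.assert_array_equal(tm.polyline, np.asarray(pos))

    def test_image_dimensions_equal_frame_dimensions(self, tmp_path):
        from PIL import Image

        tm = make_trajectory_map(
            _traj([(30.0, 30.0), (60.0, 60.0)]), self.geometry, tmp_path / "t.png"
        )
        with Image.open(tmp_path / "t.png") as im:
            assert im.size == tm.image_size
        H, W = self.geometry.image_shape
        assert tm.image_size == (W, H)

    def test_gap_segments_follow_dropouts(self):
        det = [True, True, False, True]
        tm = make_trajectory_map(
            _traj([(30.0, 30.0)] * 4, detected=det), self.geometry
        )
        assert tm.gap_segments == [(1, 2), (2, 3)]
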