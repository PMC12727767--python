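import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from loomsync.trajectory_io import (
    CalibrationSpec,
    N_FRAMES,
    TrackingParseError,
    TrackingTable,
    build_velocity_matrix,
    calibrate,
    compute_speed,
    read_tracking,
    smooth_speed,
)
from loomsync.synthetic import write_fixture


def _table(coords: dict[int, np.ndarray], units="cm", **kw) -> TrackingTable:
    n = len(next(iter(coords.values())))
    data = {"frame": np.arange(n)}
    for i, xy in coords.items():
        data[f"id{i}_x"] = xy[:, 0]
        data[f"id{i}_y"] = xy[:, 1]
    return TrackingTable(data=pd.DataFrame(data), units=units, **kw)


def _straight_path(step_x, step_y=0.0, n=N_FRAMES):
    xy = np.zeros((n, 2))
    xy[:, 0] = np.arange(n) * step_x
    xy[:, 1] = np.arange(n) * step_y
    return xy


class TestCalibration:
    def test_linear_scaling(self):
        cal = CalibrationSpec.from_span(400, 20.0)
        assert cal.pixels_per_cm == 20.0
        t = _table({0: _straight_path(0.0) + [40.0, 20.0]}, units="px")
        out = calibrate(t, cal)
        assert out.units == "cm"
        assert out.data["id0_x"].iloc[0] == pytest.approx(2.0)
        assert out.data["id0_y"].iloc[0] == pytest.approx(1.0)

    def test_cm_input_is_noop_with_warning(self):
        t = _table({0: _straight_path(0.1)})
        with pytest.warns(UserWarning, match="no-op"):
            out = calibrate(t, CalibrationSpec(20.0))
        pd.testing.assert_frame_equal(out.data, t.data)

    @pytest.mark.parametrize("ppc", [0.0, -3.0])
    def test_nonpositive_pixels_per_cm_rejected(self, ppc):
        with pytest.raises(Exception, match="positive"):
            CalibrationSpec(ppc)


class TestSpeed:
    @pytest.mark.parametrize(
        "step, expected",
        [((0.2, 0.0), 1.0), ((0.0, 0.0), 0.0), ((0.9, 1.2), 7.5)],
    )
    def test_displacement_times_fps(self, step, expected):
        t = _table({0: _straight_path(*step)})
        v = compute_speed(t)
        assert v.shape == (1, N_FRAMES)
        assert np.allclose(v, expected)

    def test_first_frame_duplicates_frame_one(self):
        xy = _straight_path(0.0)
        xy[1:] += [0.3, 0.4]  # single 0.5 cm jump between frames 0 and 1
        v = compute_speed(_table({0: xy}))
        assert v[0, 0] == v[0, 1] == pytest.approx(2.5)

    def test_pixel_units_rejected(self):
        t = _table({0: _straight_path(1.0)}, units="px")
        with pytest.raises(ValueError, match="calibrate first"):
            compute_speed(t)

    @pytest.mark.parametrize("angle", [0.3, 1.2, 2.9])
    def test_rigid_motion_invariance(self, angle, rng):
        xy = rng.normal(size=(N_FRAMES, 2)).cumsum(axis=0)
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = xy @ rot.T + [5.0, -3.0]
        v1 = compute_speed(_table({0: xy}))
        v2 = compute_speed(_table({0: moved}))
        assert np.allclose(v1, v2)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        assert np.allclose(smooth_speed(np.full(20, 3.3)), 3.3)

    def test_trailing_window_mean(self):
        out = smooth_speed(np.array([0.0, 0, 0, 0, 5]), window=5)
        assert out[-1] == pytest.approx(1.0)
        # partial leading windows: mean over the frames available so far
        assert np.allclose(out[:4], 0.0)

    def test_window_one_is_identity(self, rng):
        x = rng.random(30)
        assert np.allclose(smooth_speed(x, window=1), x)

    def test_window_below_one_rejected(self):
        with pytest.raises(ValueError, match="window"):
            smooth_speed(np.ones(5), window=0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=1, max_size=60), st.integers(1, 10))
    def test_smoothing_stays_within_data_range(self, values, window):
        x = np.array(values)
        out = smooth_speed(x, window=window)
        assert out.min() >= x.min() - 1e-9 and out.max() <= x.max() + 1e-9


class TestReadTracking:
    def test_roundtrip_through_fixture(self, small_experiment, tmp_path):
        _, tables, truth = small_experiment
        manifest = write_fixture(tables, tmp_path, truth=truth, seed=11)
        back = read_tracking(tmp_path / "g000_t00.csv", manifest)
        orig = tables[0]
        assert back.group_id == orig.group_id and back.trial_id == orig.trial_id
        assert np.array_equal(back.data.to_numpy(), orig.data.to_numpy())

    def test_frame_gap_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"frame": list(range(100)) + list(range(101, 151)),
             "id0_x": 1.0, "id0_y": 1.0}
        )
        p = tmp_path / "gap.csv"
        df.to_csv(p, index=False)
        with pytest.raises(TrackingParseError, match="frame gap"):
            read_tracking(p)

    def test_too_few_frames_rejected(self, tmp_path):
        df = pd.DataFrame({"frame": range(149), "id0_x": 1.0, "id0_y": 1.0})
        p = tmp_path / "short.csv"
        df.to_csv(p, index=False)
        with pytest.raises(TrackingParseError, match="insufficient frames"):
            read_tracking(p)

    def test_nan_coordinate_rejected(self, tmp_path):
        df = pd.DataFrame({"frame": range(150), "id0_x": 1.0, "id0_y": 1.0})
        df.loc[7, "id0_y"] = np.nan
        p = tmp_path / "nan.csv"
        df.to_csv(p, index=False)
        with pytest.raises(TrackingParseError, match="id0_y.*row 7"):
            read_tracking(p)


class TestVelocityMatrix:
    def test_single_group_trial_shape(self, small_experiment):
        _, tables, _ = small_experiment
        vm = build_velocity_matrix(tables[:1])
        assert vm.shape == (6, N_FRAMES)

    def test_row_count_is_design_product(self, small_vm):
        # 3 groups x 4 trials x 6 individuals
        assert small_vm.shape == (3 * 4 * 6, N_FRAMES)

    def test_rows_ordered_by_group_trial_individual(self, small_vm):
        idx = small_vm.data.index
        assert list(idx) == sorted(idx)

    def test_heterogeneous_individual_counts_rejected(self, small_experiment):
        _, tables, _ = small_experiment
        bad = tables[1].data.drop(columns=["id5_x", "id5_y"])
        from loomsync.trajectory_io import TrackingTable

        t_bad = TrackingTable(data=bad, units="cm", group_id=tables[1].group_id,
                              trial_id=tables[1].trial_id)
        with pytest.raises(ValueError, match="heterogeneous"):
            build_velocity_matrix([tables[0], t_bad])

    def test_pixel_tables_need_calibration(self, small_experiment, tmp_path):
        _, tables, _ = small_experiment
        write_fixture(tables[:2], tmp_path, pixels_per_cm=20.0)
        back = [read_tracking(p) for p in sorted(tmp_path.glob("*.csv"))]
        assert back[0].units == "px"
        with pytest.raises(Exception, match="Calibration|pixels"):
            build_velocity_matrix(back)
        vm_px = build_velocity_matrix(back, cal=CalibrationSpec(20.0))
        vm_cm = build_velocity_matrix(tables[:2])
        assert np.allclose(vm_px.data.to_numpy(), vm_cm.data.to_numpy())
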