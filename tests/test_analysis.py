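import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from spherocam import (
    SpheroidRecord,
    estimate_dcell,
    group_mean_rrm,
    invasion_velocity,
    ks_compare,
    mean_rrm,
    population_dcell,
    read_tracks,
    split_by_size,
    write_tracks,
)
from spherocam.analysis import RRMSeries

from conftest import ks_statistic_oracle, make_track_table


class TestMeanRRM:
    def test_static_tracks_give_exactly_one(self, rng):
        pos = {
            k: [(x, y)] * 5
            for k, (x, y) in enumerate(rng.uniform(-50, 50, size=(10, 2)))
        }
        tab = make_track_table(pos, times_s=np.arange(5) * 600.0)
        rrm = mean_rrm(tab, (0.0, 0.0))
        assert np.all(rrm.values == 1.0)

    def test_doubled_radial_distances_give_two(self, rng):
        start = rng.uniform(-40, 40, size=(8, 2))
        pos = {k: [(x, y), (2 * x, 2 * y)] for k, (x, y) in enumerate(start)}
        tab = make_track_table(pos, times_s=[0.0, 600.0])
        rrm = mean_rrm(tab, (0.0, 0.0))
        assert rrm.values[0] == 1.0
        assert rrm.values[1] == pytest.approx(2.0)

    def test_mean_over_cells_not_distances(self):
        # radii (10, 30) then (20, 20): both time points average to 20 um
        pos = {0: [(10, 0), (20, 0)], 1: [(30, 0), (20, 0)]}
        tab = make_track_table(pos, times_s=[0.0, 600.0])
        rrm = mean_rrm(tab, (0.0, 0.0))
        assert rrm.values[1] == pytest.approx(1.0)

    def test_cells_lost_later_are_dropped_from_the_mean(self):
        tab = pd.DataFrame(
            {
                "track_id": [0, 0, 1],
                "time_s": [0.0, 600.0, 0.0],
                "x_um": [10.0, 10.0, 30.0],
                "y_um": [0.0, 0.0, 0.0],
            }
        )
        rrm = mean_rrm(tab, (0.0, 0.0))
        # t0 mean is 20; at t1 only the r=10 cell remains
        assert rrm.values[1] == pytest.approx(0.5)

    def test_zero_denominator_rejected(self):
        tab = make_track_table({0: [(0, 0), (5, 5)]}, times_s=[0.0, 600.0])
        with pytest.raises(ValueError, match="centroid"):
            mean_rrm(tab, (0.0, 0.0))

    def test_empty_table_rejected(self):
        empty = pd.DataFrame(columns=["track_id", "time_s", "x_um", "y_um"])
        with pytest.raises(ValueError):
            mean_rrm(empty, (0.0, 0.0))

    @given(
        dx=st.floats(-500, 500),
        dy=st.floats(-500, 500),
        theta=st.floats(0, 2 * np.pi),
    )
    def test_invariant_under_translation_and_rotation(self, dx, dy, theta):
        rng = np.random.default_rng(99)
        start = rng.uniform(-30, 30, size=(6, 2)) + [40, -20]
        moved = start * 1.7
        pos = {k: [tuple(start[k]), tuple(moved[k])] for k in range(6)}
        tab = make_track_table(pos, times_s=[0.0, 600.0])
        base = mean_rrm(tab, (0.0, 0.0)).values

        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        tab2 = tab.copy()
        xy = tab2[["x_um", "y_um"]].to_numpy() @ rot.T + [dx, dy]
        tab2[["x_um", "y_um"]] = xy
        got = mean_rrm(tab2, (dx, dy)).values
        np.testing.assert_allclose(got, base, rtol=1e-9)

    def test_first_value_exactly_one(self, rng):
        pos = {
            k: list(map(tuple, rng.uniform(-50, 50, size=(4, 2))))
            for k in range(7)
        }
        tab = make_track_table(pos, times_s=np.arange(4) * 600.0)
        assert mean_rrm(tab, (3.0, -2.0)).values[0] == 1.0


class TestDiffusionEstimators:
    def test_stationary_track_is_zero(self):
        tab = make_track_table({0: [(5, 5)] * 4}, times_s=np.arange(4) * 600.0)
        assert estimate_dcell(tab) == 0.0

    def test_single_step_closed_form(self):
        tab = make_track_table({0: [(0, 0), (10, 0)]}, times_s=[0.0, 420.0])
        assert estimate_dcell(tab) == pytest.approx(100 / (4 * 420))

    def test_explicit_duration_argument(self):
        tab = make_track_table({0: [(0, 0), (10, 0)]}, times_s=[0.0, 420.0])
        assert estimate_dcell(tab, T_s=840.0) == pytest.approx(100 / (4 * 840))

    def test_single_point_rejected(self):
        tab = make_track_table({0: [(0, 0)]}, times_s=[0.0])
        with pytest.raises(ValueError):
            estimate_dcell(tab)

    def test_rigid_motion_invariance_and_scaling(self, rng):
        steps = rng.normal(0, 3, size=(20, 2))
        xy = np.cumsum(steps, axis=0)
        times = np.arange(20) * 600.0
        tab = make_track_table({0: list(map(tuple, xy))}, times_s=times)
        base = estimate_dcell(tab)

        theta = 0.73
        c, s = np.cos(theta), np.sin(theta)
        xy_rot = xy @ np.array([[c, -s], [s, c]]).T + [100, -50]
        tab_rot = make_track_table({0: list(map(tuple, xy_rot))}, times_s=times)
        assert estimate_dcell(tab_rot) == pytest.approx(base)

        tab_scaled = make_track_table({0: list(map(tuple, 3 * xy))}, times_s=times)
        assert estimate_dcell(tab_scaled) == pytest.approx(9 * base)
        tab_slow = make_track_table({0: list(map(tuple, xy))}, times_s=2 * times)
        assert estimate_dcell(tab_slow) == pytest.approx(base / 2)

    def test_population_mean_and_sem(self):
        # two tracks engineered to give estimates 0.1 and 0.3 um^2/s
        def track_with(dc, tid):
            step = np.sqrt(dc * 4 * 600)
            return {tid: [(0, 0), (step, 0)]}

        tab = pd.concat(
            [
                make_track_table(track_with(0.1, 0), times_s=[0.0, 600.0]),
                make_track_table(track_with(0.3, 1), times_s=[0.0, 600.0]),
            ]
        )
        mean, sem = population_dcell(tab)
        assert mean == pytest.approx(0.2)
        assert sem == pytest.approx(0.1)

    def test_identical_tracks_have_zero_sem(self):
        one = [(0, 0), (4, 3), (8, 0)]
        tab = make_track_table({0: one, 1: one}, times_s=[0.0, 600.0, 1200.0])
        _, sem = population_dcell(tab)
        assert sem == 0.0

    def test_single_track_population_rejected(self):
        tab = make_track_table({0: [(0, 0), (1, 1)]}, times_s=[0.0, 600.0])
        with pytest.raises(ValueError):
            population_dcell(tab)


class TestInvasionVelocity:
    def test_constant_series_zero_slope(self):
        rrm = RRMSeries(np.linspace(0, 24, 20), np.ones(20))
        assert invasion_velocity(rrm) == pytest.approx(0.0)

    def test_linear_series_recovers_slope(self):
        t = np.linspace(0, 24, 30)
        rrm = RRMSeries(t, 1 + 0.2 * t)
        assert invasion_velocity(rrm) == pytest.approx(0.2)

    def test_window_excludes_late_plateau(self):
        t = np.linspace(0, 24, 49)
        v = np.where(t <= 7.5, 1 + 0.3 * t, 1 + 0.3 * 7.5)
        rrm = RRMSeries(t, v)
        assert invasion_velocity(rrm, window_h=7.5) == pytest.approx(0.3)
        assert invasion_velocity(rrm, window_h=24.0) < 0.3

    def test_insufficient_points_rejected(self):
        rrm = RRMSeries(np.array([0.0, 10.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            invasion_velocity(rrm, window_h=5.0)


class TestSizeSplitAndGroups:
    def _record(self, diam):
        tab = make_track_table({0: [(30, 0), (31, 0)]}, times_s=[0.0, 600.0])
        return SpheroidRecord(
            id=f"s{diam}", diameter_um=diam, centroid_um=(0.0, 0.0), tracks=tab
        )

    def test_threshold_partition(self):
        records = [self._record(d) for d in (60, 90, 120, 160)]
        small, large = split_by_size(records)
        assert [r.diameter_um for r in small] == [60, 90]
        assert [r.diameter_um for r in large] == [120, 160]

    def test_exactly_threshold_is_large(self):
        small, large = split_by_size([self._record(100)])
        assert not small and len(large) == 1

    def test_all_small_leaves_large_empty(self):
        small, large = split_by_size([self._record(d) for d in (50, 70)])
        assert len(small) == 2 and large == []

    def test_group_mean_rrm_pointwise(self):
        t = np.array([0.0, 1.0])
        a = RRMSeries(t, np.array([1.0, 2.0]))
        b = RRMSeries(t, np.array([1.0, 4.0]))
        avg = group_mean_rrm([a, b])
        np.testing.assert_allclose(avg.values, [1.0, 3.0])
        with pytest.raises(ValueError):
            group_mean_rrm([a, RRMSeries(np.array([0.0, 2.0]), np.array([1.0, 2.0]))])


class TestKSCompare:
    def test_identical_samples(self):
        stat, p = ks_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        stat, _ = ks_compare([1, 2, 3, 4], [5, 6, 7, 8])
        assert stat == 1.0

    def test_small_sample_enumeration(self):
        stat, _ = ks_compare([1, 2], [1, 3])
        assert stat == pytest.approx(0.5)

    def test_matches_ecdf_oracle(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1.3, 60)
        stat, _ = ks_compare(a, b)
        assert stat == pytest.approx(ks_statistic_oracle(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


class TestTrackIO:
    def test_round_trip_identity(self, tmp_path, rng):
        pos = {
            k: list(map(tuple, rng.uniform(0, 100, size=(5, 2))))
            for k in range(4)
        }
        tab = make_track_table(pos, times_s=np.arange(5) * 600.0)
        path = tmp_path / "tracks.csv"
        write_tracks(tab, path)
        back = read_tracks(path)
        pd.testing.assert_frame_equal(
            back.sort_values(["track_id", "time_s"], ignore_index=True),
            tab.sort_values(["track_id", "time_s"], ignore_index=True),
            check_dtype=False,
        )

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"TRACK_ID": [0], "POSITION_X": [1.0], "FRAME": [0]}).to_csv(
            path, index=False
        )
        with pytest.raises(ValueError, match="POSITION_Y"):
            read_tracks(path)

    def test_frame_converted_by_interval(self, tmp_path):
        path = tmp_path / "frames.csv"
        pd.DataFrame(
            {
                "TRACK_ID": [0, 0, 0],
                "FRAME": [0, 1, 2],
                "POSITION_X": [1.0, 2.0, 3.0],
                "POSITION_Y": [0.0, 0.0, 0.0],
            }
        ).to_csv(path, index=False)
        tab = read_tracks(path, interval_s=600.0)
        np.testing.assert_allclose(tab["time_s"], [0.0, 600.0, 1200.0])

    def test_trackmate_header_padding_rows_dropped(self, tmp_path):
        path = tmp_path / "tm.csv"
        path.write_text(
            "TRACK_ID,FRAME,POSITION_X,POSITION_Y\n"
            "Track ID,Frame,X,Y\n"  # label row as in TrackMate v7 exports
            "0,0,1.5,2.5\n"
            "0,1,1.6,2.4\n"
        )
        tab = read_tracks(path)
        assert len(tab) == 2
        assert tab["x_um"].iloc[0] == 1.5

    def test_non_monotone_track_times_rejected(self):
        tab = pd.DataFrame(
            {
                "track_id": [0, 0],
                "time_s": [600.0, 0.0],
                "x_um": [0.0, 1.0],
                "y_um": [0.0, 1.0],
            }
        )
        # sorting fixes ordering, duplicates do not
        dup = pd.DataFrame(
            {
                "track_id": [0, 0],
                "time_s": [0.0, 0.0],
                "x_um": [0.0, 1.0],
                "y_um": [0.0, 1.0],
            }
        )
        with pytest.raises(ValueError, match="increasing"):
            mean_rrm(dup, (10.0, 10.0))
        assert mean_rrm(tab, (10.0, 10.0)) is not None
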