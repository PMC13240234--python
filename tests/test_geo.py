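"""Projection, cleaning, segmentation and step-series construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gibbonwalk import geo
from gibbonwalk.geo import FeedingPeriod


def snyder_utm(lon, lat, zone):
    """Independent transverse-Mercator oracle (USGS/Snyder series, WGS84)."""
    a = 6378137.0
    f = 1 / 298.257223563
    e2 = f * (2 - f)
    ep2 = e2 / (1 - e2)
    k0 = 0.9996
    lam0 = np.radians(6 * zone - 183)
    phi, lam = np.radians(lat), np.radians(lon)
    N = a / np.sqrt(1 - e2 * np.sin(phi) ** 2)
    T = np.tan(phi) ** 2
    C = ep2 * np.cos(phi) ** 2
    A = (lam - lam0) * np.cos(phi)
    M = a * (
        (1 - e2 / 4 - 3 * e2**2 / 64 - 5 * e2**3 / 256) * phi
        - (3 * e2 / 8 + 3 * e2**2 / 32 + 45 * e2**3 / 1024) * np.sin(2 * phi)
        + (15 * e2**2 / 256 + 45 * e2**3 / 1024) * np.sin(4 * phi)
        - (35 * e2**3 / 3072) * np.sin(6 * phi)
    )
    x = (
        k0 * N * (A + (1 - T + C) * A**3 / 6 + (5 - 18 * T + T**2 + 72 * C - 58 * ep2) * A**5 / 120)
        + 500000
    )
    y = k0 * (
        M
        + N
        * np.tan(phi)
        * (A**2 / 2 + (5 - T + 9 * C + 4 * C**2) * A**4 / 24
           + (61 - 58 * T + T**2 + 600 * C - 330 * ep2) * A**6 / 720)
    )
    return x, y


class TestProjection:
    def test_round_trip_below_one_metre(self):
        lon = np.array([108.9, 109.1, 109.25])
        lat = np.array([18.9, 19.1, 19.05])
        x, y = geo.utm_from_lonlat(lon, lat, 49)
        lon2, lat2 = geo.lonlat_from_utm(x, y, 49)
        # 1e-5 degrees is about 1 m; round-trip should be far tighter
        assert np.max(np.abs(lon2 - lon)) < 1e-8
        assert np.max(np.abs(lat2 - lat)) < 1e-8

    def test_study_area_easting_inside_zone_bounds(self):
        x, y = geo.utm_from_lonlat(109.1, 19.1, 49)
        assert 166_000 < x < 834_000
        assert y > 0

    @pytest.mark.parametrize(
        "lon,lat", [(109.1, 19.1), (108.92, 19.05), (109.5, 18.8), (111.0, 19.2)]
    )
    def test_matches_independent_geodesy_series(self, lon, lat):
        xs, ys = snyder_utm(lon, lat, 49)
        xk, yk = geo.utm_from_lonlat(lon, lat, 49)
        assert abs(xs - xk) < 0.5 and abs(ys - yk) < 0.5

    def test_missing_coordinates_rejected(self):
        df = pd.DataFrame(
            {
                "group_id": ["a", "a"],
                "timestamp": pd.to_datetime(["2023-05-01 06:00", "2023-05-01 06:15"]),
                "lon": [109.1, np.nan],
                "lat": [19.1, 19.1],
            }
        )
        with pytest.warns(UserWarning, match="missing coordinates"):
            out = geo.project_to_utm(df, zone=49)
        assert len(out) == 1

    def test_out_of_zone_warns_but_projects(self):
        df = pd.DataFrame(
            {
                "group_id": ["a"],
                "timestamp": pd.to_datetime(["2023-05-01 06:00"]),
                "lon": [120.0],
                "lat": [19.1],
            }
        )
        with pytest.warns(UserWarning, match="outside the nominal width"):
            out = geo.project_to_utm(df, zone=49)
        assert np.isfinite(out["x"]).all()


def _fix_table(coords, t0="2023-05-01 06:00", step_min=15, group="a"):
    times = pd.date_range(t0, periods=len(coords), freq=f"{step_min}min")
    x, y = zip(*coords)
    return pd.DataFrame(
        {"group_id": group, "timestamp": times, "x": list(x), "y": list(y)}
    )


class TestOutlierRemoval:
    def test_teleporting_middle_fix_dropped(self):
        df = _fix_table([(0, 0), (10_000, 0), (50, 0)])
        out = geo.remove_outliers(df, max_step_speed=1000.0)
        assert len(out) == 2
        assert out["x"].tolist() == [0, 50]

    def test_plausible_track_unchanged(self):
        df = _fix_table([(0, 0), (200, 100), (400, 150), (500, 400)])
        out = geo.remove_outliers(df, max_step_speed=1000.0)
        pd.testing.assert_frame_equal(out, df)

    def test_duplicate_timestamp_keeps_first(self):
        df = _fix_table([(0, 0), (100, 0), (110, 0)])
        df.loc[2, "timestamp"] = df.loc[1, "timestamp"]
        out = geo.remove_outliers(df)
        assert len(out) == 2
        assert out["x"].tolist() == [0, 100]

    def test_threshold_scales_with_gap_length(self):
        # 1.8 km in 30 min is within a 1 km-per-15-min cap
        df = _fix_table([(0, 0), (1800, 0)], step_min=30)
        out = geo.remove_outliers(df, max_step_speed=1000.0)
        assert len(out) == 2

    def test_empty_input(self):
        assert geo.remove_outliers(pd.DataFrame()).empty


class TestSegmentation:
    def test_five_fixes_spanning_an_hour_valid(self):
        df = _fix_table([(i * 10, 0) for i in range(5)])  # 60-min span
        segs = geo.segment_trajectory(df)
        assert len(segs) == 1 and segs[0].n_fixes == 5

    def test_four_fixes_spanning_45min_rejected(self):
        df = _fix_table([(i * 10, 0) for i in range(4)])  # 45-min span
        assert geo.segment_trajectory(df) == []

    def test_three_fixes_spanning_two_hours_rejected(self):
        df = _fix_table([(0, 0), (10, 0), (20, 0)], step_min=60)
        # span 120 min but only 3 fixes; also gap 60 > tolerance splits runs
        assert geo.segment_trajectory(df, gap_tolerance_min=60) == []

    def test_gap_above_tolerance_splits(self):
        a = _fix_table([(i * 10, 0) for i in range(5)])
        b = _fix_table([(i * 10, 0) for i in range(5)], t0="2023-05-01 09:00")
        df = pd.concat([a, b], ignore_index=True)
        segs = geo.segment_trajectory(df, gap_tolerance_min=45)
        assert len(segs) == 2
        assert all(s.n_fixes == 5 for s in segs)

    def test_segments_preserve_fix_order(self):
        df = _fix_table([(i * 10, 0) for i in range(12)])
        segs = geo.segment_trajectory(df)
        rebuilt = pd.concat([s.fixes for s in segs], ignore_index=True)
        assert rebuilt["x"].tolist() == df["x"].tolist()


class TestStepSeries:
    def _series(self, coords):
        seg = geo.TrajectorySegment(group_id="a", fixes=_fix_table(coords))
        return geo.compute_step_series(seg)

    def test_three_four_five_triangle(self):
        s = self._series([(0, 0), (3, 4)])
        assert s.step_lengths[0] == pytest.approx(5.0)

    def test_collinear_motion_has_zero_turning(self):
        s = self._series([(0, 0), (1, 0), (2, 0)])
        assert s.turning_angles[0] == pytest.approx(0.0)

    def test_right_turn_is_negative_half_pi(self):
        s = self._series([(0, 0), (1, 0), (1, -1)])
        assert s.turning_angles[0] == pytest.approx(-np.pi / 2)

    def test_reversal_wraps_to_plus_pi(self):
        s = self._series([(0, 0), (1, 0), (0, 0)])
        assert s.turning_angles[0] == pytest.approx(np.pi)

    def test_zero_length_step_blanks_adjacent_angles(self):
        s = self._series([(0, 0), (1, 0), (1, 0), (2, 0)])
        assert s.step_lengths[1] == 0.0
        assert np.isnan(s.turning_angles).all()

    def test_counts_match_fixes(self):
        s = self._series([(i, i % 3) for i in range(7)])
        assert len(s.step_lengths) == 6 and len(s.turning_angles) == 5

    def test_reversing_fixes_negates_angles_and_keeps_steps(self):
        coords = [(0, 0), (3, 1), (4, 5), (2, 6), (1, 2)]
        fwd = self._series(coords)
        rev = self._series(coords[::-1])
        np.testing.assert_allclose(rev.step_lengths, fwd.step_lengths[::-1])
        # up to the +/- pi tie, reversal negates each turning angle
        fwd_th = fwd.turning_angles[::-1]
        ok = np.isclose(rev.turning_angles, -fwd_th) | np.isclose(
            np.abs(rev.turning_angles), np.pi
        )
        assert ok.all()


class TestAngleWrapping:
    @given(st.floats(-50.0, 50.0))
    @settings(max_examples=80, derandomize=True)
    def test_wrap_lands_in_half_open_interval_and_is_idempotent(self, theta):
        w = float(geo.wrap_angle(theta))
        assert -np.pi < w <= np.pi
        assert float(geo.wrap_angle(w)) == pytest.approx(w, abs=1e-12)


class TestFeedingPeriod:
    @pytest.mark.parametrize(
        "date,expected",
        [
            ("2023-05-10", FeedingPeriod.FRUIT),
            ("2024-01-05", FeedingPeriod.MIXED),
            ("2023-10-01", FeedingPeriod.MIXED),
            ("2023-04-01", FeedingPeriod.FRUIT),
            ("2023-09-30", FeedingPeriod.FRUIT),
            ("2024-03-31", FeedingPeriod.MIXED),
        ],
    )
    def test_month_rule(self, date, expected):
        assert geo.assign_period(date) is expected
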