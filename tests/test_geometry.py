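"""Projection, rotation and turning-point step extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betpl.geometry import (PlanarTrack, Trajectory, extract_steps,
                            haversine_km, inverse_project, project_to_plane,
                            rotate, split_on_gaps, steps_1d, turning_points_1d)


def _make_traj(lat, lon):
    t0 = np.datetime64("2015-06-01T00:00:00")
    times = t0 + np.arange(len(lat)) * np.timedelta64(600, "s")
    return Trajectory(id="x", times=times, lat=np.asarray(lat, float),
                      lon=np.asarray(lon, float))


def brute_turning_points(series):
    """Sign-change scan oracle (explicit loop, zeros carried over)."""
    d = np.sign(np.diff(np.asarray(series, float)))
    idx, last = [0], 0.0
    for i, s in enumerate(d):
        if s == 0.0:
            continue
        if last != 0.0 and s != last:
            idx.append(i)
        last = s
    if idx[-1] != len(series) - 1:
        idx.append(len(series) - 1)
    return np.array(idx)


class TestProjection:
    def test_half_degree_latitude_separation(self):
        # haversine oracle: 0.5 deg of latitude ~ 55.6 km
        traj = _make_traj([39.0, 39.5, 39.25], [-9.0, -9.0, -9.0])
        track = project_to_plane(traj)
        d = np.hypot(track.x[1] - track.x[0], track.y[1] - track.y[0])
        expected = haversine_km(39.0, -9.0, 39.5, -9.0)
        assert d == pytest.approx(expected, rel=0.01)
        assert expected == pytest.approx(55.6, rel=0.01)

    def test_repeated_fix_is_identity(self):
        times = np.datetime64("2015-06-01") + np.arange(3) * np.timedelta64(600, "s")
        traj = Trajectory(id="x", times=times, lat=[39.0] * 3, lon=[-9.0] * 3)
        track = project_to_plane(traj)
        assert np.allclose(track.x, track.x[0])
        assert np.allclose(track.y, track.y[0])

    def test_3_4_5_triangle_side_ratios(self):
        # construct vertices by inverse projection, re-project, check ratios
        origin = (40.0, 5.0)
        x = np.array([0.0, 300.0, 0.0])
        y = np.array([0.0, 0.0, 400.0])
        lat, lon = inverse_project(x, y, origin)
        traj = _make_traj(lat, lon)
        track = project_to_plane(traj, max_speed_kmh=np.inf)
        p = np.column_stack([track.x, track.y])
        a = np.linalg.norm(p[1] - p[0])
        b = np.linalg.norm(p[2] - p[0])
        c = np.linalg.norm(p[2] - p[1])
        assert a / b == pytest.approx(3.0 / 4.0, rel=0.01)
        assert c / b == pytest.approx(5.0 / 4.0, rel=0.01)

    def test_round_trip_inverse(self):
        origin = (40.0, 5.0)
        rng = np.random.default_rng(0)
        x, y = rng.uniform(-400, 400, 50), rng.uniform(-400, 400, 50)
        lat, lon = inverse_project(x, y, origin)
        traj = _make_traj(lat, lon)
        track = project_to_plane(traj, origin=origin, max_speed_kmh=np.inf)
        assert np.allclose(track.x, x, atol=1e-6)
        assert np.allclose(track.y, y, atol=1e-6)

    def test_nonfinite_coordinates_rejected_with_index(self):
        times = np.datetime64("2015-06-01") + np.arange(3) * np.timedelta64(600, "s")
        with pytest.raises(ValueError, match="fix 1"):
            Trajectory(id="x", times=times, lat=[39.0, np.nan, 39.1],
                       lon=[-9.0, -9.0, -9.0])

    def test_implausible_jump_flagged(self):
        traj = _make_traj([39.0, 41.0, 41.1], [-9.0, -9.0, -9.0])  # 222 km/10 min
        with pytest.raises(ValueError, match="implausible"):
            project_to_plane(traj)


class TestRotation:
    def _track(self, rng, n=40):
        xy = rng.normal(0, 50, (n, 2))
        times = np.datetime64("2015-06-01") + np.arange(n) * np.timedelta64(600, "s")
        return PlanarTrack(id="x", x=xy[:, 0], y=xy[:, 1], origin=(0, 0), times=times)

    def test_theta_zero_identity(self, rng):
        track = self._track(rng)
        rot = rotate(track, 0.0)
        assert np.array_equal(rot.x, track.x) and np.array_equal(rot.y, track.y)

    def test_quarter_turn(self):
        times = np.datetime64("2015-06-01") + np.arange(2) * np.timedelta64(600, "s")
        track = PlanarTrack(id="x", x=[0.0, 1.0], y=[0.0, 0.0], origin=(0, 0),
                            times=times)
        rot = rotate(track, 90.0)
        assert rot.x[1] - rot.x[0] == pytest.approx(0.0, abs=1e-12)
        assert rot.y[1] - rot.y[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("theta", [15.0, 30.0, 45.0, 123.4])
    def test_isometry(self, rng, theta):
        track = self._track(rng, n=25)
        rot = rotate(track, theta)
        p0 = np.column_stack([track.x, track.y])
        p1 = np.column_stack([rot.x, rot.y])
        d0 = np.linalg.norm(p0[:, None] - p0[None], axis=-1)
        d1 = np.linalg.norm(p1[:, None] - p1[None], axis=-1)
        assert np.max(np.abs(d0 - d1)) < 1e-9


class TestTurningPoints:
    @pytest.mark.parametrize("series,expected_steps", [
        ([0, 1, 2, 1, 3], [2, 1, 2]),
        ([0, 1, 2, 3], [3]),
        ([0, 1, 0, 1], [1, 1, 1]),
    ])
    def test_known_series(self, series, expected_steps):
        assert list(steps_1d(series)) == expected_steps

    def test_example_turn_indices(self):
        assert list(turning_points_1d([0, 1, 2, 1, 3])) == [0, 2, 3, 4]

    def test_zero_runs_do_not_break_direction(self):
        # stationary fixes inside a monotone run: no spurious turns
        assert list(steps_1d([0, 1, 1, 1, 2, 3])) == [3]
        # direction carried across the zero run, reversal still detected
        assert list(steps_1d([0, 2, 2, 1])) == [2, 1]

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(-5, 5), min_size=2, max_size=30))
    def test_matches_bruteforce_oracle(self, series):
        got = turning_points_1d(series)
        want = brute_turning_points(series)
        assert np.array_equal(got, want)


class TestExtractSteps:
    def _alternating_track(self, n=60):
        # axis-aligned unit moves alternating direction each fix
        x = np.tile([0.0, 1.0], n // 2)
        times = np.datetime64("2015-06-01") + np.arange(n) * np.timedelta64(600, "s")
        return PlanarTrack(id="x", x=x, y=np.zeros(n), origin=(0, 0), times=times)

    def test_alternating_walk_unit_steps(self):
        sample = extract_steps(self._alternating_track(), theta=0.0, lim_a=0.5)
        assert sample.sufficient
        assert np.allclose(sample.lengths, 1.0)

    def test_high_lim_a_forces_insufficient(self):
        sample = extract_steps(self._alternating_track(), theta=0.0, lim_a=2.0)
        assert sample.n == 0 and not sample.sufficient

    def test_pooling_counts_axes_sum(self, rng):
        n = 200
        xy = np.cumsum(rng.normal(0, 3, (n, 2)), axis=0)
        times = np.datetime64("2015-06-01") + np.arange(n) * np.timedelta64(600, "s")
        track = PlanarTrack(id="x", x=xy[:, 0], y=xy[:, 1], origin=(0, 0), times=times)
        lim_a, l_max = 0.5, 600.0
        sample = extract_steps(track, 0.0, lim_a)
        nx = sum(1 for s in steps_1d(track.x) if lim_a <= s <= l_max)
        ny = sum(1 for s in steps_1d(track.y) if lim_a <= s <= l_max)
        assert sample.n == nx + ny

    def test_monotone_in_lim_a(self, rng):
        n = 300
        xy = np.cumsum(rng.normal(0, 3, (n, 2)), axis=0)
        times = np.datetime64("2015-06-01") + np.arange(n) * np.timedelta64(600, "s")
        track = PlanarTrack(id="x", x=xy[:, 0], y=xy[:, 1], origin=(0, 0), times=times)
        counts = [extract_steps(track, 0.0, a).n for a in (0.1, 0.5, 1.0, 2.0)]
        assert counts == sorted(counts, reverse=True)


def test_split_on_gaps():
    t0 = np.datetime64("2015-06-01T00:00:00")
    times = np.concatenate([
        t0 + np.arange(5) * np.timedelta64(600, "s"),
        t0 + np.timedelta64(5, "h") + np.arange(5) * np.timedelta64(600, "s"),
    ])
    traj = Trajectory(id="g", times=times, lat=np.linspace(39, 39.1, 10),
                      lon=np.full(10, -9.0))
    pieces = split_on_gaps(traj, max_gap_min=60.0)
    assert len(pieces) == 2
    assert all(p.n_fixes == 5 for p in pieces)
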