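"""Wind grids: trilinear interpolation, trip summaries, head/tail components."""

import numpy as np
import pytest

from betpl.geometry import Trajectory
from betpl.wind import (WindGrid, headtail_components, interp_wind,
                        summarize_wind)


def _grid(u=None, v=None, nt=5, nlat=4, nlon=6):
    time = (np.datetime64("2015-06-01T00:00:00")
            + np.arange(nt) * np.timedelta64(6, "h"))
    lat = 38.0 + 0.5 * np.arange(nlat)
    lon = -10.0 + 0.5 * np.arange(nlon)
    shape = (nt, nlat, nlon)
    if u is None:
        rng = np.random.default_rng(0)
        u, v = rng.normal(3, 2, shape), rng.normal(-1, 2, shape)
    return WindGrid(time=time, lat=lat, lon=lon, u=u, v=v)


def brute_trilinear(grid, lat, lon, t):
    """Explicit 8-corner weighted average oracle."""
    tf = np.datetime64(t, "s").astype("int64")
    taxis = grid.time.astype("int64")
    it = np.searchsorted(taxis, tf, side="right") - 1
    it = min(max(it, 0), len(taxis) - 2)
    ila = min(max(np.searchsorted(grid.lat, lat, side="right") - 1, 0),
              len(grid.lat) - 2)
    ilo = min(max(np.searchsorted(grid.lon, lon, side="right") - 1, 0),
              len(grid.lon) - 2)
    wt = (tf - taxis[it]) / (taxis[it + 1] - taxis[it])
    wa = (lat - grid.lat[ila]) / (grid.lat[ila + 1] - grid.lat[ila])
    wo = (lon - grid.lon[ilo]) / (grid.lon[ilo + 1] - grid.lon[ilo])
    out = []
    for arr in (grid.u, grid.v):
        acc = 0.0
        for dt, ft in ((0, 1 - wt), (1, wt)):
            for da, fa in ((0, 1 - wa), (1, wa)):
                for do, fo in ((0, 1 - wo), (1, wo)):
                    acc += ft * fa * fo * arr[it + dt, ila + da, ilo + do]
        out.append(acc)
    return out[0], out[1]


class TestInterpolation:
    def test_node_identity(self):
        g = _grid()
        u, v, s = interp_wind(g, g.lat[2], g.lon[3], g.time[1])
        assert u[0] == pytest.approx(g.u[1, 2, 3])
        assert v[0] == pytest.approx(g.v[1, 2, 3])
        assert s[0] == pytest.approx(np.hypot(g.u[1, 2, 3], g.v[1, 2, 3]))

    def test_spatial_midpoint_linear(self):
        u = np.zeros((2, 2, 2))
        u[:, :, 0], u[:, :, 1] = 4.0, 8.0
        g = _grid(u=u, v=np.zeros((2, 2, 2)), nt=2, nlat=2, nlon=2)
        ui, _, _ = interp_wind(g, g.lat[0], (g.lon[0] + g.lon[1]) / 2, g.time[0])
        assert ui[0] == pytest.approx(6.0)

    def test_matches_bruteforce_oracle(self):
        g = _grid()
        rng = np.random.default_rng(7)
        for _ in range(25):
            la = rng.uniform(g.lat[0], g.lat[-1])
            lo = rng.uniform(g.lon[0], g.lon[-1])
            t = g.time[0] + np.timedelta64(int(rng.uniform(0, 24 * 3600)), "s")
            ui, vi, _ = interp_wind(g, la, lo, t)
            ub, vb = brute_trilinear(g, la, lo, t)
            assert abs(ui[0] - ub) < 1e-10 and abs(vi[0] - vb) < 1e-10

    def test_bounded_by_corner_extremes(self):
        g = _grid()
        rng = np.random.default_rng(1)
        la = rng.uniform(g.lat[0], g.lat[-1], 50)
        lo = rng.uniform(g.lon[0], g.lon[-1], 50)
        t = g.time[0] + np.timedelta64(3, "h")
        ui, _, _ = interp_wind(g, la, lo, np.full(50, t))
        assert np.all(ui <= g.u[:2].max() + 1e-12)
        assert np.all(ui >= g.u[:2].min() - 1e-12)

    def test_outside_hull_names_axis(self):
        g = _grid()
        with pytest.raises(ValueError, match="lat"):
            interp_wind(g, 60.0, g.lon[0], g.time[0])
        with pytest.raises(ValueError, match="time"):
            interp_wind(g, g.lat[0], g.lon[0],
                        g.time[-1] + np.timedelta64(1, "D"))

    def test_masked_corner_nearest_fallback(self):
        u = np.full((2, 2, 2), 5.0)
        u[0, 0, 0] = np.nan
        g = _grid(u=u, v=np.zeros((2, 2, 2)), nt=2, nlat=2, nlon=2)
        ui, _, _ = interp_wind(g, g.lat[0] + 0.1, g.lon[0] + 0.1, g.time[0])
        assert np.isfinite(ui[0])


def _traj_at(grid, lats, lons, dt_s=600):
    times = grid.time[0] + np.arange(len(lats)) * np.timedelta64(dt_s, "s")
    return Trajectory(id="w", times=times, lat=lats, lon=lons)


class TestSummaries:
    def test_uniform_field_all_averages_equal(self):
        shape = (5, 4, 6)
        g = _grid(u=np.full(shape, 7.0), v=np.zeros(shape))
        traj = _traj_at(g, np.linspace(38.2, 39.0, 10), np.linspace(-9.8, -9.0, 10))
        ws = summarize_wind(traj, g)
        assert ws.mean_v == pytest.approx(7.0)
        assert ws.rms_v == pytest.approx(7.0)
        assert ws.cubic_v == pytest.approx(7.0)

    def test_two_fix_hand_arithmetic(self):
        # speeds {3, 4}: mean 3.5, rms sqrt(12.5), cubic cbrt(45.5)
        shape = (2, 2, 2)
        u = np.zeros(shape)
        u[0] = 3.0
        u[1] = 5.0  # linear in time: 3 at t0, 4 at t0+3h (halfway to 6h node)
        g = _grid(u=u, v=np.zeros(shape), nt=2, nlat=2, nlon=2)
        times = np.array([g.time[0], g.time[0] + np.timedelta64(3, "h")])
        traj = Trajectory(id="w", times=np.append(times, times[1] + np.timedelta64(5400, "s")).astype("datetime64[s]"),
                          lat=[g.lat[0]] * 3, lon=[g.lon[0]] * 3)
        ws = summarize_wind(traj, g)
        speeds = np.array([3.0, 4.0, 4.5])
        assert ws.mean_v == pytest.approx(speeds.mean())
        assert ws.rms_v == pytest.approx(np.sqrt((speeds ** 2).mean()))
        assert ws.cubic_v == pytest.approx(np.cbrt((speeds ** 3).mean()))

    def test_power_mean_ordering(self):
        g = _grid()
        rng = np.random.default_rng(5)
        traj = _traj_at(g, rng.uniform(38.2, 39.2, 30), rng.uniform(-9.8, -8.0, 30))
        ws = summarize_wind(traj, g)
        assert ws.mean_v <= ws.rms_v + 1e-12 <= ws.cubic_v + 1e-12

    def test_no_usable_fixes_raises(self):
        g = _grid()
        times = g.time[-1] + np.timedelta64(10, "D") + np.arange(3) * np.timedelta64(600, "s")
        traj = Trajectory(id="w", times=times, lat=[38.2] * 3, lon=[-9.8] * 3)
        with pytest.raises(ValueError, match="hull"):
            summarize_wind(traj, g)


class TestHeadTail:
    def test_aligned_and_orthogonal(self):
        shape = (2, 3, 3)
        g = _grid(u=np.zeros(shape), v=np.full(shape, 5.0), nt=2, nlat=3, nlon=3)
        # flight due north
        traj = _traj_at(g, np.array([38.2, 38.4, 38.6]), np.full(3, -9.5))
        head, cross = headtail_components(traj, g)
        assert head[0] == pytest.approx(-5.0, abs=1e-6)   # tailwind
        assert cross[0] == pytest.approx(0.0, abs=1e-6)
        # wind due east, flight due north
        g2 = _grid(u=np.full(shape, 5.0), v=np.zeros(shape), nt=2, nlat=3, nlon=3)
        head2, cross2 = headtail_components(traj, g2)
        assert head2[0] == pytest.approx(0.0, abs=1e-6)
        assert abs(cross2[0]) == pytest.approx(5.0, abs=1e-6)

    def test_energy_identity_and_vector_oracle(self):
        g = _grid()
        rng = np.random.default_rng(11)
        traj = _traj_at(g, 38.2 + np.cumsum(rng.uniform(0, 0.05, 20)),
                        -9.8 + np.cumsum(rng.uniform(0, 0.05, 20)))
        head, cross = headtail_components(traj, g)
        u, v, speed = interp_wind(g, traj.lat[:-1], traj.lon[:-1], traj.times[:-1])
        ok = np.isfinite(head)
        assert np.allclose(head[ok] ** 2 + cross[ok] ** 2, speed[ok] ** 2,
                           atol=1e-9)

    def test_zero_displacement_skipped(self):
        g = _grid()
        traj = _traj_at(g, np.array([38.2, 38.2, 38.4]), np.array([-9.5, -9.5, -9.5]))
        head, _ = headtail_components(traj, g)
        assert np.isnan(head[0]) and np.isfinite(head[1])


def test_csv_round_trip(tmp_path):
    g = _grid()
    path = tmp_path / "wind.csv"
    g.to_csv(path)
    g2 = WindGrid.from_csv(path)
    assert np.allclose(g.u, g2.u) and np.allclose(g.v, g2.v)
    assert np.array_equal(g.time, g2.time)
    ds = g.to_dataset()
    g3 = WindGrid.from_dataset(ds)
    assert np.allclose(g.v, g3.v)
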