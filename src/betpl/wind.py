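"""Gridded wind fields: interpolation to fixes, trip summaries, head/tail winds.

Wind comes as eastward (u) and northward (v) 10-m components on a regular
0.5-degree / 6-hour grid.  Components (never speeds) are interpolated
trilinearly in (time, lat, lon) to each GPS fix — interpolating speed
directly is biased low wherever the direction shears — and the speed is
the magnitude of the interpolated vector.  Per-trajectory summaries
report the arithmetic mean speed <v> plus the higher-order averages
sqrt(<v^2>) and cbrt(<v^3>) that weight gusts more heavily.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .geometry import Trajectory


@dataclass
class WindGrid:
    """Regular (time, lat, lon) grid of wind components in m/s."""

    time: np.ndarray   # datetime64[s], strictly increasing, regular
    lat: np.ndarray    # degrees, increasing
    lon: np.ndarray    # degrees, increasing
    u: np.ndarray      # east component, shape (time, lat, lon)
    v: np.ndarray      # north component, same shape

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype="datetime64[s]")
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        shape = (self.time.size, self.lat.size, self.lon.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(f"component arrays must have shape {shape}")
        for name, ax in (("time", self.time.astype("int64")),
                         ("lat", self.lat), ("lon", self.lon)):
            if ax.size > 1 and np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} axis not strictly increasing")

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_dataset(cls, ds: xr.Dataset, u_var: str = "u", v_var: str = "v"):
        return cls(time=ds["time"].values, lat=ds["lat"].values,
                   lon=ds["lon"].values, u=ds[u_var].values, v=ds[v_var].values)

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"u": (("time", "lat", "lon"), self.u),
             "v": (("time", "lat", "lon"), self.v)},
            coords={"time": self.time, "lat": self.lat, "lon": self.lon},
            attrs={"description": "10-m wind components, m/s"},
        )

    @classmethod
    def from_csv(cls, path):
        """Long-format CSV (time, lat, lon, u, v) reshaped to the grid."""
        df = pd.read_csv(path)
        df["time"] = pd.to_datetime(df["time"]).astype("datetime64[s]")
        time = np.sort(df["time"].unique())
        lat = np.sort(df["lat"].unique())
        lon = np.sort(df["lon"].unique())
        shape = (time.size, lat.size, lon.size)
        if len(df) != np.prod(shape):
            raise ValueError("long CSV does not cover a full regular grid")
        df = df.sort_values(["time", "lat", "lon"])
        return cls(time=time, lat=lat, lon=lon,
                   u=df["u"].to_numpy().reshape(shape),
                   v=df["v"].to_numpy().reshape(shape))

    def to_csv(self, path) -> None:
        tt, la, lo = np.meshgrid(self.time, self.lat, self.lon, indexing="ij")
        pd.DataFrame({
            "time": pd.to_datetime(tt.ravel()).strftime("%Y-%m-%dT%H:%M:%S"),
            "lat": la.ravel(), "lon": lo.ravel(),
            "u": self.u.ravel(), "v": self.v.ravel(),
        }).to_csv(path, index=False)


def _time_float(t) -> np.ndarray:
    return np.asarray(t, dtype="datetime64[s]").astype("int64").astype(float)


def interp_wind(grid: WindGrid, lat, lon, time):
    """Trilinear interpolation of (u, v) at query points; speed = |(u, v)|.

    Queries must lie inside the grid hull; the offending axis is named
    otherwise.  NaN (masked) nodes propagate: queries touching them fall
    back to the nearest valid node value and are flagged by a NaN-free
    result with ``flagged`` True in :func:`summarize_wind`.
    """
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    tf = np.atleast_1d(_time_float(time))
    axes = (_time_float(grid.time), grid.lat, grid.lon)
    for name, ax, q in (("time", axes[0], tf), ("lat", axes[1], lat),
                        ("lon", axes[2], lon)):
        if np.any(q < ax[0]) or np.any(q > ax[-1]):
            raise ValueError(f"query outside wind grid hull on axis '{name}'")
    pts = np.column_stack([tf, lat, lon])
    ui = RegularGridInterpolator(axes, grid.u, method="linear")(pts)
    vi = RegularGridInterpolator(axes, grid.v, method="linear")(pts)
    nan = ~(np.isfinite(ui) & np.isfinite(vi))
    if nan.any():  # masked corners: nearest-valid-node fallback
        from scipy.ndimage import distance_transform_edt
        bad = ~(np.isfinite(grid.u) & np.isfinite(grid.v))
        idx = distance_transform_edt(bad, return_distances=False,
                                     return_indices=True)
        u_fill, v_fill = grid.u[tuple(idx)], grid.v[tuple(idx)]
        un = RegularGridInterpolator(axes, u_fill, method="nearest")(pts[nan])
        vn = RegularGridInterpolator(axes, v_fill, method="nearest")(pts[nan])
        ui[nan], vi[nan] = un, vn
    return ui, vi, np.hypot(ui, vi)


@dataclass
class WindSummary:
    source_id: str
    mean_v: float    # <v>
    rms_v: float     # sqrt(<v^2>)
    cubic_v: float   # cbrt(<v^3>)
    n_fixes: int
    n_skipped: int = 0
    mean_head: float = np.nan   # mean headwind component (positive part)
    mean_tail: float = np.nan   # mean tailwind component (positive part)
    flagged: bool = False


def summarize_wind(traj: Trajectory, grid: WindGrid,
                   with_headtail: bool = False) -> WindSummary:
    """Wind speed averaged over the usable fixes of one trajectory."""
    lat, lon = traj.lat, traj.lon
    tf = _time_float(traj.times)
    axes_t = _time_float(grid.time)
    ok = ((tf >= axes_t[0]) & (tf <= axes_t[-1])
          & (lat >= grid.lat[0]) & (lat <= grid.lat[-1])
          & (lon >= grid.lon[0]) & (lon <= grid.lon[-1]))
    if not ok.any():
        raise ValueError(f"trajectory {traj.id}: no fixes inside the wind grid hull")
    u, v, speed = interp_wind(grid, lat[ok], lon[ok], traj.times[ok])
    out = WindSummary(
        source_id=traj.id,
        mean_v=float(speed.mean()),
        rms_v=float(np.sqrt((speed ** 2).mean())),
        cubic_v=float(np.cbrt((speed ** 3).mean())),
        n_fixes=int(ok.sum()), n_skipped=int((~ok).sum()),
    )
    if with_headtail:
        head, _cross = headtail_components(traj, grid)
        h = head[np.isfinite(head)]
        out.mean_head = float(np.maximum(h, 0.0).mean()) if h.size else np.nan
        out.mean_tail = float(np.maximum(-h, 0.0).mean()) if h.size else np.nan
    return out


def headtail_components(traj: Trajectory, grid: WindGrid):
    """Per-fix head and cross wind components (m/s).

    The flight direction at fix i is the bearing of the displacement to
    fix i+1 (computed in the local plane).  head = -(wind . unit flight
    direction), so positive = headwind, negative = tailwind; cross is the
    signed perpendicular component (positive = wind from the left of the
    flight direction).  Fixes with zero displacement or outside the grid
    hull give NaN.
    """
    from .geometry import project_to_plane
    if traj.n_fixes < 2:
        raise ValueError("need >= 2 fixes")
    track = project_to_plane(traj)
    dx, dy = np.diff(track.x), np.diff(track.y)
    norm = np.hypot(dx, dy)
    head = np.full(traj.n_fixes - 1, np.nan)
    cross = np.full(traj.n_fixes - 1, np.nan)
    tf = _time_float(traj.times[:-1])
    axes_t = _time_float(grid.time)
    ok = ((norm > 0)
          & (tf >= axes_t[0]) & (tf <= axes_t[-1])
          & (traj.lat[:-1] >= grid.lat[0]) & (traj.lat[:-1] <= grid.lat[-1])
          & (traj.lon[:-1] >= grid.lon[0]) & (traj.lon[:-1] <= grid.lon[-1]))
    if ok.any():
        u, v, _ = interp_wind(grid, traj.lat[:-1][ok], traj.lon[:-1][ok],
                              traj.times[:-1][ok])
        ex, ey = dx[ok] / norm[ok], dy[ok] / norm[ok]
        head[ok] = -(u * ex + v * ey)
        cross[ok] = ex * v - ey * u
    return head, cross
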