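"""Planar projection of GPS tracks and step-length extraction.

Trajectories of central-place foraging seabirds arrive as timestamped
latitude/longitude fixes.  The analysis operates on planar kilometre
coordinates: tracks are projected with a local azimuthal-equidistant
projection about the trajectory centroid (distance distortion < 1% for
the <= 1000 km spans of shearwater foraging trips), optionally rotated,
and step lengths are extracted with the axis-projection turning-point
method: each planar track is projected onto the x and y axes, turning
points of the resulting 1-D series are direction reversals, and the 1-D
distances between consecutive reversals from both axes are pooled into
one step-length sample.  The method needs no turning-angle threshold and
preserves power-law step statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

#: hard upper bound on usable step lengths (km); longest step observed at sea
L_MAX_KM = 600.0

#: default minimum number of surviving steps for a sample to be usable
MIN_STEPS = 30


@dataclass
class Trajectory:
    """A GPS track: ordered timestamped geographic fixes plus metadata.

    ``times`` are UTC (numpy datetime64), strictly increasing; at least
    3 fixes; |lat| <= 90 and lon wrapped to (-180, 180].
    """

    id: str
    times: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        n = len(self.times)
        if not (n == len(self.lat) == len(self.lon)):
            raise ValueError(f"trajectory {self.id}: ragged fix arrays")
        if n < 3:
            raise ValueError(f"trajectory {self.id}: needs >= 3 fixes, got {n}")
        if not (np.isfinite(self.lat).all() and np.isfinite(self.lon).all()):
            bad = int(np.flatnonzero(~(np.isfinite(self.lat) & np.isfinite(self.lon)))[0])
            raise ValueError(f"trajectory {self.id}: non-finite coordinates at fix {bad}")
        if np.any(np.abs(self.lat) > 90.0):
            raise ValueError(f"trajectory {self.id}: |lat| > 90")
        # wrap lon to (-180, 180]
        lon = np.mod(self.lon + 180.0, 360.0) - 180.0
        lon[lon == -180.0] = 180.0
        self.lon = lon
        if np.any(np.diff(self.times.astype("int64")) <= 0):
            raise ValueError(f"trajectory {self.id}: timestamps not strictly increasing")

    @property
    def n_fixes(self) -> int:
        return len(self.times)

    def duration_days(self) -> float:
        span = (self.times[-1] - self.times[0]) / np.timedelta64(1, "s")
        return float(span) / 86400.0

    def max_displacement_km(self) -> float:
        """Maximum great-circle distance of any fix from the first fix.

        The first fix stands in for the colony when colony coordinates are
        not part of the metadata.
        """
        return float(
            haversine_km(self.lat[0], self.lon[0], self.lat, self.lon).max()
        )


@dataclass
class PlanarTrack:
    """Planar kilometre coordinates of a trajectory about a stated origin."""

    id: str
    x: np.ndarray
    y: np.ndarray
    origin: tuple  # (lat, lon) of projection centre
    times: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class StepSample:
    """Pooled 1-D step lengths for one (lim_a, theta) parametrization."""

    lengths: np.ndarray
    lim_a: float
    theta: float
    source_id: str
    n_raw: int = 0  # pooled steps before the [lim_a, l_max] filter
    l_max: float = L_MAX_KM
    min_steps: int = MIN_STEPS

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)

    @property
    def n(self) -> int:
        return len(self.lengths)

    @property
    def sufficient(self) -> bool:
        return self.n >= self.min_steps


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (spherical earth)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def project_to_plane(traj: Trajectory, origin: tuple | None = None,
                     max_speed_kmh: float = 1200.0) -> PlanarTrack:
    """Project a trajectory to planar km (azimuthal equidistant).

    The projection centre defaults to the trajectory centroid.  Distances
    from the centre are exact; for spans <= 1000 km the distortion of
    other pairwise distances stays below 1%.

    ``max_speed_kmh`` flags physically implausible jumps (default
    corresponds to 200 km per 10-min gap).
    """
    if origin is None:
        origin = (float(traj.lat.mean()), float(_mean_lon(traj.lon)))
    lat0, lon0 = np.radians(origin[0]), np.radians(origin[1])
    lat = np.radians(traj.lat)
    dlon = np.radians(traj.lon) - lon0
    dlon = np.mod(dlon + np.pi, 2 * np.pi) - np.pi

    # azimuthal equidistant: rho = angular distance, theta = azimuth from centre
    cos_c = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(dlon)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    k = np.where(c > 0, c / np.maximum(np.sin(c), 1e-300), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlon)
    y = EARTH_RADIUS_KM * k * (
        np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(dlon)
    )

    d = np.hypot(np.diff(x), np.diff(y))
    dt_h = np.diff(traj.times.astype("int64")) / 3600.0
    bad = np.flatnonzero(d > max_speed_kmh * dt_h)
    if bad.size:
        raise ValueError(
            f"trajectory {traj.id}: implausible jump of {d[bad[0]]:.0f} km "
            f"at fix {int(bad[0]) + 1}"
        )
    return PlanarTrack(id=traj.id, x=x, y=y, origin=origin, times=traj.times)


def inverse_project(x, y, origin: tuple) -> tuple:
    """Inverse azimuthal-equidistant: planar km -> (lat, lon) degrees."""
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
    lat0, lon0 = np.radians(origin[0]), np.radians(origin[1])
    c = np.hypot(x, y)
    with np.errstate(invalid="ignore"):
        lat = np.where(
            c > 0,
            np.arcsin(np.clip(
                np.cos(c) * np.sin(lat0) + y * np.sin(c) * np.cos(lat0) / np.maximum(c, 1e-300),
                -1.0, 1.0)),
            lat0,
        )
        lon = lon0 + np.arctan2(
            x * np.sin(c),
            c * np.cos(lat0) * np.cos(c) - y * np.sin(lat0) * np.sin(c),
        )
    lon = np.mod(lon + np.pi, 2 * np.pi) - np.pi
    return np.degrees(lat), np.degrees(lon)


def _mean_lon(lon: np.ndarray) -> float:
    """Circular mean longitude (safe near the date line)."""
    rad = np.radians(lon)
    return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))


def rotate(track: PlanarTrack, theta_deg: float) -> PlanarTrack:
    """Rigid rotation of the track by theta degrees about its first point."""
    if theta_deg == 0.0:
        return replace(track, x=track.x.copy(), y=track.y.copy())
    t = np.radians(theta_deg)
    ct, st = np.cos(t), np.sin(t)
    dx, dy = track.x - track.x[0], track.y - track.y[0]
    return replace(
        track,
        x=track.x[0] + ct * dx - st * dy,
        y=track.y[0] + st * dx + ct * dy,
    )


def turning_points_1d(series: Sequence[float]) -> np.ndarray:
    """Indices of direction reversals in a 1-D position series.

    A turning point is a fix where the sign of the successive displacement
    flips from nonzero to the opposite nonzero sign.  Zero displacements
    (stationary fixes) do not count as reversals: the travel direction is
    carried over runs of ties, so GPS jitter at rest does not fragment
    steps.  The first and last indices are always included as segment
    boundaries.
    """
    s = np.asarray(series, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 positions")
    d = np.sign(np.diff(s))
    nz = np.flatnonzero(d)
    rev = nz[1:][d[nz][1:] != d[nz][:-1]]  # reversal at the fix starting that move
    idx = np.concatenate([[0], rev, [s.size - 1]])
    return np.unique(idx).astype(int)


def steps_1d(series: Sequence[float]) -> np.ndarray:
    """1-D step lengths between consecutive turning points."""
    s = np.asarray(series, dtype=float)
    tp = turning_points_1d(s)
    return np.abs(np.diff(s[tp]))


def extract_steps(track: PlanarTrack, theta: float, lim_a: float,
                  l_max: float = L_MAX_KM, min_steps: int = MIN_STEPS) -> StepSample:
    """Axis-projection step-length sample for one (lim_a, theta).

    Rotates the track by ``theta``, projects onto the x and y axes,
    extracts 1-D steps on each axis, pools both axes, then keeps lengths
    in [lim_a, l_max].  The lower cut removes small-scale behaviour not
    related to navigation; the upper cut removes implausible giants.
    """
    rot = rotate(track, theta)
    pooled = np.concatenate([steps_1d(rot.x), steps_1d(rot.y)])
    pooled = pooled[pooled > 0]
    kept = pooled[(pooled >= lim_a) & (pooled <= l_max)]
    return StepSample(
        lengths=np.sort(kept), lim_a=lim_a, theta=theta,
        source_id=track.id, n_raw=len(pooled), l_max=l_max, min_steps=min_steps,
    )


def split_on_gaps(traj: Trajectory, max_gap_min: float = 60.0) -> list:
    """Split a trajectory into pieces wherever the fix gap exceeds the limit.

    The 10-min fix cadence is assumed downstream; longer holes break the
    track into separately processed pieces.  Pieces with < 3 fixes are
    dropped.
    """
    gaps = np.diff(traj.times.astype("int64")) / 60.0
    cut = np.flatnonzero(gaps > max_gap_min) + 1
    if cut.size == 0:
        return [traj]
    pieces = []
    bounds = np.concatenate([[0], cut, [traj.n_fixes]])
    for k, (i, j) in enumerate(zip(bounds[:-1], bounds[1:])):
        if j - i >= 3:
            pieces.append(Trajectory(
                id=f"{traj.id}#{k}", times=traj.times[i:j],
                lat=traj.lat[i:j], lon=traj.lon[i:j], meta=dict(traj.meta),
            ))
    return pieces


def filter_colony_radius(traj: Trajectory, colony: tuple | None = None,
                         radius_km: float = 1.0) -> Trajectory:
    """Drop fixes within ``radius_km`` of the colony (nest attendance).

    The colony defaults to the first fix.  If fewer than 3 fixes survive
    the filter the original trajectory is returned unchanged (the lim_a
    scan already discards small-scale behaviour).
    """
    if colony is None:
        colony = (float(traj.lat[0]), float(traj.lon[0]))
    d = haversine_km(colony[0], colony[1], traj.lat, traj.lon)
    keep = d > radius_km
    if keep.sum() < 3:
        return traj
    return Trajectory(id=traj.id, times=traj.times[keep], lat=traj.lat[keep],
                      lon=traj.lon[keep], meta=dict(traj.meta))


# ---------------------------------------------------------------------------
# track I/O (CSV of fixes + metadata side table)

def read_tracks(path, meta_path=None) -> list:
    """Read trajectories from a fixes CSV (id, timestamp, lat, lon).

    ``meta_path`` optionally points to a side table CSV with columns
    id, species, colony, sex, period, region.
    """
    df = pd.read_csv(path)
    meta = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, dtype={"id": str})
        meta = {row["id"]: row.drop("id").to_dict() for _, row in mdf.iterrows()}
    out = []
    for tid, g in df.groupby("id", sort=False):
        g = g.sort_values("timestamp")
        out.append(Trajectory(
            id=str(tid),
            times=pd.to_datetime(g["timestamp"]).to_numpy().astype("datetime64[s]"),
            lat=g["lat"].to_numpy(),
            lon=g["lon"].to_numpy(),
            meta=meta.get(str(tid), {}),
        ))
    return out


def write_tracks(trajs: Sequence[Trajectory], path, meta_path=None) -> None:
    rows = []
    for t in trajs:
        rows.append(pd.DataFrame({
            "id": t.id,
            "timestamp": pd.to_datetime(t.times).strftime("%Y-%m-%dT%H:%M:%S"),
            "lat": t.lat,
            "lon": t.lon,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    if meta_path is not None:
        mrows = [{"id": t.id, **t.meta} for t in trajs]
        pd.DataFrame(mrows).to_csv(meta_path, index=False)


def to_geojson(traj: Trajectory) -> dict:
    """GeoJSON LineString for quick inspection in a viewer."""
    return {
        "type": "Feature",
        "properties": {"id": traj.id, **{k: str(v) for k, v in traj.meta.items()}},
        "geometry": {
            "type": "LineString",
            "coordinates": [[float(lo), float(la)] for lo, la in zip(traj.lon, traj.lat)],
        },
    }
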