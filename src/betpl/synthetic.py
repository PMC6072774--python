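"""Synthetic trajectories, wind fields and cohorts.

Two generators produce tracks with the statistical structure the
analysis assumes, so every pipeline stage is testable without any data
download:

* :func:`gen_betpl_walk` draws step lengths directly from a BETPL and
  assembles a 2-D walk (optionally biased toward a target bearing) —
  used for parameter-recovery and method-validation studies;
* :func:`gen_odor_walk` is mechanistic: the usable odor signal
  experienced during a straight flight bout decays stochastically — a
  Brownian concentration path with turbulent diffusivity D = a^2 C^2 / T
  and a slow systematic loss v = b C / T (flying on a fixed heading
  carries the bird out of the filament it locked onto; T is the signal
  decorrelation time, C the mean concentration scale).  The bout starts
  when the map is re-acquired at a solid signal level (2 c_tau, a
  detection-hysteresis band that keeps signal chatter from fragmenting
  flight) and ends at the first passage below the detection threshold
  c_tau; while lost, the bird reorients and the recovering signal climbs
  back (drift +v) until re-acquisition.  Flight-bout durations are then
  first passages of Brownian motion with drift over the band width
  c_tau, i.e. inverse-Gaussian: exactly t^(-3/2) exp(-t/tau1)
  exp(-tau0/t) with tau1 = 4D/v^2 = (4 a^2/b^2) T (lambda1 prop 1/T) and
  tau0 = c_tau^2/(4D) = T c_tau^2 / (4 a^2 C^2) (lambda2 prop
  T c_tau^2/C^2) — the BETPL emerges with exponent 3/2 from the
  diffusive square-root scaling, without 3/2 being an input anywhere.

Wind coupling: the mean concentration follows the emission heuristic
C = Q/V prop F/U with the sea-surface flux F prop U^gamma (gamma in
[2, 3]), so C prop U^(gamma-1); the signal correlation time is taken to
increase with wind speed as T prop U^t_exp (default t_exp = +1.5, which
reproduces a large-scale truncation that weakens with wind, i.e. a
negative log-log slope of lambda1 on U).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Trajectory, inverse_project
from .model import BetplParams, betpl_sample
from .wind import WindGrid

DEFAULT_COLONY = (39.4, -9.5)      # latitude, longitude of the synthetic colony
FIX_INTERVAL_S = 600.0             # GPS cadence: one fix every 10 minutes


@dataclass(frozen=True)
class OdorSignalParams:
    """Parameters of the simulated odor signal and flight behaviour.

    T : decorrelation timescale of the concentration signal (s)
    C : mean odor concentration (arbitrary units)
    c_tau : detection threshold (same units as C)
    fluct : relative turbulent fluctuation amplitude a; the signal
        diffusivity is D = a^2 C^2 / T
    drift : relative systematic signal-loss rate b; the in-flight
        concentration drifts down at v = b C / T (and recovers at +v
        while the bird searches)
    reacq_factor : map re-acquired above reacq_factor * c_tau
    flight_speed : km/h, constant within and between segments
    sim_dt : integration step (s); defaults to T/200
    """

    T: float = 1500.0
    C: float = 1.0
    c_tau: float = 0.25
    fluct: float = 0.5
    drift: float = 0.5
    reacq_factor: float = 2.0
    flight_speed: float = 36.0
    sim_dt: float | None = None

    def __post_init__(self):
        if min(self.T, self.C, self.c_tau, self.fluct, self.drift,
               self.flight_speed) <= 0:
            raise ValueError("T, C, c_tau, fluct, drift, flight_speed must be positive")
        if self.reacq_factor <= 1.0:
            raise ValueError("reacq_factor must exceed 1 (hysteresis band empty)")
        if self.dt > self.T / 50.0:
            raise ValueError("sim_dt must be <= T/50")

    @property
    def dt(self) -> float:
        return self.sim_dt if self.sim_dt is not None else self.T / 200.0

    @property
    def speed_km_s(self) -> float:
        return self.flight_speed / 3600.0

    @property
    def diffusivity(self) -> float:
        return self.fluct ** 2 * self.C ** 2 / self.T

    @property
    def loss_rate(self) -> float:
        return self.drift * self.C / self.T

    def predicted_lambdas_km(self) -> tuple:
        """Theoretical (lambda1, lambda2) in spatial units for reference."""
        gap = (self.reacq_factor - 1.0) * self.c_tau
        lam1_t = self.loss_rate ** 2 / (4.0 * self.diffusivity)
        lam2_t = gap ** 2 / (4.0 * self.diffusivity)
        return lam1_t / self.speed_km_s, lam2_t * self.speed_km_s


@dataclass(frozen=True)
class WindScenario:
    """Couples the odor-signal parameters to the mean wind speed U.

    C prop U^(gamma-1) from the flux heuristic (F prop U^gamma, C prop
    F/U); T prop U^t_exp.  Proportionality constants are free scales
    anchored at (U_ref, T_ref, C_ref).
    """

    U: float                      # mean wind speed, m/s
    gamma: float = 2.1            # volatile flux exponent, in [2, 3]
    t_exp: float = 1.5            # T prop U^t_exp
    U_ref: float = 6.0
    T_ref: float = 1500.0
    C_ref: float = 1.0
    c_tau: float = 0.25

    def __post_init__(self):
        if self.U <= 0:
            raise ValueError("U must be positive")
        if not (2.0 <= self.gamma <= 3.0):
            raise ValueError("gamma must lie in [2, 3]")

    def odor_params(self, **overrides) -> OdorSignalParams:
        scale = self.U / self.U_ref
        kw = dict(T=self.T_ref * scale ** self.t_exp,
                  C=self.C_ref * scale ** (self.gamma - 1.0),
                  c_tau=self.c_tau)
        kw.update(overrides)
        return OdorSignalParams(**kw)


# ---------------------------------------------------------------------------
# the mechanistic simulator


def _first_passage_steps(rng, gap: float, drift: float, sigma: float,
                         max_steps: int, block: int) -> int:
    """Euler-path step count until the cumulative path first drops below
    -gap (drift < 0 toward the barrier, > 0 away)."""
    x = 0.0
    taken = 0
    while taken < max_steps:
        path = x + np.cumsum(rng.normal(drift, sigma, block))
        hit = path < -gap
        if hit.any():
            return taken + int(np.argmax(hit)) + 1
        taken += block
        x = float(path[-1])
    return max_steps


def simulate_odor_phases(odor: OdorSignalParams, duration_s: float, seed=None):
    """Alternating (flight, lost) phase durations from the odor signal.

    Each flight bout is an Euler-simulated Brownian path of the
    concentration from the re-acquisition level down across the
    hysteresis band (width (reacq_factor - 1) c_tau) with drift -v;
    each lost phase is the recovery path back up with drift +v.  Phases
    are independent first passages (the signal state at each phase start
    sits exactly at the band edge).

    Returns (flight_s, lost_s, starts_with_flight).
    """
    dt = odor.dt
    sigma = np.sqrt(2.0 * odor.diffusivity * dt)
    v_dt = odor.loss_rate * dt
    gap = (odor.reacq_factor - 1.0) * odor.c_tau
    mean_flight = gap / odor.loss_rate
    if mean_flight > duration_s:
        raise ValueError(
            "degenerate signal geometry: expected flight bout "
            f"({mean_flight:.0f} s) exceeds the simulated duration")
    rng = np.random.default_rng(seed)
    n_total = int(np.ceil(duration_s / dt))
    block = int(np.clip(4 * gap / max(v_dt, 1e-300), 64, 65536))
    flights, losts = [], []
    flying = bool(rng.random() < 0.5)
    starts_with_flight = flying
    remaining = n_total
    while remaining > 0:
        # the lost phase mirrors the flight: recovery drift +v toward the
        # upper band edge is, after reflection, drift -v toward -gap
        steps = _first_passage_steps(rng, gap, -v_dt, sigma, remaining, block)
        (flights if flying else losts).append(min(steps, remaining))
        remaining -= steps
        flying = not flying
    return (np.asarray(flights, dtype=float) * dt,
            np.asarray(losts, dtype=float) * dt,
            starts_with_flight)


def odor_segment_lengths(odor: OdorSignalParams, duration_s: float,
                         seed=None) -> np.ndarray:
    """Flight-segment lengths (km) from one signal realization.

    Segments shorter than 2 sim_dt are discretization artefacts and are
    discarded from the sample (they remain part of the flown path in
    :func:`gen_odor_walk`).
    """
    flights, _, _ = simulate_odor_phases(odor, duration_s, seed)
    flights = flights[flights >= 2.0 * odor.dt]
    if flights.size == 0:
        raise ValueError("no flight segments produced; signal below threshold throughout")
    return flights * odor.speed_km_s


def _resample_path(bound_t, bound_x, bound_y, fix_interval, duration_s):
    t_fix = np.arange(0.0, duration_s + 0.5 * fix_interval, fix_interval)
    t_fix = t_fix[t_fix <= bound_t[-1]]
    return t_fix, np.interp(t_fix, bound_t, bound_x), np.interp(t_fix, bound_t, bound_y)


def gen_odor_walk(odor: OdorSignalParams, duration_days: float, seed=None,
                  colony: tuple = DEFAULT_COLONY, traj_id: str = "odor",
                  start_time=np.datetime64("2015-06-01T00:00:00"),
                  fix_interval: float | None = FIX_INTERVAL_S,
                  bias: tuple | None = None, meta: dict | None = None) -> Trajectory:
    """Mechanistic odor-threshold trajectory, resampled to GPS fixes.

    The bird flies straight during each map-contact phase (heading
    uniform, or von Mises about a target bearing when ``bias=(bearing_deg,
    kappa)``), and drifts with one uniform heading per lost phase at the
    same speed.  ``fix_interval=None`` keeps the exact phase boundaries.
    """
    rng = np.random.default_rng(seed)
    duration_s = duration_days * 86400.0
    flights, losts, starts_with_flight = simulate_odor_phases(
        odor, duration_s, rng)
    phases = _interleave(flights, losts, starts_with_flight)
    n_ph = len(phases)
    if bias is None:
        headings = rng.uniform(0.0, 2 * np.pi, n_ph)
    else:
        bearing, kappa = np.radians(bias[0]), bias[1]
        headings = np.where(
            [is_flight for _, is_flight in phases],
            rng.vonmises(bearing, kappa, n_ph),
            rng.uniform(0.0, 2 * np.pi, n_ph),
        )
    dur = np.array([d for d, _ in phases])
    seg = dur * odor.speed_km_s
    bx = np.concatenate([[0.0], np.cumsum(seg * np.cos(headings))])
    by = np.concatenate([[0.0], np.cumsum(seg * np.sin(headings))])
    bt = np.concatenate([[0.0], np.cumsum(dur)])
    if fix_interval is not None:
        t, x, y = _resample_path(bt, bx, by, fix_interval, duration_s)
    else:
        t, x, y = bt, bx, by
    lat, lon = inverse_project(x, y, colony)
    times = np.asarray(start_time, dtype="datetime64[s]") + np.round(t).astype("timedelta64[s]")
    return Trajectory(id=traj_id, times=times, lat=lat, lon=lon, meta=meta or {})


def _interleave(flights, losts, starts_with_flight):
    phases = []
    fi = li = 0
    is_flight = starts_with_flight
    while fi < len(flights) or li < len(losts):
        if is_flight and fi < len(flights):
            phases.append((flights[fi], True)); fi += 1
        elif not is_flight and li < len(losts):
            phases.append((losts[li], False)); li += 1
        is_flight = not is_flight
    return phases


# ---------------------------------------------------------------------------
# direct BETPL walks (and generic step walks for null scenarios)


def _walk_from_steps(steps, headings, speed_km_s, fix_interval, colony,
                     traj_id, start_time, meta):
    bx = np.concatenate([[0.0], np.cumsum(steps * np.cos(headings))])
    by = np.concatenate([[0.0], np.cumsum(steps * np.sin(headings))])
    bt = np.concatenate([[0.0], np.cumsum(steps / speed_km_s)])
    if fix_interval is not None:
        t, x, y = _resample_path(bt, bx, by, fix_interval, bt[-1])
    else:
        t, x, y = bt, bx, by  # exact step endpoints
    lat, lon = inverse_project(x, y, colony)
    times = np.asarray(start_time, dtype="datetime64[s]") + np.ceil(t).astype("timedelta64[s]")
    # guard against duplicate timestamps after rounding
    tt = times.astype("int64")
    tt = np.maximum.accumulate(tt + (np.diff(tt, prepend=tt[0] - 1) <= 0))
    while np.any(np.diff(tt) <= 0):
        bad = np.flatnonzero(np.diff(tt) <= 0) + 1
        tt[bad] = tt[bad - 1] + 1
    return Trajectory(id=traj_id, times=tt.astype("datetime64[s]"),
                      lat=lat, lon=lon, meta=meta or {})


def gen_betpl_walk(params: BetplParams, n_steps: int, bias: tuple | None = None,
                   seed=None, colony: tuple = DEFAULT_COLONY,
                   flight_speed: float = 36.0,
                   fix_interval: float | None = None,
                   traj_id: str = "betpl",
                   start_time=np.datetime64("2015-06-01T00:00:00"),
                   meta: dict | None = None) -> Trajectory:
    """2-D walk with BETPL step lengths.

    Headings are uniform, or von Mises about a target bearing when
    ``bias=(bearing_deg, kappa)`` (birds may prefer a direction, e.g.
    toward the colony).  ``fix_interval`` in seconds resamples to a GPS
    cadence; None keeps exact step endpoints.
    """
    if n_steps < 1:
        raise ValueError("n_steps >= 1")
    rng = np.random.default_rng(seed)
    steps = betpl_sample(params, n_steps, seed=rng)
    if bias is None or bias[1] == 0:
        headings = rng.uniform(0.0, 2 * np.pi, n_steps)
    else:
        headings = rng.vonmises(np.radians(bias[0]), bias[1], n_steps)
    return _walk_from_steps(steps, headings, flight_speed / 3600.0, fix_interval,
                            colony, traj_id, start_time, meta)


def gen_steps_walk(steps: np.ndarray, seed=None, colony: tuple = DEFAULT_COLONY,
                   flight_speed: float = 36.0,
                   fix_interval: float | None = FIX_INTERVAL_S,
                   traj_id: str = "walk",
                   start_time=np.datetime64("2015-06-01T00:00:00"),
                   meta: dict | None = None) -> Trajectory:
    """Uniform-heading walk from externally supplied step lengths."""
    rng = np.random.default_rng(seed)
    headings = rng.uniform(0.0, 2 * np.pi, len(steps))
    return _walk_from_steps(np.asarray(steps, dtype=float), headings,
                            flight_speed / 3600.0, fix_interval, colony,
                            traj_id, start_time, meta)


# ---------------------------------------------------------------------------
# wind grids consistent with per-trajectory mean speeds


def gen_wind_grid(trajs, U_per_traj, seed=None, margin_deg: float = 1.5,
                  spatial_rel_amp: float | None = None) -> WindGrid:
    """0.5-degree / 6-hour wind grid covering all fixes.

    Within each trajectory's time window the field speed equals that
    trajectory's U (trajectories are assumed staggered in time); the
    direction wanders slowly.  A small smooth spatial modulation (zero
    when all U are equal) keeps the field non-trivial while holding the
    along-track mean within 5% of U.
    """
    rng = np.random.default_rng(seed)
    U = np.asarray(U_per_traj, dtype=float)
    lat_min = min(t.lat.min() for t in trajs) - margin_deg
    lat_max = max(t.lat.max() for t in trajs) + margin_deg
    lon_min = min(t.lon.min() for t in trajs) - margin_deg
    lon_max = max(t.lon.max() for t in trajs) + margin_deg
    lat = np.arange(np.floor(lat_min * 2) / 2, np.ceil(lat_max * 2) / 2 + 0.25, 0.5)
    lon = np.arange(np.floor(lon_min * 2) / 2, np.ceil(lon_max * 2) / 2 + 0.25, 0.5)
    t0 = min(t.times[0] for t in trajs) - np.timedelta64(6, "h")
    t1 = max(t.times[-1] for t in trajs) + np.timedelta64(6, "h")
    step = np.timedelta64(6, "h")
    time = np.arange(t0, t1 + step, step).astype("datetime64[s]")
    tf = time.astype("int64").astype(float)

    knots_t, knots_u = [], []
    for traj, u in zip(trajs, U):
        knots_t += [float(traj.times[0].astype("int64")) - 1.0,
                    float(traj.times[-1].astype("int64")) + 1.0]
        knots_u += [u, u]
    order = np.argsort(knots_t)
    node_speed = np.interp(tf, np.asarray(knots_t)[order], np.asarray(knots_u)[order])

    # slowly wandering direction
    phi = np.cumsum(rng.normal(0.0, 0.3, time.size)) + rng.uniform(0, 2 * np.pi)
    if spatial_rel_amp is None:
        spread = float(np.std(U) / np.mean(U)) if np.mean(U) > 0 else 0.0
        spatial_rel_amp = min(0.03, 0.2 * spread)
    glat, glon = np.meshgrid(lat, lon, indexing="ij")
    pert = spatial_rel_amp * np.sin(
        2 * np.pi * (glat - lat.min()) / max(np.ptp(lat), 1.0)
        + rng.uniform(0, 2 * np.pi)
    ) * np.cos(2 * np.pi * (glon - lon.min()) / max(np.ptp(lon), 1.0)
               + rng.uniform(0, 2 * np.pi))
    speed = node_speed[:, None, None] * (1.0 + pert[None, :, :])
    u = speed * np.cos(phi)[:, None, None]
    v = speed * np.sin(phi)[:, None, None]
    return WindGrid(time=time, lat=lat, lon=lon, u=u, v=v)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SyntheticCohort:
    """A full synthetic dataset: tracks, wind grid, truth table, metadata."""

    trajectories: list
    wind: WindGrid
    truth: pd.DataFrame
    meta: pd.DataFrame
    seed: int
    scenario: str = ""

    def to_dir(self, path) -> None:
        from .geometry import write_tracks
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_tracks(self.trajectories, path / "tracks.csv", path / "meta.csv")
        self.wind.to_csv(path / "wind.csv")
        self.truth.to_csv(path / "truth.csv", index=False)


SCENARIOS = ("wind_coupled", "wind_independent", "exponential_null",
             "biexponential_null")


def gen_cohort(n_traj: int, scenario: str = "wind_coupled", seed: int = 0,
               u_range=(2.0, 12.0), duration_range=(3.0, 8.0),
               gamma: float = 2.1, t_exp: float = 1.5,
               colony: tuple = DEFAULT_COLONY) -> SyntheticCohort:
    """Generate a cohort of trajectories plus a consistent wind grid.

    Scenarios: ``wind_coupled`` couples (T, C) to the per-trip wind speed
    U via the flux heuristic; ``wind_independent`` holds (T, C) at the
    reference values whatever U; ``exponential_null`` and
    ``biexponential_null`` draw step lengths from single- and two-scale
    exponentials for model-discrimination power tests.  Trips are
    staggered in time (12 h apart) so one wind field can carry every
    trip's U.
    """
    if n_traj < 2:
        raise ValueError("n_traj >= 2")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_traj + 1)
    rng = np.random.default_rng(child[-1])
    U = rng.uniform(*u_range, n_traj)
    durations = rng.uniform(*duration_range, n_traj)
    sexes = rng.choice(["male", "female"], n_traj)
    periods = rng.choice(["incubation", "chick-rearing"], n_traj)
    regions = rng.choice(["Atlantic", "Mediterranean"], n_traj)

    trajs, truth_rows, meta_rows = [], [], []
    t_cursor = np.datetime64("2015-06-01T00:00:00", "s")
    for i in range(n_traj):
        tid = f"{scenario[:4]}{i:03d}"
        t_rng = np.random.default_rng(child[i])
        row = {"id": tid, "U": U[i], "duration_days": durations[i],
               "scenario": scenario}
        if scenario in ("wind_coupled", "wind_independent"):
            if scenario == "wind_coupled":
                sc = WindScenario(U=U[i], gamma=gamma, t_exp=t_exp)
                odor = sc.odor_params()
            else:
                odor = OdorSignalParams()
            traj = gen_odor_walk(odor, durations[i], seed=t_rng, colony=colony,
                                 traj_id=tid, start_time=t_cursor)
            row.update(T=odor.T, C=odor.C, c_tau=odor.c_tau)
        elif scenario == "exponential_null":
            rate = t_rng.uniform(0.05, 0.15)  # mean step 7-20 km
            n_steps = max(60, int(durations[i] * 86400.0 * 0.01 * rate))
            steps = t_rng.exponential(1.0 / rate, n_steps)
            traj = gen_steps_walk(steps, seed=t_rng, colony=colony,
                                  traj_id=tid, start_time=t_cursor)
            row.update(rate=rate)
        else:  # biexponential_null
            r1, r2 = t_rng.uniform(0.02, 0.05), t_rng.uniform(0.3, 0.8)
            w = t_rng.uniform(0.3, 0.7)
            n_steps = 400
            pick = t_rng.random(n_steps) < w
            steps = np.where(pick, t_rng.exponential(1.0 / r1, n_steps),
                             t_rng.exponential(1.0 / r2, n_steps))
            traj = gen_steps_walk(steps, seed=t_rng, colony=colony,
                                  traj_id=tid, start_time=t_cursor)
            row.update(rate1=r1, rate2=r2, weight=w)
        traj.meta = {"species": "synthetic", "colony": "synthetic",
                     "sex": sexes[i], "period": periods[i], "region": regions[i]}
        trajs.append(traj)
        truth_rows.append(row)
        meta_rows.append({"id": tid, **traj.meta})
        t_cursor = traj.times[-1] + np.timedelta64(12, "h")

    wind = gen_wind_grid(trajs, U, seed=np.random.default_rng(ss.spawn(1)[0]))
    return SyntheticCohort(trajectories=trajs, wind=wind,
                           truth=pd.DataFrame(truth_rows),
                           meta=pd.DataFrame(meta_rows), seed=seed,
                           scenario=scenario)
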