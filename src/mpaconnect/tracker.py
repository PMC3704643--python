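"""Lagrangian transport of virtual larvae in daily gridded current fields.

The scheme follows the standard coastal larval-dispersal recipe: forward
Euler advection of passive particles with trilinearly interpolated daily-mean
velocities, a sub-grid random-walk horizontal diffusion whose coefficient
follows the Monin–Ozmidov scaling K_h = eps^(1/3) * l^(4/3), and coastal
boundary rules (loss at the open-domain edge, surface reflection, standstill
at the land interface). An optional diel vertical-migration behaviour forces
larvae to the surface at night and to 50 m during the day.

Positions are integrated with a time step bounded by cell size over maximum
current speed, so a particle never crosses more than one cell per step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from .geo import EARTH_RADIUS_M, METERS_PER_DEGREE
from .grids import GridSpec, MPASite, VelocityField, ValidationError

# particle status codes
ACTIVE = 0
LOST = 1
STANDSTILL = 2

STATUS_NAMES = {ACTIVE: "active", LOST: "lost", STANDSTILL: "standstill"}


class CoverageError(ValueError):
    """The velocity field does not cover the spawn window plus PLD."""


class ReleaseError(ValueError):
    """An MPA polygon has no sea area to release larvae from."""


@dataclass
class SimulationConfig:
    """Numerical and biological parameters of one dispersal simulation.

    Defaults are the grouper-like reference scenario: 30-day pelagic larval
    duration, 2 h time step, ten release events of 1000 larvae every three
    days from the 1st of the spawning month, release at 20 cm depth, daily
    position records, and turbulent dissipation eps = 1e-9 m^2 s^-3 feeding
    the Monin–Ozmidov diffusivity.
    """

    pld_days: float = 30.0
    dt_s: float = 7200.0
    record_interval_s: float = 86400.0
    epsilon: float = 1e-9
    kh: Optional[float] = None           # derived from epsilon and grid when None
    release_depth_m: float = 0.2
    vertical_migration: bool = False
    night_depth_m: float = 0.2
    day_depth_m: float = 50.0
    ascend_hour: float = 20.0
    descend_hour: float = 8.0
    spawn_start_date: str = "2000-08-01"
    n_events: int = 10
    event_interval_days: int = 3
    larvae_per_event: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.pld_days <= 0 or self.dt_s <= 0:
            raise ValidationError("pld_days and dt_s must be positive")
        if self.record_interval_s % self.dt_s != 0:
            raise ValidationError("record_interval_s must be a multiple of dt_s")
        if (self.pld_days * 86400.0) % self.dt_s != 0:
            raise ValidationError("pld_days * 86400 must be a multiple of dt_s")


@dataclass
class TrajectoryRecord:
    """Release/final state of every particle, plus optional daily positions."""

    source_mpa: np.ndarray       # (n,) MPA id per particle
    release_day: np.ndarray      # (n,) days since spawn start
    release_lon: np.ndarray
    release_lat: np.ndarray
    final_lon: np.ndarray
    final_lat: np.ndarray
    final_depth: np.ndarray
    status: np.ndarray           # (n,) ACTIVE / LOST / STANDSTILL at PLD end
    record_times_s: Optional[np.ndarray] = None   # (m,) seconds since spawn start
    traj_lon: Optional[np.ndarray] = None          # (m, n)
    traj_lat: Optional[np.ndarray] = None

    @property
    def n_particles(self) -> int:
        return len(self.source_mpa)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "particle_id": np.arange(self.n_particles),
            "source_mpa": self.source_mpa,
            "release_day": self.release_day,
            "release_lon": self.release_lon,
            "release_lat": self.release_lat,
            "final_lon": self.final_lon,
            "final_lat": self.final_lat,
            "final_depth": self.final_depth,
            "status": [STATUS_NAMES[s] for s in self.status],
        })

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "TrajectoryRecord":
        df = pd.read_csv(path)
        inv = {v: k for k, v in STATUS_NAMES.items()}
        return cls(source_mpa=df["source_mpa"].to_numpy(),
                   release_day=df["release_day"].to_numpy(),
                   release_lon=df["release_lon"].to_numpy(),
                   release_lat=df["release_lat"].to_numpy(),
                   final_lon=df["final_lon"].to_numpy(),
                   final_lat=df["final_lat"].to_numpy(),
                   final_depth=df["final_depth"].to_numpy(),
                   status=df["status"].map(inv).to_numpy())


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def choose_time_step(cell_length_m: float, max_speed_mps: float) -> float:
    """Admissible time-step bound: cell size over maximum current speed.

    A configured dt must not exceed this bound, so that a particle cannot
    cross more than one cell boundary per iteration.
    """
    if cell_length_m <= 0 or max_speed_mps <= 0:
        raise ValidationError("cell length and max speed must be positive")
    return cell_length_m / max_speed_mps


def horizontal_diffusivity(epsilon: float, cell_length_m: float) -> float:
    """Monin–Ozmidov Lagrangian horizontal diffusivity K_h = eps^(1/3) l^(4/3)."""
    if epsilon <= 0 or cell_length_m <= 0:
        raise ValidationError("epsilon and cell length must be positive")
    return epsilon ** (1.0 / 3.0) * cell_length_m ** (4.0 / 3.0)


def random_walk_velocity(kh: float, dt_s: float, rng: np.random.Generator, n: int = 1):
    """Random-walk velocity components u_r = delta * sqrt(2 K_h / dt).

    delta is uniform on [-1, 1], drawn independently for each horizontal
    component, so each component is bounded by sqrt(2 K_h / dt) and has
    variance (1/3) * 2 K_h / dt.
    """
    if kh < 0 or dt_s <= 0:
        raise ValidationError("kh must be >= 0 and dt > 0")
    scale = np.sqrt(2.0 * kh / dt_s)
    delta = rng.uniform(-1.0, 1.0, size=(2, n))
    return scale * delta[0], scale * delta[1]


def interpolate_velocity(field: VelocityField, grid: GridSpec,
                         lon, lat, depth, day_index: int):
    """Trilinear interpolation of (u, v, w) to particle positions.

    Interpolates in lon/lat/depth among the 8 surrounding nodes of the daily
    snapshot ``day_index``; land nodes contribute their stored zero velocity.
    Depths outside the level range use the nearest level (constant
    extrapolation). Vectorized over positions.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    depth = np.broadcast_to(np.atleast_1d(np.asarray(depth, dtype=float)), lon.shape)

    ax, ay, az = grid.lon_axis, grid.lat_axis, grid.depth_levels
    ix0, wx = _axis_locate(ax, lon)
    iy0, wy = _axis_locate(ay, lat)
    iz0, wz = _axis_locate(az, depth)
    ix1 = np.minimum(ix0 + 1, len(ax) - 1)
    iy1 = np.minimum(iy0 + 1, len(ay) - 1)
    iz1 = np.minimum(iz0 + 1, len(az) - 1)

    out = []
    for comp in (field.u, field.v, field.w):
        c = comp[day_index]
        val = np.zeros_like(lon)
        for iz, fz in ((iz0, 1 - wz), (iz1, wz)):
            for iy, fy in ((iy0, 1 - wy), (iy1, wy)):
                for ix, fx in ((ix0, 1 - wx), (ix1, wx)):
                    val += fz * fy * fx * c[iz, iy, ix]
        out.append(val)
    return tuple(out)


def _axis_locate(axis: np.ndarray, x: np.ndarray):
    """Bracketing lower index and linear weight along a monotone axis."""
    if len(axis) == 1:
        return np.zeros(x.shape, dtype=int), np.zeros_like(x, dtype=float)
    i = np.searchsorted(axis, x, side="right") - 1
    i0 = np.clip(i, 0, len(axis) - 2)
    w = (x - axis[i0]) / (axis[i0 + 1] - axis[i0])
    return i0, np.clip(w, 0.0, 1.0)


def advect_step(lon, lat, depth, u, v, w, dt_s: float):
    """Forward-Euler position update on the sphere; returns new (lon, lat, depth).

    The horizontal velocity (current + random-walk component) is converted to
    degrees with the local spherical metric; near-polar latitudes are
    rejected as a numerical guard.
    """
    lat = np.asarray(lat, dtype=float)
    coslat = np.cos(np.radians(lat))
    if np.any(coslat <= 0.01):
        raise ValidationError("advection poleward of +-89.4 degrees is not supported")
    dlat = np.degrees(np.asarray(v) * dt_s / EARTH_RADIUS_M)
    dlon = np.degrees(np.asarray(u) * dt_s / (EARTH_RADIUS_M * coslat))
    return np.asarray(lon) + dlon, lat + dlat, np.asarray(depth) + np.asarray(w) * dt_s


def apply_boundaries(prev_lon, prev_lat, new_lon, new_lat, new_depth,
                     status, grid: GridSpec):
    """Boundary rules applied to candidate post-advection positions.

    - outside the domain box -> LOST (excluded from further integration);
    - above the surface -> depth reflected back into the water column;
    - deeper than the deepest level midpoint -> clamped (bottom velocities
      are zero at layer midpoints, so this is a numerical guard only);
    - onto a land cell -> position reverted to the last sea position and the
      particle enters STANDSTILL: frozen in place, clock still running,
      still scoreable at settlement.

    Returns updated (lon, lat, depth, status) arrays.
    """
    lon = np.array(new_lon, dtype=float)
    lat = np.array(new_lat, dtype=float)
    depth = np.array(new_depth, dtype=float)
    status = np.array(status, dtype=int)

    lon_min, lat_min, lon_max, lat_max = grid.bbox
    lost = (lon < lon_min) | (lon > lon_max) | (lat < lat_min) | (lat > lat_max)
    status[lost] = LOST

    depth = np.abs(depth)  # surface reflection
    depth = np.minimum(depth, grid.depth_levels[-1])

    inside = ~lost
    if np.any(inside):
        onland = np.zeros_like(lost)
        onland[inside] = grid.is_land(lon[inside], lat[inside])
        lon[onland] = np.asarray(prev_lon, dtype=float)[onland]
        lat[onland] = np.asarray(prev_lat, dtype=float)[onland]
        status[onland & (status == ACTIVE)] = STANDSTILL
    return lon, lat, depth, status


def vertical_migration_step(depth, lon, lat, t_s: float, dt_s: float,
                            cfg: SimulationConfig, grid: GridSpec):
    """Force diel ascent/descent when the clock crosses the trigger hours.

    At the ascent hour (default 20:00) depth is set to the night depth
    (0.2 m); at the descent hour (default 08:00) to the day depth (50 m),
    capped above the local seafloor at the deepest admissible level midpoint.
    ``t_s`` is seconds since local midnight of the simulation origin.
    """
    if not cfg.vertical_migration:
        return np.asarray(depth, dtype=float)
    depth = np.array(depth, dtype=float)
    if _crosses_hour(t_s, dt_s, cfg.ascend_hour):
        depth[:] = cfg.night_depth_m
    if _crosses_hour(t_s, dt_s, cfg.descend_hour):
        bathy = grid.bathymetry_at(lon, lat)
        depth[:] = np.minimum(cfg.day_depth_m, _deepest_level_above(grid, bathy))
    return depth


def _crosses_hour(t_s: float, dt_s: float, hour: float) -> bool:
    trig = hour * 3600.0
    return np.floor((t_s + dt_s - trig) / 86400.0) > np.floor((t_s - trig) / 86400.0)


def _deepest_level_above(grid: GridSpec, bathy):
    """Deepest level midpoint shallower than the local seafloor."""
    levels = grid.depth_levels
    idx = np.searchsorted(levels, np.asarray(bathy, dtype=float), side="left") - 1
    idx = np.clip(idx, 0, len(levels) - 1)
    return levels[idx]


# ---------------------------------------------------------------------------
# Release and integration
# ---------------------------------------------------------------------------

def release_cohort(mpas: Sequence[MPASite], cfg: SimulationConfig,
                   grid: GridSpec, rng: np.random.Generator):
    """Release particles for every MPA and spawning event.

    For each MPA and each of the ``n_events`` events (days 0, 3, ..., 27 of
    the spawning month by default), ``larvae_per_event`` particles are placed
    at uniform-random sea points inside the polygon at the release depth.

    Returns dict of arrays: source (MPA id), release_day, lon, lat, depth.
    """
    src, day, lons, lats = [], [], [], []
    for m in mpas:
        pts = _sample_polygon_sea(m, grid, cfg.larvae_per_event * cfg.n_events, rng)
        for e in range(cfg.n_events):
            s = slice(e * cfg.larvae_per_event, (e + 1) * cfg.larvae_per_event)
            src.append(np.full(cfg.larvae_per_event, m.id))
            day.append(np.full(cfg.larvae_per_event, e * cfg.event_interval_days))
            lons.append(pts[0][s])
            lats.append(pts[1][s])
    return {
        "source": np.concatenate(src),
        "release_day": np.concatenate(day),
        "lon": np.concatenate(lons),
        "lat": np.concatenate(lats),
        "depth": np.full(sum(len(a) for a in src), cfg.release_depth_m, dtype=float),
    }


def _sample_polygon_sea(mpa: MPASite, grid: GridSpec, n: int,
                        rng: np.random.Generator, max_tries: int = 200):
    minx, miny, maxx, maxy = mpa.polygon.bounds
    out_lon = np.empty(0)
    out_lat = np.empty(0)
    for _ in range(max_tries):
        m = max(4 * n, 256)
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        ok = shapely.intersects_xy(mpa.polygon, cx, cy)
        ok &= ~grid.is_land(cx, cy)
        out_lon = np.concatenate([out_lon, cx[ok]])
        out_lat = np.concatenate([out_lat, cy[ok]])
        if len(out_lon) >= n:
            return out_lon[:n], out_lat[:n]
    raise ReleaseError(f"MPA {mpa.name} (id {mpa.id}) overlaps no sea cells")


def run_simulation(field: VelocityField, grid: GridSpec,
                   mpas: Sequence[MPASite], cfg: SimulationConfig,
                   record_trajectories: bool = False) -> TrajectoryRecord:
    """Integrate every released particle for exactly the pelagic larval
    duration and return final positions for settlement scoring.

    Deterministic for a given ``cfg.seed``. Raises :class:`CoverageError`
    when the field is shorter than the spawn window plus PLD, and
    :class:`ValidationError` when dt exceeds the admissibility bound.
    """
    field.validate_against(grid)
    vmax = field.max_speed()
    if vmax > 0 and cfg.dt_s > choose_time_step(grid.cell_length_m, vmax):
        raise ValidationError(
            f"dt = {cfg.dt_s} s exceeds the admissible bound "
            f"{grid.cell_length_m / vmax:.0f} s (cell / max speed)")
    kh = cfg.kh if cfg.kh is not None else horizontal_diffusivity(cfg.epsilon, grid.cell_length_m)

    start = np.datetime64(cfg.spawn_start_date, "ns")
    offset_d = (start - field.times[0]) / np.timedelta64(1, "D")
    last_event_d = (cfg.n_events - 1) * cfg.event_interval_days
    need_days = offset_d + last_event_d + cfg.pld_days
    if offset_d < 0 or need_days > field.n_days:
        raise CoverageError(
            f"field covers {field.n_days} d from {field.times[0]}, "
            f"needs {need_days:.0f} d for spawn window + PLD")

    rng = np.random.default_rng(cfg.seed)
    cohort = release_cohort(mpas, cfg, grid, rng)
    n = len(cohort["source"])
    lon = cohort["lon"].copy()
    lat = cohort["lat"].copy()
    depth = cohort["depth"].copy()
    status = np.full(n, ACTIVE, dtype=int)
    release_t = cohort["release_day"] * 86400.0
    pld_s = cfg.pld_days * 86400.0

    t_end = last_event_d * 86400.0 + pld_s
    n_steps = int(round(t_end / cfg.dt_s))
    rec_every = int(cfg.record_interval_s // cfg.dt_s)
    rec_t, rec_lon, rec_lat = [], [], []
    if record_trajectories:
        rec_t.append(0.0)
        rec_lon.append(lon.copy())
        rec_lat.append(lat.copy())

    for step in range(n_steps):
        t = step * cfg.dt_s  # seconds since spawn start (midnight)
        live = (status == ACTIVE) & (release_t <= t) & (t < release_t + pld_s)
        if np.any(live):
            if cfg.vertical_migration:
                depth[live] = vertical_migration_step(
                    depth[live], lon[live], lat[live], t, cfg.dt_s, cfg, grid)
            day_idx = int((offset_d * 86400.0 + t) // 86400.0)
            u, v, w = interpolate_velocity(field, grid, lon[live], lat[live],
                                           depth[live], day_idx)
            ur, vr = random_walk_velocity(kh, cfg.dt_s, rng, n=int(live.sum()))
            nlon, nlat, ndep = advect_step(lon[live], lat[live], depth[live],
                                           u + ur, v + vr, w, cfg.dt_s)
            lon[live], lat[live], depth[live], status[live] = apply_boundaries(
                lon[live], lat[live], nlon, nlat, ndep, status[live], grid)
        if record_trajectories and (step + 1) % rec_every == 0:
            rec_t.append((step + 1) * cfg.dt_s)
            rec_lon.append(lon.copy())
            rec_lat.append(lat.copy())
        # particle conservation at every step boundary
        assert np.isin(status, (ACTIVE, LOST, STANDSTILL)).all()

    return TrajectoryRecord(
        source_mpa=cohort["source"],
        release_day=cohort["release_day"],
        release_lon=cohort["lon"],
        release_lat=cohort["lat"],
        final_lon=lon, final_lat=lat, final_depth=depth, status=status,
        record_times_s=np.asarray(rec_t) if record_trajectories else None,
        traj_lon=np.asarray(rec_lon) if record_trajectories else None,
        traj_lat=np.asarray(rec_lat) if record_trajectories else None,
    )
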