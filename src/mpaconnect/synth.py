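"""Synthetic study domains: current fields, coastline, bathymetry and MPAs.

Stand-in for eddy-resolving regional ocean model output (daily-mean, ~1/12
degree, vertically layered, land-masked) and for a digitized coastal MPA
layer. Four elementary flow kinds are provided; realistic basin circulation
(a coastal boundary current over meso-scale gyres, surface-intensified and
weakening through late summer) is composed by summing fields with
:func:`add_fields` or via :func:`demo_study_domain`.

The double-gyre field is derived from a streamfunction by centered
differences, so its discrete divergence vanishes identically in the sea
interior — the property particle-conservation tests rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .geo import METERS_PER_DEGREE
from .grids import GridSpec, MPASite, VelocityField, ValidationError


class PlacementError(ValueError):
    """An MPA polygon could not be placed over sea cells."""


FLOW_KINDS = ("uniform", "solid_rotation", "double_gyre", "boundary_jet")


@dataclass
class SyntheticDomainConfig:
    """Configuration of a synthetic Mediterranean-like domain.

    The defaults describe a coastal band along the northern edge, a
    continental shelf (< 200 m) of configurable width, and rectangular MPAs
    placed mid-shelf.
    """

    lon_min: float = 0.0
    lon_max: float = 10.0
    lat_min: float = 40.0
    lat_max: float = 44.0
    resolution_deg: float = 1.0 / 12.0
    depth_levels: tuple = (0.5, 5.0, 15.0, 30.0, 60.0, 120.0, 300.0, 800.0)

    flow_kind: str = "double_gyre"
    flow_amplitude_ms: float = 0.15      # peak horizontal speed
    flow_direction_deg: float = 90.0     # uniform flow: compass-like, 90 = eastward
    rotation_period_days: float = 30.0   # solid rotation
    n_gyres: int = 2                     # double gyre: zonal cell count
    gyre_lat_band: Optional[tuple] = None  # (lat0, lat1) confining the gyres
    gyre_drift_period_days: Optional[float] = None  # eastward phase translation
    jet_width_km: float = 35.0           # boundary jet e-folding width
    jet_direction: float = -1.0          # -1 = westward along a northern coast
    vertical_decay_m: Optional[float] = None  # exp depth decay scale; None = barotropic
    seasonal_trend_per_day: float = 0.0  # fractional amplitude change per day

    coast_edge: str = "north"
    coast_width_deg: float = 0.375
    shelf_width_km: float = 40.0
    slope_width_km: float = 60.0
    max_depth_m: float = 2500.0

    n_mpas: int = 12
    mpa_size_deg: tuple = (0.25, 0.125)  # (lon, lat) extent
    mpa_spacing_km: Optional[float] = None  # None = spread evenly along coast
    mpa_band_lon: Optional[tuple] = None    # (lon_min, lon_max) placement band
    mpa_centers_lon: Optional[tuple] = None  # explicit center longitudes
    mpa_coast_offset_deg: Optional[float] = None  # center distance off the coast
    seed: int = 0

    def __post_init__(self):
        if self.flow_kind not in FLOW_KINDS:
            raise ValidationError(f"flow_kind must be one of {FLOW_KINDS}")
        if self.coast_edge not in ("north", "south"):
            raise ValidationError("coast_edge must be 'north' or 'south'")
        nsea_lat = (self.lat_max - self.lat_min - self.coast_width_deg) / self.resolution_deg
        nsea_lon = (self.lon_max - self.lon_min) / self.resolution_deg
        if nsea_lat < 10 or nsea_lon < 10:
            raise ValidationError("resolution must yield at least 10x10 sea cells")


# ---------------------------------------------------------------------------
# Coastline, bathymetry and MPA placement
# ---------------------------------------------------------------------------

def synth_coast_and_mpas(cfg: SyntheticDomainConfig):
    """Build the grid (land band + shelf bathymetry) and the MPA polygons.

    Returns ``(grid, mpas)``. Bathymetry ramps linearly from the coast to
    200 m across the shelf, then to ``max_depth_m`` across the slope. Cells
    adjacent to land keep a shallow nearshore depth even at zero shelf width.
    """
    res = cfg.resolution_deg
    lon = np.arange(cfg.lon_min + res / 2, cfg.lon_max, res)
    lat = np.arange(cfg.lat_min + res / 2, cfg.lat_max, res)
    nlat, nlon = len(lat), len(lon)

    if cfg.coast_edge == "north":
        coast_lat = cfg.lat_max - cfg.coast_width_deg
        land = np.broadcast_to((lat >= coast_lat)[:, None], (nlat, nlon)).copy()
        dist_deg = coast_lat - lat  # positive offshore
    else:
        coast_lat = cfg.lat_min + cfg.coast_width_deg
        land = np.broadcast_to((lat <= coast_lat)[:, None], (nlat, nlon)).copy()
        dist_deg = lat - coast_lat

    km_per_deg_lat = METERS_PER_DEGREE / 1000.0
    d_km = np.maximum(0.0, dist_deg) * km_per_deg_lat
    bathy_1d = np.empty(nlat)
    for i, d in enumerate(d_km):
        if cfg.shelf_width_km > 0 and d <= cfg.shelf_width_km:
            b = 200.0 * d / cfg.shelf_width_km
        else:
            b = 200.0 + (d - cfg.shelf_width_km) * (cfg.max_depth_m - 200.0) / cfg.slope_width_km
        bathy_1d[i] = min(cfg.max_depth_m, b)
    bathy = np.broadcast_to(bathy_1d[:, None], (nlat, nlon)).copy()
    bathy[land] = 0.0
    # nearshore ring stays shallow (sea cells bordering land)
    sea = ~land
    ring = sea & _adjacent_to(land)
    bathy[ring] = np.minimum(np.where(bathy[ring] > 0, bathy[ring], 100.0), 100.0)
    bathy[sea] = np.maximum(bathy[sea], 5.0)

    grid = GridSpec(lon_axis=lon, lat_axis=lat,
                    depth_levels=np.asarray(cfg.depth_levels, dtype=float),
                    land_mask=land, bathymetry_m=bathy)
    mpas = _place_mpas(cfg, grid, coast_lat)
    return grid, mpas


def _adjacent_to(mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    out[:-1, :] |= mask[1:, :]
    out[1:, :] |= mask[:-1, :]
    out[:, :-1] |= mask[:, 1:]
    out[:, 1:] |= mask[:, :-1]
    return out


def _place_mpas(cfg: SyntheticDomainConfig, grid: GridSpec, coast_lat: float):
    wlon, wlat = cfg.mpa_size_deg
    # coastal center latitude (mid-shelf unless an explicit offset is given)
    shelf_deg = cfg.shelf_width_km / (METERS_PER_DEGREE / 1000.0)
    offset = cfg.mpa_coast_offset_deg
    if offset is None:
        offset = max(shelf_deg / 2.0, cfg.resolution_deg + wlat)
    if cfg.coast_edge == "north":
        clat = coast_lat - offset
    else:
        clat = coast_lat + offset
    margin = 0.5 + wlon / 2.0
    band_lo, band_hi = cfg.mpa_band_lon or (cfg.lon_min + margin, cfg.lon_max - margin)
    if cfg.mpa_centers_lon is not None:
        if len(cfg.mpa_centers_lon) != cfg.n_mpas:
            raise ValidationError("mpa_centers_lon must list n_mpas longitudes")
        centers = np.asarray(cfg.mpa_centers_lon, dtype=float)
    elif cfg.mpa_spacing_km is not None:
        km_per_deg_lon = METERS_PER_DEGREE / 1000.0 * np.cos(np.radians(clat))
        spacing_deg = cfg.mpa_spacing_km / km_per_deg_lon
        centers = band_lo + spacing_deg * np.arange(cfg.n_mpas)
        if centers[-1] > band_hi:
            raise PlacementError("MPAs at the requested spacing do not fit the domain")
    elif cfg.n_mpas == 1:
        centers = np.array([(band_lo + band_hi) / 2.0])
    else:
        centers = np.linspace(band_lo, band_hi, cfg.n_mpas)
        if centers[1] - centers[0] < wlon:
            raise PlacementError("too many MPAs for the domain width")
    mpas = []
    for k, cx in enumerate(centers, start=1):
        ring = np.array([
            [cx - wlon / 2, clat - wlat / 2],
            [cx + wlon / 2, clat - wlat / 2],
            [cx + wlon / 2, clat + wlat / 2],
            [cx - wlon / 2, clat + wlat / 2],
            [cx - wlon / 2, clat - wlat / 2],
        ])
        area = _rect_area_km2(cx, clat, wlon, wlat)
        site = MPASite(id=k, name=f"MPA-{k:03d}", ring=ring, area_km2=area)
        iy, ix = grid.cell_index(*site.centroid)
        if grid.land_mask[iy, ix]:
            raise PlacementError(f"MPA {site.name} lies over land")
        mpas.append(site)
    return mpas


def _rect_area_km2(clon, clat, wlon, wlat) -> float:
    km_per_deg = METERS_PER_DEGREE / 1000.0
    return float(wlon * km_per_deg * np.cos(np.radians(clat)) * wlat * km_per_deg)


# ---------------------------------------------------------------------------
# Flow fields
# ---------------------------------------------------------------------------

def synth_flow(cfg: SyntheticDomainConfig, grid: GridSpec, n_days: int,
               start_date="2000-08-01") -> VelocityField:
    """Generate ``n_days`` of daily-mean currents of ``cfg.flow_kind``.

    All kinds return w = 0 and zero velocity on land. The amplitude is
    modulated by the (optional) seasonal linear trend, and decays with depth
    as ``exp(-z / vertical_decay_m)`` when a decay scale is set.
    """
    if cfg.flow_amplitude_ms > 2.0:
        warnings.warn("flow amplitude exceeds 2 m/s: unrealistic for basin currents")
    times = np.datetime64(start_date, "D") + np.arange(n_days)
    nlat, nlon, nz = grid.nlat, grid.nlon, grid.ndepth
    lon2, lat2 = np.meshgrid(grid.lon_axis, grid.lat_axis)
    mid_lat = 0.5 * (grid.lat_axis[0] + grid.lat_axis[-1])
    # local planar coordinates (m)
    x = (lon2 - grid.lon_axis[0]) * METERS_PER_DEGREE * np.cos(np.radians(mid_lat))
    y = (lat2 - grid.lat_axis[0]) * METERS_PER_DEGREE

    u = np.zeros((n_days, nz, nlat, nlon))
    v = np.zeros_like(u)
    for d in range(n_days):
        us, vs = _surface_flow(cfg, grid, x, y, day=d)
        amp_t = 1.0 + cfg.seasonal_trend_per_day * d
        us, vs = us * amp_t, vs * amp_t
        for k, z in enumerate(grid.depth_levels):
            decay = 1.0 if cfg.vertical_decay_m is None else float(np.exp(-z / cfg.vertical_decay_m))
            u[d, k] = us * decay
            v[d, k] = vs * decay
    u[:, :, grid.land_mask] = 0.0
    v[:, :, grid.land_mask] = 0.0
    w = np.zeros_like(u)
    return VelocityField(times=times.astype("datetime64[ns]"), u=u, v=v, w=w)


def _surface_flow(cfg: SyntheticDomainConfig, grid: GridSpec, x, y, day: int):
    A = cfg.flow_amplitude_ms
    if cfg.flow_kind == "uniform":
        theta = np.radians(cfg.flow_direction_deg)
        ue, vn = np.sin(theta), np.cos(theta)
        ue = 0.0 if abs(ue) < 1e-14 else ue
        vn = 0.0 if abs(vn) < 1e-14 else vn
        return (A * ue * np.ones_like(x), A * vn * np.ones_like(x))
    if cfg.flow_kind == "solid_rotation":
        omega = 2.0 * np.pi / (cfg.rotation_period_days * 86400.0)
        xc, yc = x.mean(), y.mean()
        return (-omega * (y - yc), omega * (x - xc))
    if cfg.flow_kind == "double_gyre":
        return _gyre_flow(cfg, grid, x, y, day)
    if cfg.flow_kind == "boundary_jet":
        sea_lat = grid.lat_axis[~np.all(grid.land_mask, axis=1)]
        if cfg.coast_edge == "north":
            coast_y = (sea_lat[-1] - grid.lat_axis[0]) * METERS_PER_DEGREE
            dist = coast_y - y
        else:
            coast_y = (sea_lat[0] - grid.lat_axis[0]) * METERS_PER_DEGREE
            dist = y - coast_y
        dist = np.maximum(0.0, dist)
        jet = A * np.exp(-(dist / (cfg.jet_width_km * 1000.0)) ** 2)
        return (cfg.jet_direction * jet, np.zeros_like(jet))
    raise ValidationError(f"unknown flow kind {cfg.flow_kind}")


def _gyre_flow(cfg: SyntheticDomainConfig, grid: GridSpec, x, y, day: int):
    """Gyres from a streamfunction, discretely non-divergent.

    psi = Apsi * sin(n pi (x - phase)/Lx) * sin(pi y'/Ly) over the sea box;
    u = -d(psi)/dy, v = d(psi)/dx by centered differences, so the centered
    discrete divergence cancels exactly in the interior.
    """
    sea_rows = ~np.all(grid.land_mask, axis=1)
    ys = y[sea_rows, 0]
    y0, y1 = ys.min(), ys.max()
    if cfg.gyre_lat_band is not None:
        b0, b1 = cfg.gyre_lat_band
        y0 = (b0 - grid.lat_axis[0]) * METERS_PER_DEGREE
        y1 = (b1 - grid.lat_axis[0]) * METERS_PER_DEGREE
    Ly = max(y1 - y0, 1.0)
    Lx = max(x.max() - x.min(), 1.0)
    phase = 0.0
    if cfg.gyre_drift_period_days:
        phase = (day / cfg.gyre_drift_period_days) * Lx / cfg.n_gyres
    # scale so that peak |u| ~= amplitude
    Apsi = cfg.flow_amplitude_ms * Ly / np.pi
    yy = np.clip(y - y0, 0.0, Ly)
    psi = Apsi * np.sin(cfg.n_gyres * np.pi * (x - phase) / Lx) * np.sin(np.pi * yy / Ly)
    psi[~sea_rows, :] = 0.0
    u = -_centered_d(psi, axis=0) / _centered_d(y, axis=0)
    v = _centered_d(psi, axis=1) / _centered_d(x, axis=1)
    return u, v


def _centered_d(f: np.ndarray, axis: int) -> np.ndarray:
    """Centered difference, one-sided at the edges (same shape as f)."""
    out = np.empty_like(f, dtype=float)
    sl = [slice(None)] * f.ndim

    def at(i):
        s = sl.copy()
        s[axis] = i
        return tuple(s)

    out[at(slice(1, -1))] = f[at(slice(2, None))] - f[at(slice(None, -2))]
    out[at(0)] = 2.0 * (f[at(1)] - f[at(0)])
    out[at(-1)] = 2.0 * (f[at(-1)] - f[at(-2)])
    return out / 2.0


def add_fields(*fields: VelocityField) -> VelocityField:
    """Sum velocity fields defined on the same grid and times."""
    base = fields[0]
    for f in fields[1:]:
        if f.u.shape != base.u.shape or not np.array_equal(f.times, base.times):
            raise ValidationError("fields to add must share shape and times")
    return VelocityField(times=base.times,
                         u=sum(f.u for f in fields),
                         v=sum(f.v for f in fields),
                         w=sum(f.w for f in fields))


# ---------------------------------------------------------------------------
# The packaged study domain
# ---------------------------------------------------------------------------

#: three groups of four coastal MPAs on the eastern shelf, ~29 km apart
#: within groups and ~85 km between groups, leaving a long MPA-free
#: downstream (western) shelf
DEMO_MPA_CENTERS = (3.9, 4.25, 4.6, 4.95, 6.0, 6.35, 6.7, 7.05,
                    8.1, 8.45, 8.8, 9.15)


def demo_study_domain(n_days: int = 120, start_date: str = "2000-07-01",
                      resolution_deg: float = 1.0 / 12.0, n_mpas: int = 12,
                      seed: int = 0):
    """The package's standard synthetic study system.

    A 10 x 4 degree Mediterranean-like basin with a northern coast, at the
    1/12-degree resolution of eddy-resolving regional ocean models: two
    counter-rotating, slowly propagating offshore gyres (0.15 m/s — the
    meso-scale eddy field, confined south of the shelf break) under a weak
    westward coastal boundary current (0.05 m/s, 35 km wide — the
    along-slope mean drift), both surface-intensified (75 m e-folding) and
    weakening by 0.3 %/day through late summer. A 40 km shelf runs along
    the whole coast; the 12 small (~65 km^2) MPAs sit near the coast in
    three groups on the eastern shelf, so a large downstream shelf carries
    no MPAs — the analogue of the sparsely protected southern basins.

    Returns ``(grid, mpas, field, cfg_gyre)``.
    """
    base = dict(lon_min=0.0, lon_max=10.0, lat_min=40.0, lat_max=44.0,
                resolution_deg=resolution_deg, n_mpas=n_mpas, seed=seed,
                shelf_width_km=40.0, vertical_decay_m=75.0,
                seasonal_trend_per_day=-0.003, gyre_drift_period_days=90.0,
                mpa_size_deg=(0.12, 0.08), gyre_lat_band=(40.0, 43.45),
                mpa_centers_lon=DEMO_MPA_CENTERS if n_mpas == 12 else None)
    cfg_gyre = SyntheticDomainConfig(flow_kind="double_gyre",
                                     flow_amplitude_ms=0.15, n_gyres=2, **base)
    cfg_jet = SyntheticDomainConfig(flow_kind="boundary_jet",
                                    flow_amplitude_ms=0.05, **base)
    grid, mpas = synth_coast_and_mpas(cfg_gyre)
    gyres = synth_flow(cfg_gyre, grid, n_days, start_date)
    jet = synth_flow(cfg_jet, grid, n_days, start_date)
    return grid, mpas, add_fields(gyres, jet), cfg_gyre
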