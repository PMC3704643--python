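import numpy as np
import pytest

from mpaconnect.grids import GridSpec, MPASite, VelocityField
from mpaconnect.synth import SyntheticDomainConfig, synth_coast_and_mpas, synth_flow


def make_grid(lon0=0.0, lon1=10.0, lat0=40.0, lat1=44.0, res=0.25,
              depths=(0.5, 10.0, 50.0, 200.0), bathy=1000.0, land_rows=0):
    """All-sea (or north-land-band) regular grid for unit tests."""
    lon = np.arange(lon0 + res / 2, lon1, res)
    lat = np.arange(lat0 + res / 2, lat1, res)
    land = np.zeros((len(lat), len(lon)), dtype=bool)
    if land_rows:
        land[-land_rows:, :] = True
    b = np.full((len(lat), len(lon)), float(bathy))
    b[land] = 0.0
    return GridSpec(lon_axis=lon, lat_axis=lat,
                    depth_levels=np.asarray(depths, dtype=float),
                    land_mask=land, bathymetry_m=b)


def uniform_field(grid, n_days=40, u=0.1, v=0.0, start="2000-08-01"):
    times = (np.datetime64(start, "D") + np.arange(n_days)).astype("datetime64[ns]")
    shape = (n_days, grid.ndepth, grid.nlat, grid.nlon)
    uu = np.full(shape, float(u))
    vv = np.full(shape, float(v))
    uu[:, :, grid.land_mask] = 0.0
    vv[:, :, grid.land_mask] = 0.0
    return VelocityField(times=times, u=uu, v=vv, w=np.zeros(shape))


def square_mpa(mid, clon, clat, half=0.1, area=100.0):
    ring = np.array([[clon - half, clat - half], [clon + half, clat - half],
                     [clon + half, clat + half], [clon - half, clat + half],
                     [clon - half, clat - half]])
    return MPASite(id=mid, name=f"M{mid}", ring=ring, area_km2=area)


@pytest.fixture
def sea_grid():
    return make_grid()


@pytest.fixture
def coastal_cfg():
    """Small, fast synthetic coastal domain configuration."""
    return SyntheticDomainConfig(lon_min=0.0, lon_max=8.0, lat_min=40.0,
                                 lat_max=44.0, resolution_deg=0.25,
                                 n_mpas=4, shelf_width_km=40.0)


@pytest.fixture
def coastal_domain(coastal_cfg):
    grid, mpas = synth_coast_and_mpas(coastal_cfg)
    return grid, mpas
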