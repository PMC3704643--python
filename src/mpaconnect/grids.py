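"""Domain types for gridded current fields and MPA polygons, with NetCDF and
GeoJSON input/output.

The grid is a regular lon/lat/depth box: cell centers in degrees east/north,
depth-level centers in meters positive down. A boolean land mask and a
bathymetry field live on the horizontal grid. Velocity fields are daily-mean
snapshots of (u, v, w) in m/s on (time, depth, lat, lon), zero on land cells
so that interpolation decays smoothly toward the coast and the coastal
standstill rule of the tracker works.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import xarray as xr
import shapely
from shapely.geometry import Polygon, shape, mapping

from .geo import METERS_PER_DEGREE, haversine_km


class FormatError(ValueError):
    """A file does not have the expected dimensions/variables."""


class ValidationError(ValueError):
    """Inputs violate a structural invariant."""


@dataclass
class GridSpec:
    """Regular lon/lat/depth grid with land mask and bathymetry.

    Parameters
    ----------
    lon_axis, lat_axis : 1-D arrays of cell-center coordinates, strictly
        increasing, degrees east / north.
    depth_levels : 1-D array of layer-midpoint depths in meters, positive
        down, strictly increasing.
    land_mask : bool array (nlat, nlon); True marks land.
    bathymetry_m : float array (nlat, nlon); seafloor depth on sea cells,
        0 on land.
    cell_length_m : representative horizontal cell width l (m). If omitted it
        is computed from the longitude spacing at the domain mid-latitude.
    """

    lon_axis: np.ndarray
    lat_axis: np.ndarray
    depth_levels: np.ndarray
    land_mask: np.ndarray
    bathymetry_m: np.ndarray
    cell_length_m: Optional[float] = None

    def __post_init__(self):
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.depth_levels = np.asarray(self.depth_levels, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        self.bathymetry_m = np.asarray(self.bathymetry_m, dtype=float)
        for name, ax in (("lon_axis", self.lon_axis), ("lat_axis", self.lat_axis),
                         ("depth_levels", self.depth_levels)):
            if ax.ndim != 1 or len(ax) < 1:
                raise ValidationError(f"{name} must be a non-empty 1-D array")
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValidationError(f"{name} must be strictly increasing")
        shp = (len(self.lat_axis), len(self.lon_axis))
        if self.land_mask.shape != shp or self.bathymetry_m.shape != shp:
            raise ValidationError("land_mask/bathymetry shape must be (nlat, nlon)")
        sea = ~self.land_mask
        if np.any(self.bathymetry_m[sea] <= 0):
            raise ValidationError("bathymetry must be > 0 on sea cells")
        if self.cell_length_m is None:
            mid = 0.5 * (self.lat_axis[0] + self.lat_axis[-1])
            dlon = float(np.mean(np.diff(self.lon_axis))) if len(self.lon_axis) > 1 else 1.0
            self.cell_length_m = float(dlon * METERS_PER_DEGREE * np.cos(np.radians(mid)))
        if self.cell_length_m <= 0:
            raise ValidationError("cell_length_m must be > 0")

    # -- geometry helpers -------------------------------------------------

    @property
    def nlon(self) -> int:
        return len(self.lon_axis)

    @property
    def nlat(self) -> int:
        return len(self.lat_axis)

    @property
    def ndepth(self) -> int:
        return len(self.depth_levels)

    @property
    def lon_edges(self) -> np.ndarray:
        from .geo import _edges
        return _edges(self.lon_axis)

    @property
    def lat_edges(self) -> np.ndarray:
        from .geo import _edges
        return _edges(self.lat_axis)

    @property
    def bbox(self):
        """(lon_min, lat_min, lon_max, lat_max) of cell edges."""
        le, te = self.lon_edges, self.lat_edges
        return (le[0], te[0], le[-1], te[-1])

    def cell_index(self, lon, lat):
        """(iy, ix) of the cell containing each point; clipped to the grid."""
        ix = np.searchsorted(self.lon_edges, np.asarray(lon, dtype=float), side="right") - 1
        iy = np.searchsorted(self.lat_edges, np.asarray(lat, dtype=float), side="right") - 1
        return (np.clip(iy, 0, self.nlat - 1), np.clip(ix, 0, self.nlon - 1))

    def is_land(self, lon, lat):
        iy, ix = self.cell_index(lon, lat)
        return self.land_mask[iy, ix]

    def bathymetry_at(self, lon, lat):
        iy, ix = self.cell_index(lon, lat)
        return self.bathymetry_m[iy, ix]


@dataclass
class VelocityField:
    """Daily-mean 3-D currents: u, v, w (m/s) on (time, depth, lat, lon)."""

    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        for name in ("u", "v", "w"):
            arr = np.asarray(getattr(self, name))
            setattr(self, name, arr)
            if arr.ndim != 4:
                raise ValidationError(f"{name} must be 4-D (time, depth, lat, lon)")
            if arr.shape[0] != len(self.times):
                raise ValidationError(f"{name} time axis mismatch")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
        if not (self.u.shape == self.v.shape == self.w.shape):
            raise ValidationError("u, v, w must share one shape")
        if len(self.times) > 1:
            d = np.diff(self.times).astype("timedelta64[s]").astype(int)
            if not np.all(d == 86400):
                raise ValidationError("times must be one snapshot per day")

    @property
    def n_days(self) -> int:
        return len(self.times)

    def max_speed(self) -> float:
        return float(np.sqrt(self.u.astype(float) ** 2 + self.v.astype(float) ** 2).max())

    def validate_against(self, grid: GridSpec) -> None:
        exp = (len(self.times), grid.ndepth, grid.nlat, grid.nlon)
        if self.u.shape != exp:
            raise ValidationError(f"field shape {self.u.shape} != grid shape {exp}")
        if np.any(self.u[:, :, grid.land_mask] != 0) or np.any(self.v[:, :, grid.land_mask] != 0):
            raise ValidationError("velocity must be zero on land cells")


@dataclass
class MPASite:
    """A marine protected area polygon used for release and settlement."""

    id: int
    name: str
    ring: np.ndarray  # (n, 2) lon/lat vertices, closed
    area_km2: float
    ecoregion: Optional[str] = None
    _polygon: Optional[Polygon] = dc_field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.ring = np.asarray(self.ring, dtype=float)
        if self.ring.ndim != 2 or self.ring.shape[1] != 2 or len(self.ring) < 4:
            raise ValidationError(f"MPA {self.id}: ring must be (n>=4, 2)")
        if not np.allclose(self.ring[0], self.ring[-1]):
            raise ValidationError(f"MPA {self.id}: ring must be closed")
        poly = Polygon(self.ring)
        if not poly.is_valid:
            raise ValidationError(f"MPA {self.id}: self-intersecting ring")
        if self.area_km2 <= 0:
            raise ValidationError(f"MPA {self.id}: area_km2 must be > 0")
        self._polygon = poly

    @property
    def polygon(self) -> Polygon:
        if self._polygon is None:
            self._polygon = Polygon(self.ring)
        return self._polygon

    @property
    def centroid(self):
        c = self.polygon.centroid
        return (c.x, c.y)


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style; dims time/depth/lat/lon; vars u, v, w, bathymetry, mask)
# ---------------------------------------------------------------------------

def write_velocity_field(field: VelocityField, grid: GridSpec, path) -> None:
    """Write a velocity field + grid to a CF-style NetCDF file."""
    field.validate_against(grid)
    ds = xr.Dataset(
        {
            "u": (("time", "depth", "lat", "lon"), field.u, {"units": "m s-1"}),
            "v": (("time", "depth", "lat", "lon"), field.v, {"units": "m s-1"}),
            "w": (("time", "depth", "lat", "lon"), field.w, {"units": "m s-1"}),
            "bathymetry": (("lat", "lon"), grid.bathymetry_m, {"units": "m"}),
            "mask": (("lat", "lon"), grid.land_mask.astype(np.int8),
                     {"long_name": "land mask (1 = land)"}),
        },
        coords={
            "time": field.times,
            "depth": ("depth", grid.depth_levels, {"units": "m", "positive": "down"}),
            "lat": ("lat", grid.lat_axis, {"units": "degrees_north"}),
            "lon": ("lon", grid.lon_axis, {"units": "degrees_east"}),
        },
        attrs={"cell_length_m": grid.cell_length_m},
    )
    ds.to_netcdf(path, engine="scipy")


def read_velocity_field(path):
    """Read a NetCDF velocity file -> (VelocityField, GridSpec).

    ``w`` is assumed zero when absent. Masked/fill values on land are
    zero-filled. Raises :class:`FormatError` naming any missing dimension or
    variable.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for dim in ("time", "depth", "lat", "lon"):
        if dim not in ds.dims:
            raise FormatError(f"dimension {dim} missing")
    for var in ("u", "v"):
        if var not in ds:
            raise FormatError(f"{var} missing")
        units = ds[var].attrs.get("units")
        if units is not None and units not in ("m s-1", "m/s", "m s^-1", "meter second-1"):
            raise FormatError(f"{var} has units {units!r}, expected m s-1")
    lon = ds["lon"].values.astype(float)
    lat = ds["lat"].values.astype(float)
    depth = ds["depth"].values.astype(float)
    for name, ax in (("lon", lon), ("lat", lat), ("depth", depth)):
        if len(ax) > 1 and not np.all(np.diff(ax) > 0):
            raise ValidationError(f"{name} axis not strictly increasing")
    if "mask" in ds:
        land = ds["mask"].values.astype(bool)
    else:
        land = ~np.isfinite(ds["u"].isel(time=0, depth=0).values)
    bathy = ds["bathymetry"].values.astype(float) if "bathymetry" in ds else \
        np.where(land, 0.0, float(depth[-1]))
    grid = GridSpec(lon_axis=lon, lat_axis=lat, depth_levels=depth,
                    land_mask=land, bathymetry_m=bathy,
                    cell_length_m=float(ds.attrs["cell_length_m"])
                    if "cell_length_m" in ds.attrs else None)
    u = np.nan_to_num(ds["u"].values.astype(float))
    v = np.nan_to_num(ds["v"].values.astype(float))
    w = np.nan_to_num(ds["w"].values.astype(float)) if "w" in ds else np.zeros_like(u)
    u[:, :, land] = 0.0
    v[:, :, land] = 0.0
    w[:, :, land] = 0.0
    field = VelocityField(times=ds["time"].values, u=u, v=v, w=w)
    field.validate_against(grid)
    return field, grid


# ---------------------------------------------------------------------------
# GeoJSON I/O for MPA polygons
# ---------------------------------------------------------------------------

def write_mpas(mpas: Sequence[MPASite], path) -> None:
    """Write MPA polygons to a GeoJSON FeatureCollection."""
    features = []
    for m in mpas:
        features.append({
            "type": "Feature",
            "geometry": mapping(m.polygon),
            "properties": {"id": m.id, "name": m.name, "area_km2": m.area_km2,
                           "ecoregion": m.ecoregion},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_mpas(path) -> list[MPASite]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    mpas = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise FormatError(f"feature geometry {geom.geom_type} not a Polygon")
        props = feat.get("properties", {})
        ring = np.asarray(geom.exterior.coords, dtype=float)
        mpas.append(MPASite(id=int(props["id"]), name=str(props.get("name", props["id"])),
                            ring=ring, area_km2=float(props["area_km2"]),
                            ecoregion=props.get("ecoregion")))
    return mpas


def mpa_centroid_distance_km(a: MPASite, b: MPASite) -> float:
    ax, ay = a.centroid
    bx, by = b.centroid
    return float(haversine_km(ax, ay, bx, by))
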