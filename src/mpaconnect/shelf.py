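"""Larval export onto the continental shelf.

Final larval positions are binned into grid cells; the continental shelf is
every sea cell shallower than 200 m. The summary reports which fraction of
(non-lost) larvae ends on the shelf, in the open sea, or inside an MPA, and
which fraction of shelf *area* receives no larvae at all — the unseeded
coastal fraction. Cell areas are spherical, so the unseeded fraction is an
area fraction, not a cell count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import shapely
import xarray as xr

from .geo import cell_areas_km2
from .grids import GridSpec, MPASite, ValidationError
from .tracker import LOST, TrajectoryRecord

SHELF_DEPTH_M = 200.0


@dataclass
class ShelfExportSummary:
    shelf_mask: np.ndarray       # (nlat, nlon) bool
    abundance: np.ndarray        # (nlat, nlon) larvae (possibly weighted) per cell
    frac_on_shelf: float
    frac_open_sea: float
    frac_in_mpas: float
    frac_shelf_unseeded: float   # area-weighted
    n_released: int
    n_lost: int

    def as_dict(self) -> dict:
        return {"frac_on_shelf": self.frac_on_shelf,
                "frac_open_sea": self.frac_open_sea,
                "frac_in_mpas": self.frac_in_mpas,
                "frac_shelf_unseeded": self.frac_shelf_unseeded,
                "n_released": self.n_released, "n_lost": self.n_lost}


def shelf_mask(grid: GridSpec) -> np.ndarray:
    """Sea cells with 0 < bathymetry < 200 m (strict)."""
    return (grid.bathymetry_m > 0) & (grid.bathymetry_m < SHELF_DEPTH_M) & ~grid.land_mask


def export_summary(traj: TrajectoryRecord, grid: GridSpec,
                   mpas: Sequence[MPASite],
                   production_weights: Optional[np.ndarray] = None) -> ShelfExportSummary:
    """Bin non-lost final positions and compute the export fractions.

    ``production_weights`` maps source MPA (in id order) to a relative
    larval production; weights are normalized to preserve the total count,
    so uniform weights reproduce the unweighted abundance map. The fractions
    of larvae on shelf / open sea / in MPAs are per-larva (unweighted);
    standstill larvae sit in their coastal cell and count as on-shelf.
    """
    mask = shelf_mask(grid)
    ok = traj.status != LOST
    x, y = traj.final_lon[ok], traj.final_lat[ok]
    src = traj.source_mpa[ok]
    n_ok = int(ok.sum())

    order = sorted(mpas, key=lambda m: m.id)
    if production_weights is None:
        w = np.ones(n_ok)
    else:
        pw = np.asarray(production_weights, dtype=float)
        if pw.sum() <= 0:
            raise ValidationError("production weights must sum to > 0")
        pw = pw * len(pw) / pw.sum()   # normalize to equal total
        lookup = {m.id: pw[k] for k, m in enumerate(order)}
        w = np.array([lookup[s] for s in src])

    iy, ix = grid.cell_index(x, y)
    abundance = np.zeros((grid.nlat, grid.nlon))
    np.add.at(abundance, (iy, ix), w)

    on_shelf = mask[iy, ix]
    in_mpa = np.zeros(n_ok, dtype=bool)
    for m in order:
        in_mpa |= shapely.intersects_xy(m.polygon, x, y)

    areas = cell_areas_km2(grid.lon_axis, grid.lat_axis)
    shelf_area = areas[mask].sum()
    unseeded = mask & (abundance == 0)
    frac_unseeded = float(areas[unseeded].sum() / shelf_area) if shelf_area > 0 else np.nan

    frac_shelf = float(on_shelf.mean()) if n_ok else np.nan
    return ShelfExportSummary(
        shelf_mask=mask, abundance=abundance,
        frac_on_shelf=frac_shelf,
        frac_open_sea=1.0 - frac_shelf if n_ok else np.nan,
        frac_in_mpas=float(in_mpa.mean()) if n_ok else np.nan,
        frac_shelf_unseeded=frac_unseeded,
        n_released=traj.n_particles,
        n_lost=int((traj.status == LOST).sum()),
    )


def abundance_map_write(summary: ShelfExportSummary, grid: GridSpec,
                        path_nc, path_png: Optional[str] = None) -> None:
    """Write the gridded abundance to NetCDF and optionally render a map.

    Shelf cells are colored by larval abundance; unseeded shelf cells use a
    reserved grey.
    """
    ds = xr.Dataset(
        {"larval_abundance": (("lat", "lon"), summary.abundance),
         "shelf_mask": (("lat", "lon"), summary.shelf_mask.astype(np.int8))},
        coords={"lat": grid.lat_axis, "lon": grid.lon_axis},
        attrs={k: v for k, v in summary.as_dict().items()},
    )
    ds.to_netcdf(path_nc, engine="scipy")
    if path_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(8, 4))
        shown = np.where(summary.shelf_mask, summary.abundance, np.nan)
        unseeded = summary.shelf_mask & (summary.abundance == 0)
        grey = np.where(unseeded, 1.0, np.nan)
        ax.pcolormesh(grid.lon_axis, grid.lat_axis,
                      np.where(grid.land_mask, 1.0, np.nan), cmap="Greys_r",
                      vmin=0, vmax=2)
        ax.pcolormesh(grid.lon_axis, grid.lat_axis, grey, cmap="Greys",
                      vmin=0, vmax=2)
        pm = ax.pcolormesh(grid.lon_axis, grid.lat_axis, shown, cmap="viridis")
        fig.colorbar(pm, ax=ax, label="larvae per cell")
        ax.set_xlabel("lon")
        ax.set_ylabel("lat")
        ax.set_title("Larval abundance on the continental shelf (<200 m)")
        fig.savefig(path_png, dpi=120)
        plt.close(fig)


def read_abundance_map(path_nc):
    """Round-trip reader for the abundance layer."""
    with xr.open_dataset(path_nc, engine="scipy") as ds:
        return ds["larval_abundance"].values.copy()
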