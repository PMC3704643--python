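"""Connectivity matrix and recruitment statistics from final larval positions.

The connection probability c(i, j) is the fraction of larvae released in
source MPA j whose final position (at the end of the pelagic larval
duration, with no competency window) lies inside destination MPA i. The
matrix is stored destination-by-source, so columns sum to at most 1: the
remainder of each column ended outside every MPA or was lost at the domain
edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from .geo import haversine_km
from .grids import MPASite, ValidationError
from .tracker import LOST, TrajectoryRecord


class AmbiguityError(ValueError):
    """A final position lies inside two MPAs whose interiors overlap."""


@dataclass
class ConnectivityMatrix:
    """Destination-by-source transport probabilities between MPAs."""

    mpa_ids: np.ndarray        # (n,) MPA ids ordering rows/columns
    counts: np.ndarray         # (n, n) settlers, counts[i, j]: from j into i
    released: np.ndarray       # (n,) larvae released per source

    def __post_init__(self):
        self.mpa_ids = np.asarray(self.mpa_ids)
        self.counts = np.asarray(self.counts, dtype=float)
        self.released = np.asarray(self.released, dtype=float)
        if np.any(self.released <= 0):
            raise ValidationError("released must be positive for every source MPA")

    @property
    def n(self) -> int:
        return len(self.mpa_ids)

    @property
    def c(self) -> np.ndarray:
        return self.counts / self.released[None, :]

    @property
    def detection_floor(self) -> float:
        """Smallest resolvable nonzero probability, 1 / max(released)."""
        return 1.0 / float(self.released.max())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.c, index=self.mpa_ids, columns=self.mpa_ids)

    def save_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "dest_id"
        df.to_csv(path)

    @classmethod
    def from_counts(cls, counts, released, mpa_ids=None) -> "ConnectivityMatrix":
        counts = np.asarray(counts)
        if mpa_ids is None:
            mpa_ids = np.arange(1, counts.shape[0] + 1)
        return cls(mpa_ids=mpa_ids, counts=counts, released=released)


@dataclass
class RecruitmentStats:
    """Per-MPA retention/recruitment fractions plus network connectance."""

    mpa_ids: np.ndarray
    connectance: float
    local_retention: np.ndarray     # lr(i) = c(i, i)
    self_recruitment: np.ndarray    # sr(i) = c(i,i) / sum_j c(i,j); NaN if no input
    subsidy: np.ndarray             # 1 - sr(i)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mpa_id": self.mpa_ids,
            "local_retention": self.local_retention,
            "self_recruitment": self.self_recruitment,
            "subsidy_recruitment": self.subsidy,
        })


# ---------------------------------------------------------------------------

def assign_settlement(traj: TrajectoryRecord, mpas: Sequence[MPASite]) -> np.ndarray:
    """Count settlers: counts[i, j] = larvae from source j ending inside MPA i.

    Lost larvae are excluded. Points exactly on a polygon edge count as
    inside; a point claimed by several edge-sharing MPAs goes to the lowest
    id, while genuinely overlapping polygon interiors raise
    :class:`AmbiguityError`.
    """
    order = sorted(mpas, key=lambda m: m.id)
    ids = [m.id for m in order]
    id_to_col = {mid: k for k, mid in enumerate(ids)}
    n = len(order)
    counts = np.zeros((n, n))
    ok = traj.status != LOST
    x, y = traj.final_lon[ok], traj.final_lat[ok]
    src = traj.source_mpa[ok]
    inside = np.stack([shapely.intersects_xy(m.polygon, x, y) for m in order])
    multi = inside.sum(axis=0) > 1
    if np.any(multi):
        hits = np.where(multi)[0]
        for h in hits:
            rows = np.where(inside[:, h])[0]
            for a in range(len(rows)):
                for b in range(a + 1, len(rows)):
                    inter = order[rows[a]].polygon.intersection(order[rows[b]].polygon)
                    if inter.area > 0:
                        raise AmbiguityError(
                            f"MPAs {ids[rows[a]]} and {ids[rows[b]]} overlap at a settled point")
        # edge ties: keep only the lowest-id membership
        first = inside.argmax(axis=0)
        inside[:, multi] = False
        inside[first[multi], multi] = True
    dest = np.where(inside.any(axis=0), inside.argmax(axis=0), -1)
    settled = dest >= 0
    src_col = np.array([id_to_col[s] for s in src[settled]], dtype=int)
    np.add.at(counts, (dest[settled], src_col), 1.0)
    return counts


def connectivity_matrix(counts: np.ndarray, released, mpa_ids=None) -> ConnectivityMatrix:
    """Normalize settlement counts column-wise by larvae released per source."""
    released = np.asarray(released, dtype=float)
    if np.any(released <= 0):
        raise ValidationError("released(j) must be > 0 for every source MPA")
    return ConnectivityMatrix.from_counts(counts, released, mpa_ids)


def connectance(C: ConnectivityMatrix | np.ndarray) -> float:
    """Fraction of nonzero entries of C over n^2 (self-loops included)."""
    c = C.c if isinstance(C, ConnectivityMatrix) else np.asarray(C)
    n = c.shape[0]
    return float(np.count_nonzero(c > 0) / n ** 2)


def recruitment_stats(C: ConnectivityMatrix) -> RecruitmentStats:
    """Local retention, self-recruitment and subsidy recruitment per MPA.

    Self-recruitment is undefined (NaN) for MPAs receiving no larvae at all.
    """
    c = C.c
    lr = np.diag(c).copy()
    total_in = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sr = np.where(total_in > 0, lr / total_in, np.nan)
    return RecruitmentStats(mpa_ids=C.mpa_ids, connectance=connectance(C),
                            local_retention=lr, self_recruitment=sr,
                            subsidy=1.0 - sr)


def dispersal_distances(traj: TrajectoryRecord) -> dict:
    """Great-circle release-to-final distance (km) per non-lost larva.

    Returns per-source-MPA mean/max distances and the pooled
    median/quartiles.
    """
    ok = traj.status != LOST
    d = haversine_km(traj.release_lon[ok], traj.release_lat[ok],
                     traj.final_lon[ok], traj.final_lat[ok])
    per_mpa = (pd.DataFrame({"mpa_id": traj.source_mpa[ok], "distance_km": d})
               .groupby("mpa_id")["distance_km"].agg(["mean", "max"]))
    pooled = {}
    if len(d):
        q25, med, q75 = np.percentile(d, [25, 50, 75])
        pooled = {"median_km": float(med), "q25_km": float(q25),
                  "q75_km": float(q75), "n": int(len(d))}
    return {"per_particle_km": d, "per_mpa": per_mpa, "pooled": pooled}


def mpa_pairwise_distances(mpas: Sequence[MPASite]) -> dict:
    """Centroid great-circle distances between MPAs and nearest neighbours."""
    if len(mpas) < 2:
        raise ValidationError("need at least 2 MPAs")
    order = sorted(mpas, key=lambda m: m.id)
    ids = [m.id for m in order]
    cx = np.array([m.centroid[0] for m in order])
    cy = np.array([m.centroid[1] for m in order])
    dmat = haversine_km(cx[:, None], cy[:, None], cx[None, :], cy[None, :])
    off = dmat + np.diag(np.full(len(ids), np.inf))
    nearest = off.min(axis=1)
    degenerate = [ids[i] for i in range(len(ids)) if np.any(off[i] == 0.0)]
    pairs = dmat[np.triu_indices(len(ids), k=1)]
    return {
        "pairwise": pd.DataFrame(dmat, index=ids, columns=ids),
        "nearest_neighbor_km": pd.Series(nearest, index=ids),
        "degenerate_ids": degenerate,
        "summary": {"median_km": float(np.median(pairs)),
                    "min_km": float(pairs.min()), "max_km": float(pairs.max())},
    }
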