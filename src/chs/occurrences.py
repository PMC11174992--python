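"""Occurrence records and the three cleaning standards.

Raw occurrence tables (species, lon, lat) are cleaned in two mechanical
steps before modelling: (1) coordinate dedup plus one-record-per-grid-cell
condensation at the resolution of the predictor stack, and (2) greedy
spatial thinning so every retained pair of points is more than a minimum
great-circle distance apart (10 km by default), which damps spatial
autocorrelation in the presence sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import EARTH_RADIUS_KM, RasterStack

log = logging.getLogger(__name__)

DEFAULT_MIN_KM = 10.0


@dataclass
class OccurrenceSet:
    """Presence records with geographic coordinates (WGS84 degrees)."""

    records: pd.DataFrame  # columns: species, lon, lat [, source]

    def __post_init__(self) -> None:
        need = {"species", "lon", "lat"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"occurrence table needs columns {sorted(need)}")
        lon = self.records["lon"].to_numpy(float)
        lat = self.records["lat"].to_numpy(float)
        if lon.size and (np.abs(lon) > 180).any():
            raise ValueError("longitude outside [-180, 180]")
        if lat.size and (np.abs(lat) > 90).any():
            raise ValueError("latitude outside [-90, 90]")

    @classmethod
    def from_arrays(cls, species: str, lon, lat) -> "OccurrenceSet":
        return cls(pd.DataFrame({
            "species": species,
            "lon": np.asarray(lon, float),
            "lat": np.asarray(lat, float),
        }))

    @classmethod
    def read_csv(cls, path: str | Path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records["lon"].to_numpy(float)

    @property
    def lat(self) -> np.ndarray:
        return self.records["lat"].to_numpy(float)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (spherical Earth, R = 6371.0088 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def dedupe_and_gridify(occ: OccurrenceSet, grid: RasterStack) -> OccurrenceSet:
    """Keep at most one record per grid cell; drop nodata and off-grid points.

    Exact coordinate duplicates collapse implicitly because they share a
    cell.  The first record (in input order) wins within each cell.
    """
    df = occ.records.reset_index(drop=True)
    row, col = grid.georef.cell_index(occ.lon, occ.lat)
    inside = (row >= 0) & (col >= 0)
    n_outside = int((~inside).sum())
    if n_outside:
        log.info("dropped %d records outside grid extent", n_outside)
    df = df[inside].copy()
    row, col = row[inside], col[inside]
    on_data = grid.valid[row, col]
    n_nodata = int((~on_data).sum())
    if n_nodata:
        log.info("dropped %d records on nodata cells", n_nodata)
    df = df[on_data]
    cell = row[on_data] * grid.georef.n_cols + col[on_data]
    keep = ~pd.Series(cell, index=df.index).duplicated()
    return OccurrenceSet(df[keep].reset_index(drop=True))


def thin_by_distance(occ: OccurrenceSet, min_km: float = DEFAULT_MIN_KM,
                     presort: bool = True) -> OccurrenceSet:
    """Greedy spatial thinning: keep a record iff it is > ``min_km`` from
    every record already kept.

    The greedy pass is order-dependent, so records are sorted by (lat, lon)
    first for reproducibility (``presort=False`` preserves input order).
    The output is idempotent under re-thinning and all pairwise distances
    exceed ``min_km``.
    """
    df = occ.records.reset_index(drop=True)
    if presort:
        df = df.sort_values(["lat", "lon"], kind="mergesort").reset_index(drop=True)
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    kept: list[int] = []
    for i in range(len(df)):
        if not kept:
            kept.append(i)
            continue
        d = haversine_km(lon[i], lat[i], lon[kept], lat[kept])
        if (d > min_km).all():
            kept.append(i)
    return OccurrenceSet(df.iloc[kept].reset_index(drop=True))
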