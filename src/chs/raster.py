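"""Lightweight georeferenced raster stacks on geographic (lon/lat) grids.

A :class:`RasterStack` bundles named, aligned 2-D layers with a shared
validity mask and a geographic georeference (cell centers, decimal degrees,
row 0 = northernmost row).  Layers are float arrays; categorical layers
(e.g. soil class maps) carry integer codes stored as floats and are flagged
by name so that downstream code never treats class labels as magnitudes.

Persistence uses the ESRI ASCII grid format (one ``.asc`` text file per
layer) plus a small JSON manifest recording which layers are categorical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GridGeoref:
    """Geographic grid geometry.

    ``origin_lon``/``origin_lat`` are the *west* and *north* edges of the
    grid; cell centers are offset half a cell inward.  ``cell_size`` is in
    decimal degrees and identical in both axes.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_lon: float
    origin_lat: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        """Longitude/latitude of cell centers for (row, col) indices."""
        lon = self.origin_lon + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.origin_lat - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def cell_index(self, lon: np.ndarray, lat: np.ndarray):
        """(row, col) of the cells containing the given points.

        Points outside the extent get index -1 in the offending axis.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size).astype(int)
        col = np.where((col >= 0) & (col < self.n_cols), col, -1)
        row = np.where((row >= 0) & (row < self.n_rows), row, -1)
        return row, col

    def center_grids(self):
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return self.cell_center(rows, cols)


@dataclass
class RasterStack:
    """Aligned named layers over one georeference with a shared valid mask."""

    georef: GridGeoref
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    categorical: set[str] = field(default_factory=set)
    valid: np.ndarray | None = None  # True where data present

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.georef.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.georef.shape:
            raise ValueError("valid mask shape does not match georeference")
        for name, arr in self.layers.items():
            self._check_layer(name, arr)

    def _check_layer(self, name: str, arr: np.ndarray) -> None:
        if arr.shape != self.georef.shape:
            raise ValueError(
                f"layer {name!r} shape {arr.shape} != grid {self.georef.shape}"
            )

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def continuous_names(self) -> list[str]:
        return [n for n in self.layers if n not in self.categorical]

    def add_layer(self, name: str, arr: np.ndarray, categorical: bool = False):
        arr = np.asarray(arr, dtype=float)
        self._check_layer(name, arr)
        self.layers[name] = arr
        if categorical:
            self.categorical.add(name)

    def copy(self) -> "RasterStack":
        return RasterStack(
            georef=self.georef,
            layers={k: v.copy() for k, v in self.layers.items()},
            categorical=set(self.categorical),
            valid=self.valid.copy(),
        )

    def same_grid(self, other: "RasterStack") -> bool:
        return self.georef == other.georef

    def values_at(self, lon, lat, layer_names=None):
        """Cell values at point locations; NaN outside extent or on nodata.

        Returns an (n_points, n_layers) float array.
        """
        if layer_names is None:
            layer_names = self.layer_names
        row, col = self.georef.cell_index(lon, lat)
        n = np.size(row)
        out = np.full((n, len(layer_names)), np.nan)
        inside = (np.asarray(row) >= 0) & (np.asarray(col) >= 0)
        r = np.asarray(row)[inside]
        c = np.asarray(col)[inside]
        ok = self.valid[r, c]
        for j, name in enumerate(layer_names):
            vals = np.full(r.shape, np.nan)
            vals[ok] = self.layers[name][r[ok], c[ok]]
            out[np.flatnonzero(inside), j] = vals
        return out

    # ------------------------------------------------------------------ I/O

    def write_dir(self, path: str | Path) -> None:
        """Write one ESRI ASCII grid per layer plus ``manifest.json``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_asc(path / f"{name}.asc", arr, self.georef, self.valid,
                      integer=name in self.categorical)
        manifest = {
            "layers": self.layer_names,
            "categorical": sorted(self.categorical),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read_dir(cls, path: str | Path) -> "RasterStack":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        layers: dict[str, np.ndarray] = {}
        georef = None
        valid = None
        for name in manifest["layers"]:
            arr, g, v = read_asc(path / f"{name}.asc")
            if georef is None:
                georef, valid = g, v
            elif g != georef:
                raise ValueError(f"layer {name!r} georeference mismatch")
            layers[name] = arr
        assert georef is not None
        return cls(
            georef=georef,
            layers=layers,
            categorical=set(manifest["categorical"]),
            valid=valid,
        )


def write_asc(path: str | Path, arr: np.ndarray, georef: GridGeoref,
              valid: np.ndarray, integer: bool = False) -> None:
    arr = np.where(valid, arr, NODATA)
    yll = georef.origin_lat - georef.n_rows * georef.cell_size
    header = (
        f"ncols {georef.n_cols}\n"
        f"nrows {georef.n_rows}\n"
        f"xllcorner {georef.origin_lon!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {georef.cell_size!r}\n"
        f"NODATA_value {int(NODATA) if integer else NODATA!r}\n"
    )
    fmt = "%d" if integer else "%.10g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt=fmt)


def read_asc(path: str | Path):
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        arr = np.loadtxt(fh, ndmin=2)
    n_rows = int(meta["nrows"])
    n_cols = int(meta["ncols"])
    cell = meta["cellsize"]
    georef = GridGeoref(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_lon=meta["xllcorner"],
        origin_lat=meta["yllcorner"] + n_rows * cell,
    )
    nodata = meta["nodata_value"]
    valid = arr != nodata
    arr = np.where(valid, arr, np.nan)
    return arr, georef, valid


def cell_areas(georef: GridGeoref) -> np.ndarray:
    """Per-cell surface area in km² on the sphere.

    Each cell is a spherical quadrangle: A = R²·Δλ·(sin φ_top − sin φ_bot),
    so areas shrink toward the poles and are constant along a latitude band.
    """
    cell = np.radians(georef.cell_size)
    rows = np.arange(georef.n_rows)
    lat_top = np.radians(georef.origin_lat - rows * georef.cell_size)
    lat_bot = lat_top - cell
    band = EARTH_RADIUS_KM**2 * cell * (np.sin(lat_top) - np.sin(lat_bot))
    return np.repeat(band[:, None], georef.n_cols, axis=1)
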