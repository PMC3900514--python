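"""Regular lon/lat analysis grid: interpolation, per-cell indices, pattern score.

The grid partitions a bounding box into square cells of a fixed size in
arc-minutes.  Cells are indexed row-major starting from the north-west
corner (row 0 = northernmost band).  All spatial layers are stored as one
value per cell, with NaN marking cells excluded by the interpolation
coverage rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class GridSpec:
    """Geometry of the analysis grid.

    Parameters
    ----------
    lon_min, lat_min : float
        South-west corner of the bounding box, decimal degrees.
    cell_minutes : float
        Cell side length in arc-minutes (both axes).
    n_rows, n_cols : int
        Number of cell rows (latitude bands, row 0 northernmost) and columns.
    active : ndarray of bool, optional
        Mask of analysis cells; defaults to all active.
    """

    lon_min: float
    lat_min: float
    cell_minutes: float
    n_rows: int
    n_cols: int
    active: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.cell_minutes <= 0:
            raise ValueError("cell_minutes must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.active is None:
            self.active = np.ones(self.n_cells, dtype=bool)
        else:
            self.active = np.asarray(self.active, dtype=bool).ravel()
            if self.active.size != self.n_cells:
                raise ValueError("active mask length must equal n_rows * n_cols")

    @property
    def cell_deg(self) -> float:
        return self.cell_minutes / 60.0

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.cell_deg

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.cell_deg

    def rowcol(self, idx):
        idx = np.asarray(idx)
        return idx // self.n_cols, idx % self.n_cols

    def cell_index(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def cell_centers(self):
        """(lon, lat) arrays of cell centers, row-major from the NW corner."""
        rows, cols = self.rowcol(np.arange(self.n_cells))
        lon = self.lon_min + (cols + 0.5) * self.cell_deg
        lat = self.lat_max - (rows + 0.5) * self.cell_deg
        return lon, lat

    def locate(self, lon, lat):
        """Cell index containing each point, or -1 if outside the box."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell_deg).astype(int)
        row = np.floor((self.lat_max - lat) / self.cell_deg).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        idx = np.where(inside, row * self.n_cols + col, -1)
        return idx if idx.ndim else int(idx)

    def restrict(self, mask) -> "GridSpec":
        """New GridSpec whose active set is the intersection with ``mask``."""
        mask = np.asarray(mask, dtype=bool).ravel()
        return replace(self, active=self.active & mask)

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "lon_min": self.lon_min,
            "lat_min": self.lat_min,
            "cell_minutes": self.cell_minutes,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "active": self.active.astype(int).tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "GridSpec":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        payload["active"] = np.asarray(payload["active"], dtype=bool)
        return cls(**payload)


@dataclass
class CellLayer:
    """One numeric value per grid cell for a single variable/year."""

    grid: GridSpec
    name: str
    year: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_cells:
            raise ValueError(
                f"layer '{self.name}' has {self.values.size} values for a grid "
                f"of {self.grid.n_cells} cells"
            )

    @property
    def active_values(self) -> np.ndarray:
        return self.values[self.grid.active]

    def to_csv(self, path):
        import pandas as pd

        lon, lat = self.grid.cell_centers()
        pd.DataFrame(
            {"cell_id": np.arange(self.grid.n_cells), "lon_center": lon,
             "lat_center": lat, "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: GridSpec, name: str, year: int) -> "CellLayer":
        import pandas as pd

        df = pd.read_csv(path).sort_values("cell_id")
        return cls(grid=grid, name=name, year=year, values=df["value"].to_numpy())


@dataclass
class HarborSet:
    """Named harbor positions; at least three are required downstream."""

    names: list
    lons: np.ndarray
    lats: np.ndarray

    def __post_init__(self):
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        if not (len(self.names) == self.lons.size == self.lats.size):
            raise ValueError("names, lons and lats must have equal length")

    def __len__(self):
        return len(self.names)


def idw_interpolate(stations, grid: GridSpec, radius_cells: int = 3,
                    power: float = 2.0, name: str = "idw", year: int = 0) -> CellLayer:
    """Inverse-distance-weighted interpolation of station values to cell centers.

    ``stations`` is an iterable of ``(lon, lat, value)``.  A cell receives
    ``sum(w_i v_i) / sum(w_i)`` with ``w_i = d_i ** -power`` over the stations
    whose distance from the cell center is at most ``radius_cells`` cell
    units; cells with no station in the neighborhood are set to NaN (excluded
    from analysis).  A station coinciding with a cell center short-circuits
    to that station's value.
    """
    stations = list(stations)
    if len(stations) == 0:
        raise ValueError("at least one station is required")
    if radius_cells < 1:
        raise ValueError("radius_cells must be >= 1")

    s_lon = np.array([s[0] for s in stations], dtype=float)
    s_lat = np.array([s[1] for s in stations], dtype=float)
    s_val = np.array([s[2] for s in stations], dtype=float)

    lon_c, lat_c = grid.cell_centers()
    # distances measured in cell units so the radius is "a radius of N cells"
    dx = (lon_c[:, None] - s_lon[None, :]) / grid.cell_deg
    dy = (lat_c[:, None] - s_lat[None, :]) / grid.cell_deg
    d = np.hypot(dx, dy)

    values = np.full(grid.n_cells, np.nan)
    within = d <= radius_cells
    for c in np.flatnonzero(grid.active):
        sel = within[c]
        if not sel.any():
            continue
        dc = d[c, sel]
        vc = s_val[sel]
        exact = dc < 1e-12
        if exact.any():
            values[c] = vc[exact][0]
        else:
            w = dc ** (-power)
            values[c] = np.sum(w * vc) / np.sum(w)
    values[~grid.active] = np.nan
    return CellLayer(grid=grid, name=name, year=year, values=values)


def coverage_mask(stations, grid: GridSpec, radius_cells: int = 3) -> np.ndarray:
    """Boolean mask of cells with at least one station within the radius."""
    layer = idw_interpolate(stations, grid, radius_cells=radius_cells)
    return ~np.isnan(layer.values)


def depth_indices(pixels, expected_count: int = 36, cell_id=None):
    """Mean depth and sample-sd depth of the bathymetry pixels of one cell.

    The standard deviation is the sample sd (ddof=1) and serves as a proxy
    for sea-bottom heterogeneity within the cell.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size != expected_count:
        where = "" if cell_id is None else f" in cell {cell_id}"
        raise ValueError(
            f"expected {expected_count} depth pixels{where}, got {pixels.size}"
        )
    return float(pixels.mean()), float(pixels.std(ddof=1))


def neighbor_mean(layer: CellLayer, ray: int = 2) -> CellLayer:
    """Mean of active-cell values within Chebyshev distance <= ray, self excluded.

    Cells with no active neighbor get 0 and a logged warning.
    """
    if ray < 1:
        raise ValueError("ray must be >= 1")
    g = layer.grid
    vals = layer.values
    out = np.full(g.n_cells, np.nan)
    finite = g.active & np.isfinite(vals)
    lonely = []
    for c in np.flatnonzero(g.active):
        r, k = c // g.n_cols, c % g.n_cols
        r0, r1 = max(0, r - ray), min(g.n_rows - 1, r + ray)
        k0, k1 = max(0, k - ray), min(g.n_cols - 1, k + ray)
        acc, n = 0.0, 0
        for rr in range(r0, r1 + 1):
            base = rr * g.n_cols
            for kk in range(k0, k1 + 1):
                j = base + kk
                if j == c or not finite[j]:
                    continue
                acc += vals[j]
                n += 1
        if n == 0:
            lonely.append(c)
            out[c] = 0.0
        else:
            out[c] = acc / n
    if lonely:
        logger.warning("neighbor_mean: %d cell(s) with no active neighbors set to 0",
                       len(lonely))
    return CellLayer(grid=g, name=f"{layer.name}_nbr{ray}", year=layer.year,
                     values=out)


def mean_distance_to_harbors(grid: GridSpec, harbors: HarborSet, k: int = 3) -> np.ndarray:
    """Per-cell mean great-circle distance (km) to the k nearest harbors."""
    if len(harbors) < k:
        raise ValueError(f"at least {k} harbors are required, got {len(harbors)}")
    lon_c, lat_c = grid.cell_centers()
    d = haversine_km(lon_c[:, None], lat_c[:, None],
                     harbors.lons[None, :], harbors.lats[None, :])
    d.sort(axis=1)
    return d[:, :k].mean(axis=1)


def pattern_score(effort, harbors: HarborSet, dist3: np.ndarray = None) -> float:
    """Fuel-consumption proxy of an effort pattern.

    ``sum over occupied cells of log10(count) * mean distance to the three
    nearest harbors`` — cells with zero or one fishing point contribute 0
    (log10 of counts >= 1 only; empty cells are skipped to avoid -inf).

    ``effort`` is any object exposing ``.grid`` and integer ``.counts``;
    ``dist3`` may be passed to reuse precomputed distances.
    """
    counts = np.asarray(effort.counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("effort counts must be >= 0")
    if dist3 is None:
        dist3 = mean_distance_to_harbors(effort.grid, harbors, k=3)
    occupied = counts >= 1
    return float(np.sum(np.log10(counts[occupied]) * dist3[occupied]))
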