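"""Fishing-effort mapping from vessel ping streams.

Trips (harbor-to-harbor ping sequences, labeled in the input) are
regularized to a fixed time step, a speed window flags fishing pings, and
fishing pings are counted per grid cell to form annual effort layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from trawlsim.grid import GridSpec, haversine_km

logger = logging.getLogger(__name__)

PING_COLUMNS = ["vessel_id", "trip_id", "timestamp", "lon", "lat", "speed_kn"]

#: default trawling-speed window in knots
TRAWL_SPEED_WINDOW = (2.0, 4.5)


@dataclass
class EffortPattern:
    """Annual per-cell fishing-point counts."""

    grid: GridSpec
    year: int
    counts: np.ndarray
    dropped: int = 0   # fishing pings outside the grid bounds

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.size != self.grid.n_cells:
            raise ValueError("counts length must equal the number of grid cells")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)

    @property
    def Tf(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path):
        lon, lat = self.grid.cell_centers()
        pd.DataFrame({"cell_id": np.arange(self.grid.n_cells),
                      "lon_center": lon, "lat_center": lat,
                      "value": self.counts}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: GridSpec, year: int) -> "EffortPattern":
        df = pd.read_csv(path).sort_values("cell_id")
        return cls(grid=grid, year=year, counts=df["value"].to_numpy(dtype=np.int64))


def _validate_trip(trip: pd.DataFrame) -> pd.DataFrame:
    t = pd.to_datetime(trip["timestamp"])
    if not t.is_monotonic_increasing or t.duplicated().any():
        raise ValueError("trip timestamps must be strictly increasing")
    out = trip.copy()
    out["timestamp"] = t
    return out


def interpolate_track(trip: pd.DataFrame, step_minutes: float = 10.0) -> pd.DataFrame:
    """Regularize one trip to a fixed time step, linear in lon/lat.

    Positions are linearly interpolated in time from the first ping to the
    last (endpoints included); ping speeds (knots) are recomputed from
    consecutive interpolated positions (backward difference, first ping gets
    the forward one).  A trip shorter than one step is returned unchanged
    with a warning.
    """
    if len(trip) < 2:
        raise ValueError("a trip needs at least 2 pings")
    trip = _validate_trip(trip)
    t = trip["timestamp"]
    t0, t1 = t.iloc[0], t.iloc[-1]
    span_min = (t1 - t0).total_seconds() / 60.0
    if span_min < step_minutes:
        logger.warning("trip %s spans %.1f min (< step %.1f); returned unchanged",
                       trip["trip_id"].iloc[0], span_min, step_minutes)
        return trip.reset_index(drop=True)

    secs = (t - t0).dt.total_seconds().to_numpy()
    new_secs = np.arange(0.0, secs[-1] + 1e-9, step_minutes * 60.0)
    lon = np.interp(new_secs, secs, trip["lon"].to_numpy(dtype=float))
    lat = np.interp(new_secs, secs, trip["lat"].to_numpy(dtype=float))

    seg_km = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    seg_hr = np.diff(new_secs) / 3600.0
    seg_kn = seg_km / seg_hr / 1.852
    speed = np.empty_like(lon)
    speed[1:] = seg_kn          # backward difference
    speed[0] = seg_kn[0] if seg_kn.size else 0.0

    return pd.DataFrame({
        "vessel_id": trip["vessel_id"].iloc[0],
        "trip_id": trip["trip_id"].iloc[0],
        "timestamp": t0 + pd.to_timedelta(new_secs, unit="s"),
        "lon": lon, "lat": lat, "speed_kn": speed,
    })


def regularize_pings(pings: pd.DataFrame, step_minutes: float = 10.0) -> pd.DataFrame:
    """Apply interpolate_track to every (vessel, trip) group."""
    parts = [interpolate_track(g, step_minutes)
             for _, g in pings.groupby(["vessel_id", "trip_id"], sort=True)]
    return pd.concat(parts, ignore_index=True)


def speed_filter(pings: pd.DataFrame, v_min: float = TRAWL_SPEED_WINDOW[0],
                 v_max: float = TRAWL_SPEED_WINDOW[1]) -> pd.DataFrame:
    """Flag pings as fishing when v_min <= speed <= v_max (knots)."""
    if not v_min < v_max:
        raise ValueError("need v_min < v_max")
    out = pings.copy()
    s = out["speed_kn"].to_numpy(dtype=float)
    out["fishing"] = (s >= v_min) & (s <= v_max)
    return out


def effort_layer(flagged: pd.DataFrame, grid: GridSpec, year: int) -> EffortPattern:
    """Count fishing-flagged pings per grid cell.

    Fishing pings outside the grid bounds are dropped; the dropped count is
    logged and stored so that per-cell counts + dropped = fishing pings.
    """
    fish = flagged[flagged["fishing"]]
    idx = grid.locate(fish["lon"].to_numpy(dtype=float),
                      fish["lat"].to_numpy(dtype=float))
    idx = np.atleast_1d(idx)
    outside = int((idx < 0).sum())
    if outside:
        logger.warning("%d fishing ping(s) outside the grid were dropped", outside)
    counts = np.bincount(idx[idx >= 0], minlength=grid.n_cells).astype(np.int64)
    return EffortPattern(grid=grid, year=year, counts=counts, dropped=outside)


def pings_to_effort(pings: pd.DataFrame, grid: GridSpec, year: int,
                    step_minutes: float = 10.0,
                    speed_window=TRAWL_SPEED_WINDOW) -> EffortPattern:
    """Full chain: regularize, speed-filter, count per cell."""
    reg = regularize_pings(pings, step_minutes)
    flagged = speed_filter(reg, *speed_window)
    return effort_layer(flagged, grid, year)
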