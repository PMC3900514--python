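"""Synthetic world generator.

Produces every input the pipeline needs — bathymetry pixels, SST layers,
harbors, stratified-random survey hauls, vessel ping streams, price
schedules and fleet fuel-cost records — with the generating truth retained
so every downstream stage is testable without external data.

The world is deliberately stylized: a shelf deepening away from the northern
coast with two shallow banks, species abundance surfaces that are smooth
functions of depth (species-specific preferred depth band) times a fixed
spatial noise field and a smooth year factor, and harbor-to-harbor trips
whose trawling segments run over high-abundance cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from trawlsim import params as defaults
from trawlsim.economics import CostModel
from trawlsim.grid import GridSpec, HarborSet, depth_indices, haversine_km
from trawlsim.lfd import HaulRecord, StratumSpec

logger = logging.getLogger(__name__)

KM_PER_DEG_LAT = 111.195   # 2*pi*R/360 for R = 6371 km
NM_TO_KM = 1.852

#: species depth preference (center m, width m) and base density (N/km^2)
SPECIES_HABITAT = {
    "DPS": (250.0, 150.0, 600.0),
    "HKE": (200.0, 120.0, 260.0),
    "MUT": (80.0, 60.0, 320.0),
}

#: cohort relative abundance factors (younger cohorts more numerous)
COHORT_FACTORS = {3: (1.0, 0.6, 0.3), 2: (1.0, 0.5)}


@dataclass
class SyntheticWorldConfig:
    """Knobs of the synthetic world; a fixed seed gives byte-identical output."""

    lon_min: float = 12.0
    lat_min: float = 36.4
    cell_minutes: float = 6.0
    n_rows: int = 14
    n_cols: int = 28            # 14 x 28 = 392 cells, near the ~394 target
    years: tuple = (2006, 2007, 2008, 2009, 2010)
    species: tuple = ("DPS", "HKE", "MUT")
    n_hauls: int = 70           # per year
    n_vessels: int = 12
    trips_per_vessel: int = 6   # per year
    seed: int = 0
    max_depth: float = 800.0
    min_depth: float = 10.0
    bank_depth_frac: float = 0.88   # fractional shoaling at bank centers
    trawl_speed: tuple = (2.0, 4.5)     # knots
    steam_speed: tuple = (8.0, 12.0)    # knots
    fuel_noise_sd: float = 0.0
    fuel_years: tuple = (2006, 2007, 2008, 2009, 2010, 2011)
    mixture_proportions: dict = None    # (species, sex) -> tuple, default equal
    spatial_noise_sd: float = 0.25

    def __post_init__(self):
        if self.cell_minutes <= 0:
            raise ValueError("cell size must be > 0")
        if len(self.years) < 2:
            raise ValueError("at least 2 years are required (the predictor needs a lag)")
        if self.mixture_proportions is None:
            self.mixture_proportions = {}


@dataclass
class GroundTruth:
    """Everything the generator knew; consumed only by tests, never by the pipeline."""

    mixtures: dict              # (species, sex) -> {year: [(mean, sd), ...]}
    proportions: dict           # (species, sex) -> tuple summing to 1
    abundance: dict             # species -> sex -> (n_years, n_cells, K)
    q: dict                     # species -> generative trawl catchability
    cost_model: CostModel
    trawl_speed: tuple
    steam_speed: tuple
    fishing_counts: dict        # year -> per-cell counts of trawl-state pings

    def to_json(self, path=None) -> str:
        payload = {
            "mixtures": {f"{s}|{x}": {str(y): v for y, v in d.items()}
                         for (s, x), d in self.mixtures.items()},
            "proportions": {f"{s}|{x}": list(v)
                            for (s, x), v in self.proportions.items()},
            "abundance": {s: {x: a.tolist() for x, a in d.items()}
                          for s, d in self.abundance.items()},
            "q": self.q,
            "cost_model": {"beta0": self.cost_model.beta0,
                           "beta_ps": self.cost_model.beta_ps,
                           "beta_e": self.cost_model.beta_e},
            "trawl_speed": list(self.trawl_speed),
            "steam_speed": list(self.steam_speed),
            "fishing_counts": {str(y): c.tolist()
                               for y, c in self.fishing_counts.items()},
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class WorldBundle:
    config: SyntheticWorldConfig
    grid: GridSpec
    depth_pixels: np.ndarray          # (n_cells, pixels_per_cell)
    dbar: np.ndarray
    dsd: np.ndarray
    strata: list
    cell_stratum: np.ndarray          # stratum id per cell
    harbors: HarborSet
    sst: dict                         # year -> per-cell array
    hauls: list
    pings: pd.DataFrame
    prices: dict
    fuel_records: pd.DataFrame
    class_edges: dict                 # species -> bin edges (mm)
    truth: GroundTruth


# ---------------------------------------------------------------------------
# physical fields
# ---------------------------------------------------------------------------

def _depth_function(config: SyntheticWorldConfig):
    """Smooth depth (m): shelf deepening southwards plus two shallow banks."""
    lat_max = config.lat_min + config.n_rows * config.cell_minutes / 60.0
    lon_ext = config.n_cols * config.cell_minutes / 60.0
    lat_ext = config.n_rows * config.cell_minutes / 60.0
    banks = [
        (config.lon_min + 0.22 * lon_ext, lat_max - 0.35 * lat_ext, 0.16 * lon_ext),
        (config.lon_min + 0.75 * lon_ext, lat_max - 0.30 * lat_ext, 0.13 * lon_ext),
    ]

    def depth(lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        frac = np.clip((lat_max - lat) / lat_ext, 0.0, 1.0)
        d = config.min_depth + (config.max_depth - config.min_depth) * frac ** 1.4
        shoal = np.zeros_like(d)
        for blon, blat, w in banks:
            r2 = ((lon - blon) ** 2 + (lat - blat) ** 2) / (2.0 * w ** 2)
            shoal = np.maximum(shoal, config.bank_depth_frac * np.exp(-r2))
        d = config.min_depth + (d - config.min_depth) * (1.0 - shoal)
        return np.clip(d, config.min_depth, config.max_depth)

    return depth


def _pixels_per_cell(config: SyntheticWorldConfig) -> int:
    side = int(round(config.cell_minutes))  # 1-arc-minute pixels
    return side * side


def _bathymetry(grid: GridSpec, config: SyntheticWorldConfig, depth_fn):
    side = int(round(config.cell_minutes))
    step = grid.cell_deg / side
    lon_c, lat_c = grid.cell_centers()
    offs = (np.arange(side) + 0.5) * step - grid.cell_deg / 2.0
    dlon, dlat = np.meshgrid(offs, offs)
    pix = depth_fn(lon_c[:, None] + dlon.ravel()[None, :],
                   lat_c[:, None] + dlat.ravel()[None, :])
    dbar = np.empty(grid.n_cells)
    dsd = np.empty(grid.n_cells)
    for c in range(grid.n_cells):
        dbar[c], dsd[c] = depth_indices(pix[c], expected_count=side * side, cell_id=c)
    return pix, dbar, dsd


def _cell_area_km2(grid: GridSpec) -> float:
    lat_mid = 0.5 * (grid.lat_min + grid.lat_max)
    return (grid.cell_deg * KM_PER_DEG_LAT
            * grid.cell_deg * KM_PER_DEG_LAT * np.cos(np.radians(lat_mid)))


def _assign_strata(dbar: np.ndarray, grid: GridSpec):
    """Stratum per cell from mean depth; errors if any stratum is empty."""
    bounds = defaults.SURVEY_STRATA_BOUNDS
    edges = [b[0] for b in bounds] + [bounds[-1][1]]   # contiguous assignment bands
    d = np.clip(dbar, edges[0], edges[-1] - 1e-9)
    cell_stratum = np.digitize(d, edges[1:-1])
    area = _cell_area_km2(grid)
    strata, empty = [], []
    for i, (lo, hi) in enumerate(bounds):
        n = int((cell_stratum == i).sum())
        if n == 0:
            empty.append(f"{lo:g}-{hi:g} m")
            continue
        strata.append(StratumSpec(stratum_id=i, depth_min=lo, depth_max=hi,
                                  area_km2=n * area))
    if empty:
        raise ValueError(
            "degenerate depth field: no cells fall in strata " + ", ".join(empty))
    return strata, cell_stratum


def allocate_hauls(strata, n_hauls: int) -> dict:
    """Haul count per stratum, proportional to area (largest-remainder rounding)."""
    areas = np.array([s.area_km2 for s in strata], dtype=float)
    quota = n_hauls * areas / areas.sum()
    base = np.floor(quota).astype(int)
    rem = n_hauls - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    return {s.stratum_id: int(k) for s, k in zip(strata, base)}


# ---------------------------------------------------------------------------
# biology
# ---------------------------------------------------------------------------

def _habitat_surface(dbar, center, width):
    return np.exp(-0.5 * ((dbar - center) / width) ** 2)


def _class_edges(species: str, mixtures: dict) -> np.ndarray:
    width = defaults.CLASS_WIDTH[species]
    mus, sds = [], []
    for (s, _x), per_year in mixtures.items():
        if s != species:
            continue
        for comps in per_year.values():
            mus += [m for m, _ in comps]
            sds += [sd for _, sd in comps]
    lo = max(0.0, np.floor((min(mus) - 4 * max(sds)) / width) * width)
    hi = np.ceil((max(mus) + 4 * max(sds)) / width) * width
    return np.arange(lo, hi + width / 2, width)


def draw_cohort_lengths(mixtures, proportions, species, sex, year, n, rng):
    """Sample n lengths from the configured normal mixture.

    Returns (lengths, component labels); labels index the mixture components
    in the configured (ascending-mean) order.
    """
    comps = mixtures[(species, sex)][year]
    K = len(comps)
    p = np.asarray(proportions.get((species, sex), np.full(K, 1.0 / K)), dtype=float)
    p = p / p.sum()
    labels = rng.choice(K, size=n, p=p)
    mus = np.array([m for m, _ in comps])
    sds = np.array([s for _, s in comps])
    lengths = rng.normal(mus[labels], sds[labels])
    return lengths, labels


def _abundance_truth(config, grid, dbar, rng):
    """species -> sex -> (n_years, n_cells, K) smooth abundance surfaces."""
    truth = {}
    n_years = len(config.years)
    for si, sp in enumerate(config.species):
        center, width, base = SPECIES_HABITAT[sp]
        K = defaults.N_COHORTS[sp]
        factors = COHORT_FACTORS[K]
        habitat = _habitat_surface(dbar, center, width)
        noise = np.exp(rng.normal(0.0, config.spatial_noise_sd, grid.n_cells))
        truth[sp] = {}
        for xj, sex in enumerate(("F", "M")):
            surf = np.empty((n_years, grid.n_cells, K))
            for yi in range(n_years):
                gy = 1.0 + 0.15 * np.sin(2.0 * np.pi * yi / max(n_years, 3)
                                         + 1.3 * si + 0.4 * xj)
                for k in range(K):
                    surf[yi, :, k] = 0.5 * base * factors[k] * gy * habitat * noise
            truth[sp][sex] = surf
    return truth


def _make_hauls(config, grid, strata, cell_stratum, truth, class_edges, rng):
    hauls = []
    year_index = {y: i for i, y in enumerate(config.years)}
    per_stratum = allocate_hauls(strata, config.n_hauls)
    lon_c, lat_c = grid.cell_centers()
    half = grid.cell_deg / 2.0
    mixtures = _resolved_mixtures(config)
    for year in config.years:
        station = 0
        for s in strata:
            cells = np.flatnonzero(cell_stratum == s.stratum_id)
            chosen = rng.choice(cells, size=per_stratum[s.stratum_id],
                                replace=len(cells) < per_stratum[s.stratum_id])
            for c in chosen:
                lon = lon_c[c] + rng.uniform(-0.8 * half, 0.8 * half)
                lat = lat_c[c] + rng.uniform(-0.8 * half, 0.8 * half)
                sid = f"{year}-S{station:03d}"
                station += 1
                for sp in config.species:
                    edges = class_edges[sp]
                    for sex in ("F", "M"):
                        dens = truth[sp][sex][year_index[year], c]   # per cohort
                        comps = mixtures[(sp, sex)][year]
                        counts = np.zeros(edges.size - 1)
                        for k, (mu, sd) in enumerate(comps):
                            n_k = rng.poisson(dens[k])
                            if n_k == 0:
                                continue
                            lengths = rng.normal(mu, sd, n_k)
                            ctk, _ = np.histogram(lengths, bins=edges)
                            counts += ctk
                        hauls.append(HaulRecord(
                            station_id=sid, lon=lon, lat=lat,
                            stratum_id=s.stratum_id, year=year, species=sp,
                            sex=sex, class_edges=edges, densities=counts,
                        ))
    return hauls


def _resolved_mixtures(config) -> dict:
    out = {}
    for sp in config.species:
        for sex in ("F", "M"):
            src = defaults.COHORT_MIXTURES[(sp, sex)]
            out[(sp, sex)] = {y: src[y] for y in config.years if y in src}
            missing = [y for y in config.years if y not in src]
            for y in missing:
                # reuse the closest configured year
                nearest = min(src, key=lambda yy: abs(yy - y))
                out[(sp, sex)][y] = src[nearest]
    return out


# ---------------------------------------------------------------------------
# vessel trips
# ---------------------------------------------------------------------------

def _km_per_deg_lon(lat):
    return KM_PER_DEG_LAT * np.cos(np.radians(lat))


def _walk(lon, lat, heading, km, lat_ref):
    return (lon + km * np.sin(heading) / _km_per_deg_lon(lat_ref),
            lat + km * np.cos(heading) / KM_PER_DEG_LAT)


def _make_trips(config, grid, harbors, hotspot_p, year, rng):
    """Ping rows for one year; returns (rows, per-ping trawl flags)."""
    rows = []
    step_h = 1.0 / 6.0                       # 10-minute pings
    lon_c, lat_c = grid.cell_centers()
    margin = grid.cell_deg * 0.3
    lo_lon, hi_lon = grid.lon_min + margin, grid.lon_max - margin
    lo_lat, hi_lat = grid.lat_min + margin, grid.lat_max - margin
    t_cursor = pd.Timestamp(f"{year}-01-05")
    for v in range(config.n_vessels):
        vid = f"V{v:03d}"
        for trip in range(config.trips_per_vessel):
            tid = f"{vid}-{year}-T{trip:02d}"
            hi = rng.integers(len(harbors))
            h_lon, h_lat = harbors.lons[hi], harbors.lats[hi]
            target = rng.choice(grid.n_cells, p=hotspot_p)
            t_lon = float(np.clip(lon_c[target], lo_lon, hi_lon))
            t_lat = float(np.clip(lat_c[target], lo_lat, hi_lat))

            t0 = t_cursor + pd.Timedelta(hours=float(rng.uniform(0, 6)))
            pings = [(t0, h_lon, h_lat, 0.0, "port")]

            def steam_to(dst_lon, dst_lat, t_now, cur_lon, cur_lat):
                v_kn = float(rng.uniform(*config.steam_speed))
                km_step = v_kn * NM_TO_KM * step_h
                dist = haversine_km(cur_lon, cur_lat, dst_lon, dst_lat)
                n_steps = max(1, int(np.ceil(dist / km_step)))
                for i in range(1, n_steps + 1):
                    frac = i / n_steps
                    t_now = t_now + pd.Timedelta(minutes=10)
                    pings.append((t_now,
                                  cur_lon + frac * (dst_lon - cur_lon),
                                  cur_lat + frac * (dst_lat - cur_lat),
                                  v_kn, "steam"))
                return t_now, dst_lon, dst_lat

            t_now, cur_lon, cur_lat = steam_to(t_lon, t_lat, t0, h_lon, h_lat)

            # trawl random walk over the high-abundance ground; steps that
            # would leave the domain are re-aimed at the domain center so the
            # step length (and hence the speed) is never shortened
            mid_lon = 0.5 * (lo_lon + hi_lon)
            mid_lat = 0.5 * (lo_lat + hi_lat)
            n_tow = int(rng.integers(12, 30))    # 2-5 hours of towing
            heading = float(rng.uniform(0, 2 * np.pi))
            for _ in range(n_tow):
                v_kn = float(rng.uniform(*config.trawl_speed))
                km_step = v_kn * NM_TO_KM * step_h
                heading += float(rng.normal(0.0, 0.35))
                nlon, nlat = _walk(cur_lon, cur_lat, heading, km_step, cur_lat)
                if not (lo_lon < nlon < hi_lon and lo_lat < nlat < hi_lat):
                    heading = float(np.arctan2(mid_lon - cur_lon,
                                               mid_lat - cur_lat))
                    nlon, nlat = _walk(cur_lon, cur_lat, heading, km_step, cur_lat)
                t_now = t_now + pd.Timedelta(minutes=10)
                pings.append((t_now, nlon, nlat, v_kn, "trawl"))
                cur_lon, cur_lat = nlon, nlat

            t_now, _, _ = steam_to(h_lon, h_lat, t_now, cur_lon, cur_lat)
            # store position-consistent speeds (backward difference, first
            # ping forward) so ping tables are internally coherent
            lons = np.array([p[1] for p in pings])
            lats = np.array([p[2] for p in pings])
            seg = haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:])
            spd = np.empty(len(pings))
            spd[1:] = seg / step_h / NM_TO_KM
            spd[0] = spd[1] if len(pings) > 1 else 0.0
            for i, (t, lon, lat, _nominal, state) in enumerate(pings):
                rows.append({"vessel_id": vid, "trip_id": tid, "timestamp": t,
                             "lon": lon, "lat": lat, "speed_kn": float(spd[i]),
                             "year": year, "state": state})
            t_cursor = t_now + pd.Timedelta(hours=10)
    return rows


# ---------------------------------------------------------------------------
# generator entry point
# ---------------------------------------------------------------------------

def generate_world(config: SyntheticWorldConfig) -> WorldBundle:
    """Build a complete synthetic input bundle plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    grid = GridSpec(lon_min=config.lon_min, lat_min=config.lat_min,
                    cell_minutes=config.cell_minutes, n_rows=config.n_rows,
                    n_cols=config.n_cols)
    depth_fn = _depth_function(config)
    pixels, dbar, dsd = _bathymetry(grid, config, depth_fn)
    strata, cell_stratum = _assign_strata(dbar, grid)

    lon_ext = grid.lon_max - grid.lon_min
    coast_lat = grid.lat_max - 0.4 * grid.cell_deg
    harbors = HarborSet(
        names=["West Port", "Mid Port", "East Port"],
        lons=[grid.lon_min + f * lon_ext for f in (0.18, 0.5, 0.82)],
        lats=[coast_lat] * 3,
    )

    lon_c, lat_c = grid.cell_centers()
    lat_ext = grid.lat_max - grid.lat_min
    sst = {}
    for yi, year in enumerate(config.years):
        sst[year] = (19.0 + 1.4 * (grid.lat_max - lat_c) / lat_ext
                     + 0.3 * np.sin(2.0 * np.pi * yi / max(len(config.years), 3)))

    truth_ab = _abundance_truth(config, grid, dbar, rng)
    mixtures = _resolved_mixtures(config)
    class_edges = {sp: _class_edges(sp, {k: v for k, v in mixtures.items()
                                         if k[0] == sp})
                   for sp in config.species}
    hauls = _make_hauls(config, grid, strata, cell_stratum, truth_ab,
                        class_edges, rng)

    # effort is attracted by the first species' abundance (plus a floor)
    attract = truth_ab[config.species[0]]["F"].sum(axis=(0, 2))
    hotspot_p = attract ** 2
    hotspot_p = hotspot_p / hotspot_p.sum()

    ping_rows = []
    fishing_counts = {}
    for year in config.years:
        rows = _make_trips(config, grid, harbors, hotspot_p, year, rng)
        ping_rows.extend(rows)
        df = pd.DataFrame(rows)
        # ground truth: pings in a fishing state per the speed criterion
        v_lo, v_hi = config.trawl_speed
        fish = df[(df["speed_kn"] >= v_lo) & (df["speed_kn"] <= v_hi)]
        idx = grid.locate(fish["lon"].to_numpy(), fish["lat"].to_numpy())
        idx = np.atleast_1d(idx)
        fishing_counts[year] = np.bincount(idx[idx >= 0],
                                           minlength=grid.n_cells).astype(np.int64)
    pings = pd.DataFrame(ping_rows)

    # fuel records live on the simulated world's own pattern-score scale so
    # the fitted cost plane interpolates rather than extrapolates
    from trawlsim.grid import mean_distance_to_harbors

    dist3 = mean_distance_to_harbors(grid, harbors, k=3)
    ps_by_year = {}
    for year, counts in fishing_counts.items():
        occ = counts >= 1
        ps_by_year[year] = float(np.sum(np.log10(counts[occ]) * dist3[occ]))
    ps_mean = float(np.mean(list(ps_by_year.values())))

    cost = defaults.DEFAULT_COST_MODEL
    fuel_rows = []
    for year in config.fuel_years:
        ps = ps_by_year.get(year, ps_mean * float(rng.uniform(0.85, 1.15)))
        fuel = float(rng.uniform(0.9, 1.4))
        tc = (cost.beta0 + cost.beta_ps * ps + cost.beta_e * fuel
              + (rng.normal(0.0, config.fuel_noise_sd)
                 if config.fuel_noise_sd > 0 else 0.0))
        fuel_rows.append({"year": year, "PS": ps, "E": fuel, "TC": tc})
    fuel_records = pd.DataFrame(fuel_rows)

    proportions = {}
    for sp in config.species:
        for sex in ("F", "M"):
            K = defaults.N_COHORTS[sp]
            proportions[(sp, sex)] = tuple(
                config.mixture_proportions.get((sp, sex), np.full(K, 1.0 / K)))

    truth = GroundTruth(
        mixtures=mixtures, proportions=proportions, abundance=truth_ab,
        q={sp: defaults.DEFAULT_SPECIES_PARAMS[sp].q for sp in config.species},
        cost_model=cost, trawl_speed=config.trawl_speed,
        steam_speed=config.steam_speed, fishing_counts=fishing_counts,
    )
    return WorldBundle(
        config=config, grid=grid, depth_pixels=pixels, dbar=dbar, dsd=dsd,
        strata=strata, cell_stratum=cell_stratum, harbors=harbors, sst=sst,
        hauls=hauls, pings=pings,
        prices={sp: defaults.DEFAULT_PRICES[sp] for sp in config.species},
        fuel_records=fuel_records, class_edges=class_edges, truth=truth,
    )


# ---------------------------------------------------------------------------
# plain-text writers
# ---------------------------------------------------------------------------

def write_world(bundle: WorldBundle, outdir):
    """Write the bundle as plain CSV tables plus a JSON ground-truth sidecar."""
    import os

    os.makedirs(outdir, exist_ok=True)
    bundle.grid.to_json(os.path.join(outdir, "grid.json"))

    rows = []
    for h in bundle.hauls:
        for lo, hi, d in zip(h.class_edges[:-1], h.class_edges[1:], h.densities):
            if d == 0:
                continue
            rows.append({"station_id": h.station_id, "lon": h.lon, "lat": h.lat,
                         "stratum_id": h.stratum_id, "year": h.year,
                         "species": h.species, "sex": h.sex,
                         "class_lo_mm": lo, "class_hi_mm": hi, "density": d})
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "hauls.csv"), index=False)

    bundle.pings.to_csv(os.path.join(outdir, "pings.csv"), index=False)
    bundle.fuel_records.to_csv(os.path.join(outdir, "fuel.csv"), index=False)

    pd.DataFrame({"name": bundle.harbors.names, "lon": bundle.harbors.lons,
                  "lat": bundle.harbors.lats}).to_csv(
        os.path.join(outdir, "harbors.csv"), index=False)

    price_rows = []
    for sp, sched in bundle.prices.items():
        for lo, hi, price in sched.bands:
            price_rows.append({"species": sp, "lo_mm": lo,
                               "hi_mm": "" if hi is None else hi,
                               "eur_per_kg": price})
    pd.DataFrame(price_rows).to_csv(os.path.join(outdir, "prices.csv"), index=False)

    sst_rows = []
    for year, vals in bundle.sst.items():
        for c, v in enumerate(vals):
            sst_rows.append({"year": year, "cell_id": c, "sst": v})
    pd.DataFrame(sst_rows).to_csv(os.path.join(outdir, "sst.csv"), index=False)

    pix = pd.DataFrame(bundle.depth_pixels)
    pix.insert(0, "cell_id", np.arange(bundle.grid.n_cells))
    pix.to_csv(os.path.join(outdir, "depth_pixels.csv"), index=False)

    bundle.truth.to_json(os.path.join(outdir, "truth.json"))
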