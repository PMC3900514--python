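"""End-to-end orchestration: bundle -> layers -> nets -> economics -> scenarios.

Glue that runs the whole chain on a (synthetic or real-format) input bundle:
survey mixture fits, cohort interpolation, effort mapping, recurrent-net
training, and assembly of the fleet-economics context and the next-year
biomass predictor used by the scenario engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from trawlsim import params as defaults
from trawlsim.economics import FleetEconomics, fit_cost_model, weight_at_length
from trawlsim.effort import pings_to_effort
from trawlsim.elman import EmpnConfig, build_dataset, train
from trawlsim.lfd import cohort_abundance_matrix, fit_mixture, pool_lfd
from trawlsim.synth import WorldBundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    grid: object
    fits: dict                 # (species, sex, year) -> MixtureFit
    cohorts_sexed: dict        # species -> {year: (cells, 2K)}
    cohorts_summed: dict       # species -> {year: (cells, K)}
    effort: dict               # year -> EffortPattern
    env: dict                  # dbar, dsd, sst
    nets: dict = field(default_factory=dict)
    economics: FleetEconomics = None
    datasets: dict = field(default_factory=dict)
    cost_model: object = None

    @property
    def last_year(self) -> int:
        return max(self.effort)


def length_class_index(cohorts_sexed: np.ndarray, fits_by_sex: list,
                       edges: np.ndarray) -> np.ndarray:
    """Distribute cohort abundances over length classes (cells x classes).

    Each sex block's cohort column is spread across the bins with the normal
    bin probabilities of its fitted component.
    """
    out = np.zeros((cohorts_sexed.shape[0], edges.size - 1))
    col = 0
    for fit in fits_by_sex:
        for k in range(fit.K):
            p = np.diff(norm.cdf(edges, fit.means[k], fit.sds[k]))
            out += np.nan_to_num(cohorts_sexed[:, col])[:, None] * p[None, :]
            col += 1
    if col != cohorts_sexed.shape[1]:
        raise ValueError("cohort matrix columns do not match the sex fits")
    return out


def run_pipeline(bundle: WorldBundle, *, mixture_n_init: int = 4,
                 empn: dict = None, train_nets: bool = True,
                 radius_cells: int = 3, seed: int = 0) -> PipelineResult:
    """Run survey, effort and (optionally) predictor stages on a bundle.

    ``empn`` overrides EmpnConfig fields (n_hidden, restarts, max_epochs,
    ...) — tests and desk-scale runs shrink them.
    """
    cfg = bundle.config
    grid = bundle.grid
    years = list(cfg.years)
    sexes = ("F", "M")

    # --- survey: mixture fits and cohort matrices -------------------------
    fits = {}
    for sp in cfg.species:
        K = defaults.N_COHORTS[sp]
        for sex in sexes:
            for year in years:
                lfd = pool_lfd(bundle.hauls, bundle.strata, sp, sex, year)
                fits[(sp, sex, year)] = fit_mixture(
                    lfd, K, n_init=mixture_n_init, seed=seed)

    cohorts_sexed, cohorts_summed = {}, {}
    for sp in cfg.species:
        cohorts_sexed[sp], cohorts_summed[sp] = {}, {}
        for year in years:
            m = cohort_abundance_matrix(bundle.hauls, fits, grid, sp, year,
                                        radius_cells=radius_cells,
                                        split_sexes=True)
            cohorts_sexed[sp][year] = m
            K = defaults.N_COHORTS[sp]
            cohorts_summed[sp][year] = m[:, :K] + m[:, K:]

    # --- effort -----------------------------------------------------------
    effort = {}
    for year in years:
        sub = bundle.pings[bundle.pings["year"] == year]
        effort[year] = pings_to_effort(sub, grid, year,
                                       speed_window=cfg.trawl_speed)

    env = {"dbar": bundle.dbar, "dsd": bundle.dsd, "sst": bundle.sst}

    result = PipelineResult(grid=grid, fits=fits, cohorts_sexed=cohorts_sexed,
                            cohorts_summed=cohorts_summed, effort=effort,
                            env=env)

    # --- predictor ---------------------------------------------------------
    target_year = years[-1]
    n_lags = min(4, len(years) - 1)
    if train_nets:
        empn = dict(empn or {})
        for sp in cfg.species:
            ds = build_dataset(cohorts_sexed[sp], effort, env, grid,
                               target_year=target_year, n_lags=n_lags,
                               species=sp)
            config = EmpnConfig(
                n_inputs=ds.X.shape[2], n_outputs=ds.y.shape[1],
                seed=seed, **empn)
            result.datasets[sp] = ds
            result.nets[sp] = train(ds, config)
            logger.info("%s net: test r = %.3f", sp, result.nets[sp].test_r)

    # --- economics ----------------------------------------------------------
    cost_model = fit_cost_model(bundle.fuel_records)
    # station densities are N/km^2; scale by cell area for per-cell numbers
    from trawlsim.synth import _cell_area_km2

    cell_area = _cell_area_km2(grid)
    species_index, species_mid = {}, {}
    for sp in cfg.species:
        edges = bundle.class_edges[sp]
        fits_by_sex = [fits[(sp, sex, target_year)] for sex in sexes]
        species_index[sp] = cell_area * length_class_index(
            cohorts_sexed[sp][target_year], fits_by_sex, edges)
        species_mid[sp] = 0.5 * (edges[:-1] + edges[1:])
    result.cost_model = cost_model
    result.economics = FleetEconomics(
        grid=grid, species_index=species_index, species_midpoints=species_mid,
        species_params={sp: defaults.DEFAULT_SPECIES_PARAMS[sp]
                        for sp in cfg.species},
        prices=bundle.prices, cost_model=cost_model,
        fuel_price=float(bundle.fuel_records["E"].mean()), harbors=bundle.harbors,
    )
    return result


def make_biomass_predictor(result: PipelineResult, n_lags: int = None):
    """Callable mapping an effort pattern to next-year biomass (tons) per species.

    The pattern replaces the final lag year's effort layer; the trained nets
    then forecast each cohort's per-cell abundance for the following year,
    which is weighed at the fitted cohort mean lengths and summed.
    """
    from trawlsim.elman import predict_cohorts

    years = sorted(result.effort)
    target = years[-1]
    if n_lags is None:
        n_lags = min(4, len(years) - 1)
    lag_years = years[-n_lags:]
    sexes = ("F", "M")

    weights_kg = {}
    for sp, net in result.nets.items():
        w = []
        for sex in sexes:
            fit = result.fits[(sp, sex, target)]
            p = defaults.DEFAULT_SPECIES_PARAMS[sp].sex(sex)
            w.extend(weight_at_length(fit.means, p.a, p.b) / 1000.0)  # kg
        weights_kg[sp] = np.asarray(w)

    def predictor(pattern) -> dict:
        eff = dict(result.effort)
        eff[target] = pattern
        out = {}
        for sp, net in result.nets.items():
            # dummy target year reuses the final layers; only the lag
            # features (with the overridden effort) feed the forecast
            layers = dict(result.cohorts_sexed[sp])
            layers[target + 1] = layers[target]
            ds = build_dataset(layers, eff, result.env, result.grid,
                               target_year=target + 1, n_lags=n_lags,
                               species=sp)
            # reuse the training-time scalers for a like-for-like forecast
            raw_X = ds.x_scaler.inverse(ds.X)
            Xs = net.x_scaler.transform(raw_X)
            pred = predict_cohorts(net, Xs)
            out[sp] = float(np.sum(pred @ weights_kg[sp]) / 1000.0)  # tons
        return out

    return predictor
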