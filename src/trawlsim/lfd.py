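"""Survey length-frequency analysis.

Stratified abundance indices from haul records, EM decomposition of binned
length-frequency distributions into normal cohort components,
Kolmogorov-Smirnov fit diagnostics, and allocation of station abundances to
cohorts for spatial interpolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import kolmogorov
from scipy.stats import norm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StratumSpec:
    """One depth stratum of the stratified random survey design."""

    stratum_id: int
    depth_min: float
    depth_max: float
    area_km2: float

    def __post_init__(self):
        if self.area_km2 <= 0:
            raise ValueError(f"stratum {self.stratum_id}: area must be > 0")
        if self.depth_max <= self.depth_min:
            raise ValueError(f"stratum {self.stratum_id}: empty depth range")


@dataclass
class HaulRecord:
    """One survey haul with densities standardized to N/km^2 per length class."""

    station_id: str
    lon: float
    lat: float
    stratum_id: int
    year: int
    species: str
    sex: str
    class_edges: np.ndarray        # (L+1,) mm
    densities: np.ndarray          # (L,) N/km^2

    def __post_init__(self):
        self.class_edges = np.asarray(self.class_edges, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.size != self.class_edges.size - 1:
            raise ValueError("densities must have one value per length class")
        if (self.densities < 0).any():
            raise ValueError("densities must be >= 0")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.class_edges[:-1] + self.class_edges[1:])

    @property
    def total(self) -> float:
        return float(self.densities.sum())


@dataclass
class LFD:
    """Binned length-frequency distribution (contiguous classes, counts >= 0)."""

    species: str
    sex: str
    year: int
    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.edges.size - 1:
            raise ValueError("counts must have one value per class")
        if (np.diff(self.edges) <= 0).any():
            raise ValueError("class edges must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_sample(cls, lengths, width: float, species="", sex="", year=0) -> "LFD":
        lengths = np.asarray(lengths, dtype=float)
        lo = np.floor(lengths.min() / width) * width
        hi = np.ceil(lengths.max() / width) * width
        edges = np.arange(lo, hi + width, width)
        counts, _ = np.histogram(lengths, bins=edges)
        return cls(species=species, sex=sex, year=year, edges=edges,
                   counts=counts.astype(float))


@dataclass
class MixtureFit:
    """Normal-mixture cohort decomposition, components ordered by mean."""

    proportions: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    converged: bool
    identifiable: bool = True
    n_iter: int = 0

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (self.proportions.size == self.means.size == self.sds.size):
            raise ValueError("component arrays must have equal length")
        if (self.proportions <= 0).any() or abs(self.proportions.sum() - 1) > 1e-6:
            raise ValueError("proportions must be > 0 and sum to 1")
        if (self.sds <= 0).any():
            raise ValueError("sds must be > 0")

    @property
    def K(self) -> int:
        return self.means.size

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.sum(self.proportions[:, None]
                      * norm.pdf(x[None, :], self.means[:, None], self.sds[:, None]),
                      axis=0)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.sum(self.proportions[:, None]
                      * norm.cdf(x[None, :], self.means[:, None], self.sds[:, None]),
                      axis=0)

    def to_json(self, path=None) -> str:
        payload = {
            "proportions": self.proportions.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "identifiable": self.identifiable,
            "n_iter": self.n_iter,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "MixtureFit":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(**payload)


# ---------------------------------------------------------------------------
# stratified abundance
# ---------------------------------------------------------------------------

def stratified_abundance_by_class(hauls, strata) -> np.ndarray:
    """Design-based abundance per length class: sum_i A_i * mean density in i.

    Strata with no hauls are excluded with a warning (their contribution is
    undefined without observations).  The caller pre-filters ``hauls`` to a
    single species/sex/year.
    """
    hauls = list(hauls)
    if not hauls:
        raise ValueError("no hauls supplied")
    edges = hauls[0].class_edges
    strata_by_id = {s.stratum_id: s for s in strata}
    for h in hauls:
        if h.stratum_id not in strata_by_id:
            raise KeyError(f"haul {h.station_id} references unknown stratum "
                           f"{h.stratum_id}")
        if not np.array_equal(h.class_edges, edges):
            raise ValueError("all hauls must share the same length classes")
    N = np.zeros(edges.size - 1)
    seen = set()
    for sid, spec in strata_by_id.items():
        dens = [h.densities for h in hauls if h.stratum_id == sid]
        if not dens:
            logger.warning("stratum %s has no hauls; excluded from the index", sid)
            continue
        seen.add(sid)
        N += spec.area_km2 * np.mean(dens, axis=0)
    if not seen:
        raise ValueError("no stratum has any haul")
    return N


def stratified_abundance(hauls, strata, species: str, length_class: int,
                         year: int, sex=None) -> float:
    """Total abundance N for one species/length-class/year."""
    sel = [h for h in hauls
           if h.species == species and h.year == year
           and (sex is None or h.sex == sex)]
    return float(stratified_abundance_by_class(sel, strata)[length_class])


# ---------------------------------------------------------------------------
# EM mixture fitting on binned data
# ---------------------------------------------------------------------------

_SD_FLOOR_FRAC = 0.3   # sd floor as a fraction of the bin width


def _em_once(mid, cnt, widths, pi, mu, sd, max_iter, tol, binned_likelihood):
    """One EM run from a given start; returns (pi, mu, sd, loglik, converged, it)."""
    total = cnt.sum()
    sd_floor = _SD_FLOOR_FRAC * widths.min()
    prev_ll = -np.inf
    converged = False
    it = 0
    edges_lo = mid - widths / 2.0
    edges_hi = mid + widths / 2.0
    for it in range(1, max_iter + 1):
        if binned_likelihood:
            comp = (norm.cdf(edges_hi[None, :], mu[:, None], sd[:, None])
                    - norm.cdf(edges_lo[None, :], mu[:, None], sd[:, None]))
        else:
            comp = norm.pdf(mid[None, :], mu[:, None], sd[:, None]) * widths[None, :]
        comp = np.maximum(comp, 1e-300)
        weighted = pi[:, None] * comp
        denom = weighted.sum(axis=0)
        ll = float(np.sum(cnt * np.log(denom)))
        # EM guarantees monotone likelihood; tolerate tiny float noise only
        assert ll >= prev_ll - 1e-6 * max(1.0, abs(prev_ll)), \
            "EM log-likelihood decreased"
        resp = weighted / denom[None, :]
        nk = resp @ cnt
        pi = nk / total
        mu_new = (resp @ (cnt * mid)) / nk
        var = (resp @ (cnt * mid ** 2)) / nk - mu_new ** 2
        sd = np.sqrt(np.maximum(var, sd_floor ** 2))
        mu = mu_new
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return pi, mu, sd, prev_ll, converged, it


def fit_mixture(lfd: LFD, K: int, init: MixtureFit = None, *, n_init: int = 10,
                max_iter: int = 2000, tol: float = 1e-10, seed: int = 0,
                binned_likelihood: bool = False) -> MixtureFit:
    """Fit a K-component normal mixture to a binned LFD by EM.

    The default E-step approximates the bin mass by the component density at
    the bin midpoint times the bin width; ``binned_likelihood=True`` switches
    to exact CDF-difference bin masses.  Multiple random initializations are
    run and the best log-likelihood kept; non-convergence is flagged on the
    returned fit rather than raised.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if lfd.total <= 0:
        raise ValueError("LFD has zero total count")
    mid = lfd.midpoints
    cnt = lfd.counts
    widths = np.diff(lfd.edges)
    rng = np.random.default_rng(seed)

    mean_all = float(np.average(mid, weights=cnt))
    sd_all = float(np.sqrt(np.average((mid - mean_all) ** 2, weights=cnt)))
    sd_all = max(sd_all, _SD_FLOOR_FRAC * widths.min())

    starts = []
    if init is not None:
        if init.K != K:
            raise ValueError("init has a different number of components")
        starts.append((init.proportions.copy(), init.means.copy(), init.sds.copy()))
    n_default = max(n_init, 0 if starts else 1)   # init-only when n_init == 0
    if K == 1:
        if len(starts) < n_default:
            starts.append((np.ones(1), np.array([mean_all]), np.array([sd_all])))
    else:
        if len(starts) < n_default:
            # quantile-spread start first, then random restarts
            qs = np.linspace(0.1, 0.9, K)
            cum = np.cumsum(cnt) / cnt.sum()
            q_means = np.interp(qs, cum, mid)
            starts.append((np.full(K, 1.0 / K), q_means, np.full(K, sd_all / K)))
        probs = cnt / cnt.sum()
        while len(starts) < n_default:
            mu0 = np.sort(rng.choice(mid, size=K, replace=False, p=probs)
                          + rng.normal(0, widths.min(), K))
            starts.append((np.full(K, 1.0 / K), mu0, np.full(K, sd_all / K)))

    best = None
    for pi0, mu0, sd0 in starts:
        pi, mu, sd, ll, conv, it = _em_once(
            mid, cnt, widths, pi0.copy(), np.asarray(mu0, float).copy(),
            np.asarray(sd0, float).copy(), max_iter, tol, binned_likelihood)
        if best is None or ll > best[3]:
            best = (pi, mu, sd, ll, conv, it)

    pi, mu, sd, ll, conv, it = best
    order = np.argsort(mu)
    pi, mu, sd = pi[order], mu[order], sd[order]
    # non-identifiable when two components coincide
    identifiable = True
    for i in range(K - 1):
        if abs(mu[i + 1] - mu[i]) < 1e-6 and abs(sd[i + 1] - sd[i]) < 1e-6:
            identifiable = False
            logger.warning("mixture fit is non-identifiable: components %d and %d "
                           "coincide", i, i + 1)
    if not conv:
        logger.warning("EM did not converge in %d iterations", max_iter)
    pi = np.maximum(pi, 1e-12)
    pi = pi / pi.sum()
    return MixtureFit(proportions=pi, means=mu, sds=sd, loglik=ll,
                      converged=conv, identifiable=identifiable, n_iter=it)


def mixture_standard_errors(lfd: LFD, fit: MixtureFit,
                            binned_likelihood: bool = False) -> dict:
    """Standard errors of the fitted mixture parameters.

    Asymptotic s.e. from the inverse observed information (numerical Hessian
    of the binned log-likelihood at the fit), the same notion grouped-data
    mixture fitters report.  Parameters are packed as (p_1..p_{K-1}, means,
    log sds).  Returns dict with "proportions", "means", "sds" arrays.
    """
    mid = lfd.midpoints
    cnt = lfd.counts
    widths = np.diff(lfd.edges)
    K = fit.K
    lo_e = lfd.edges[:-1]
    hi_e = lfd.edges[1:]

    def nll(theta):
        p = np.empty(K)
        p[:K - 1] = theta[:K - 1]
        p[K - 1] = 1.0 - p[:K - 1].sum()
        mu = theta[K - 1:2 * K - 1]
        sd = np.exp(theta[2 * K - 1:])
        if (p <= 0).any() or (sd <= 0).any():
            return np.inf
        if binned_likelihood:
            comp = (norm.cdf(hi_e[None, :], mu[:, None], sd[:, None])
                    - norm.cdf(lo_e[None, :], mu[:, None], sd[:, None]))
        else:
            comp = norm.pdf(mid[None, :], mu[:, None], sd[:, None]) * widths[None, :]
        dens = np.maximum(p @ comp, 1e-300)
        return -float(np.sum(cnt * np.log(dens)))

    theta0 = np.concatenate([fit.proportions[:K - 1], fit.means,
                             np.log(fit.sds)])
    n = theta0.size
    h = 1e-4 * np.maximum(np.abs(theta0), 1e-2)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                nll(theta0 + ei + ej) - nll(theta0 + ei - ej)
                - nll(theta0 - ei + ej) + nll(theta0 - ei - ej)
            ) / (4.0 * h[i] * h[j])
    cov = np.linalg.pinv(H)
    var = np.clip(np.diag(cov), 0.0, None)
    se = np.sqrt(var)
    # delta method for sd (parametrized as log sd)
    return {
        "proportions": se[:K - 1],
        "means": se[K - 1:2 * K - 1],
        "sds": se[2 * K - 1:] * fit.sds,
    }


def ks_distance(lfd: LFD, fit: MixtureFit, alpha: float = 0.05):
    """Sup distance between the binned empirical CDF and the mixture CDF.

    Evaluated over all bin edges (the empirical CDF only jumps there).  The
    decision uses the asymptotic Kolmogorov distribution with the LFD total
    as effective sample size; used descriptively (no correction for
    estimated parameters).
    """
    if lfd.total <= 0:
        raise ValueError("empty LFD")
    # the binned ECDF is known exactly at the class edges (0 at the first,
    # the cumulative share at every other); compare there
    ecdf = np.concatenate([[0.0], np.cumsum(lfd.counts) / lfd.total])
    model = fit.cdf(lfd.edges)
    D = float(np.max(np.abs(ecdf - model)))
    n = lfd.total
    pvalue = float(kolmogorov(np.sqrt(n) * D))
    return D, {"reject": pvalue < alpha, "pvalue": pvalue, "alpha": alpha, "n": n}


def responsibilities(x, fit: MixtureFit) -> np.ndarray:
    """Posterior component probabilities pi_h phi_h(x) at points x, (len(x), K).

    Points where every component density vanishes are split equally with a
    warning.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    dens = fit.proportions[None, :] * norm.pdf(x[:, None], fit.means[None, :],
                                               fit.sds[None, :])
    tot = dens.sum(axis=1)
    dead = tot <= 0
    if dead.any():
        logger.warning("all component densities vanish at %d point(s); "
                       "splitting equally", int(dead.sum()))
        dens[dead] = 1.0
        tot[dead] = fit.K
    return dens / tot[:, None]


def allocate_cohorts(haul: HaulRecord, fit: MixtureFit) -> np.ndarray:
    """Cohort abundances at one station: class counts split by posterior weight.

    Conserves the haul total exactly: the per-class density is distributed
    across components proportionally to pi_h phi_h at the class midpoint.
    """
    resp = responsibilities(haul.midpoints, fit)
    return haul.densities @ resp


def allocate_lfd(lfd: LFD, fit: MixtureFit) -> np.ndarray:
    """Per-class x cohort allocation matrix for a pooled LFD."""
    resp = responsibilities(lfd.midpoints, fit)
    return lfd.counts[:, None] * resp


def biomass_layer(cohorts, fit: MixtureFit, a: float, b: float, grid,
                  name: str = "biomass", year: int = 0):
    """Per-cell biomass (tons) from a cells x cohorts abundance matrix.

    Each cohort's individuals are weighed at the cohort mean length with the
    length-weight law w = a*L^b (grams), then converted grams -> tons.
    """
    from trawlsim.economics import weight_at_length
    from trawlsim.grid import CellLayer

    cohorts = np.asarray(cohorts, dtype=float)
    if (fit.means < 0).any():
        raise ValueError("negative mean length")
    w_g = weight_at_length(fit.means, a, b)
    tons = cohorts @ w_g / 1e6
    return CellLayer(grid=grid, name=name, year=year, values=tons)


# ---------------------------------------------------------------------------
# station-to-grid pipeline
# ---------------------------------------------------------------------------

def pool_lfd(hauls, strata, species: str, sex: str, year: int) -> LFD:
    """Stratified-index LFD for one species/sex/year."""
    sel = [h for h in hauls if h.species == species and h.sex == sex
           and h.year == year]
    N = stratified_abundance_by_class(sel, strata)
    return LFD(species=species, sex=sex, year=year, edges=sel[0].class_edges,
               counts=N)


def cohort_abundance_matrix(hauls, fits: dict, grid, species: str, year: int,
                            radius_cells: int = 3, power: float = 2.0,
                            split_sexes: bool = False):
    """Cells x cohorts abundance matrix via IDW interpolation.

    ``fits`` maps (species, sex, year) -> MixtureFit.  Station cohort
    abundances are interpolated one cohort at a time; the returned matrix
    carries NaN rows for cells outside every station neighborhood.  By
    default the sexes are summed (K columns); with ``split_sexes=True`` each
    sex keeps its own block of K columns, ordered by sex code.
    """
    from trawlsim.grid import idw_interpolate

    sexes = sorted({h.sex for h in hauls if h.species == species and h.year == year})
    if not sexes:
        raise ValueError(f"no hauls for {species} in {year}")
    K = fits[(species, sexes[0], year)].K
    n_cols = K * len(sexes) if split_sexes else K
    per_station = {}
    for xi, sex in enumerate(sexes):
        fit = fits[(species, sex, year)]
        if fit.K != K:
            raise ValueError("all sexes must use the same number of cohorts")
        off = xi * K if split_sexes else 0
        for h in hauls:
            if h.species != species or h.sex != sex or h.year != year:
                continue
            key = (h.lon, h.lat)
            per_station.setdefault(key, np.zeros(n_cols))
            per_station[key][off:off + K] += allocate_cohorts(h, fit)
    matrix = np.full((grid.n_cells, n_cols), np.nan)
    for k in range(n_cols):
        stations = [(lon, lat, v[k]) for (lon, lat), v in per_station.items()]
        layer = idw_interpolate(stations, grid, radius_cells=radius_cells,
                                power=power, name=f"{species}_cohort{k}", year=year)
        matrix[:, k] = layer.values
    return matrix
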