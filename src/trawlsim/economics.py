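"""Deterministic bio-economic engine.

Maps (abundance layers, effort pattern) to spatial fishing mortality,
catches by length class, harvested biomass, revenue, fuel cost, gains and
overall fishing mortality per species.  All lengths in mm, weights from the
length-weight power law in grams, harvested biomass in kg, money in euros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

LN3 = np.log(3.0)
GRAMS_PER_KG = 1000.0
KG_PER_TON = 1000.0


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexParams:
    """Per-sex growth, mortality and length-weight constants."""

    linf: float   # mm
    k: float      # 1/yr
    t0: float     # yr
    M: float      # natural mortality 1/yr (carried, not used by the catch equations)
    a: float      # length-weight coefficient (grams for L in mm)
    b: float      # length-weight exponent

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("length-weight exponent b must be > 0")


@dataclass(frozen=True)
class SpeciesParams:
    """Biology/fishery constants for one species (both sexes)."""

    code: str
    male: SexParams
    female: SexParams
    L50: float          # mm, 50% retention length of the trawl codend
    L75: float          # mm, 75% retention length
    q: float            # commercial-fleet catchability per fishing point
    qM: float           # survey-gear catchability (relative -> absolute)
    F_lca_mean: float   # reference total fishing mortality
    F_lca_sd: float

    def __post_init__(self):
        if not (self.L75 > self.L50 > 0):
            raise ValueError(f"{self.code}: need L75 > L50 > 0")
        if self.q <= 0:
            raise ValueError(f"{self.code}: catchability q must be > 0")
        if not (0 < self.qM <= 1):
            raise ValueError(f"{self.code}: survey catchability qM must be in (0, 1]")

    def sex(self, code: str) -> SexParams:
        return self.female if code.upper().startswith("F") else self.male


class PriceSchedule:
    """Ordered commercial size bands (mm) mapped to prices (euros/kg)."""

    def __init__(self, species: str, bands):
        self.species = species
        self.bands = []
        prev_hi = None
        for lo, hi, price in bands:
            if price <= 0:
                raise ValueError(f"{species}: prices must be > 0")
            if hi is not None and hi <= lo:
                raise ValueError(f"{species}: empty price band [{lo}, {hi})")
            if prev_hi is not None and lo != prev_hi:
                raise ValueError(f"{species}: price bands must be contiguous")
            prev_hi = hi
            self.bands.append((float(lo), None if hi is None else float(hi),
                               float(price)))
        if self.bands[-1][1] is not None:
            # closed top band: lengths beyond it are unpriced by design
            pass

    def price_for(self, length_mm: float) -> float:
        for lo, hi, price in self.bands:
            if length_mm >= lo and (hi is None or length_mm < hi):
                return price
        raise KeyError(
            f"no price band covers species {self.species} length {length_mm} mm"
        )

    def prices(self, lengths_mm) -> np.ndarray:
        return np.array([self.price_for(l) for l in np.atleast_1d(lengths_mm)])


@dataclass
class CostModel:
    """Linear fleet fuel-cost model TC = beta0 + beta_ps*PS + beta_e*E."""

    beta0: float
    beta_ps: float
    beta_e: float
    fitted: bool = False
    stderr: dict = field(default_factory=dict)
    tvalues: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)
    singular: bool = False


@dataclass
class CatchMatrix:
    """Per cell x length class catches for one species.

    ``standing`` are absolute standing numbers (survey index times qM),
    ``numbers`` the catch in individuals, ``biomass_kg`` the harvested
    biomass.
    """

    species: str
    midpoints: np.ndarray        # (L,) mm
    standing: np.ndarray         # (cells, L)
    numbers: np.ndarray          # (cells, L)
    biomass_kg: np.ndarray       # (cells, L)

    def __post_init__(self):
        if (self.numbers - self.standing > 1e-9).any():
            raise ValueError("catch cannot exceed standing numbers")
        if (self.numbers < 0).any() or (self.standing < 0).any():
            raise ValueError("catches and standing numbers must be >= 0")

    def total_numbers(self) -> float:
        return float(self.numbers.sum())

    def total_biomass_kg(self) -> float:
        return float(self.biomass_kg.sum())

    def to_dataframe(self):
        import pandas as pd

        cells, classes = np.nonzero(np.ones_like(self.numbers, dtype=bool))
        return pd.DataFrame({
            "species": self.species,
            "cell_id": cells,
            "length_class_mm": self.midpoints[classes],
            "numbers": self.numbers[cells, classes],
            "kg": self.biomass_kg[cells, classes],
        })


# ---------------------------------------------------------------------------
# elementary relationships
# ---------------------------------------------------------------------------

def selectivity(l, L50: float, L75: float):
    """Logistic codend retention fraction at length ``l`` (mm).

    The steepness is fixed by the two quantile conditions S(L50)=0.5 and
    S(L75)=0.75, i.e. a = ln 3 / (L75 - L50).
    """
    if not L75 > L50:
        raise ValueError("need L75 > L50")
    a = LN3 / (L75 - L50)
    z = np.clip(a * (np.asarray(l, dtype=float) - L50), -500, 500)
    return 1.0 / (1.0 + np.exp(-z))


def weight_at_length(l_mm, a: float, b: float) -> np.ndarray:
    """Length-weight power law w = a * L**b, grams for L in mm."""
    l_mm = np.asarray(l_mm, dtype=float)
    if (l_mm < 0).any():
        raise ValueError("length must be >= 0")
    return a * l_mm ** b


def length_at_age(age_yr, linf: float, k: float, t0: float) -> np.ndarray:
    """Von Bertalanffy length-at-age (mm); bookkeeping helper."""
    return linf * (1.0 - np.exp(-k * (np.asarray(age_yr, dtype=float) - t0)))


def spatial_f(q: float, sel, effort_counts):
    """Spatial fishing mortality f = q * S_l * e_c (cells x classes)."""
    sel = np.atleast_1d(np.asarray(sel, dtype=float))
    e = np.atleast_1d(np.asarray(effort_counts, dtype=float))
    if (e < 0).any():
        raise ValueError("effort counts must be >= 0")
    return q * e[:, None] * sel[None, :]


def estimate_q_from_catches(ref_catches, density, effort) -> float:
    """Catchability minimizing || ref_c - q*e_c*n_c ||^2 over q (1-D numeric)."""
    r = np.asarray(ref_catches, dtype=float)
    n = np.asarray(density, dtype=float)
    e = np.asarray(effort, dtype=float)
    if not (r.shape == n.shape == e.shape):
        raise ValueError("reference catches, density and effort must align")
    if not ((n > 0) & (e > 0)).any():
        raise ValueError("q is unidentifiable: no cell with positive density and effort")

    def sse(q):
        d = r - q * e * n
        return float(d @ d)

    q0 = float(np.sum(r * e * n) / np.sum((e * n) ** 2))
    res = minimize_scalar(sse, bracket=(0.0, max(2.0 * q0, 1e-12)))
    return float(res.x)


def estimate_q(F_s: float, density, effort) -> float:
    """Catchability minimizing || F_s*n_c - q*e_c*n_c ||^2 over q.

    Reference (theoretical) catches are F_s times the per-cell density; the
    minimizer coincides with the weighted-least-squares closed form
    ``q* = F_s * sum(n^2 e) / sum(n^2 e^2)``.
    """
    n = np.asarray(density, dtype=float)
    return estimate_q_from_catches(F_s * n, n, effort)


def closed_form_q(F_s: float, density, effort) -> float:
    """WLS solution of the q-estimation objective (independent oracle)."""
    n = np.asarray(density, dtype=float)
    e = np.asarray(effort, dtype=float)
    denom = np.sum(n ** 2 * e ** 2)
    if denom == 0:
        raise ValueError("q is unidentifiable: all effort zero where density > 0")
    return float(F_s * np.sum(n ** 2 * e) / denom)


def medits_catchability(N_lca: float, N_swept: float) -> float:
    """Survey-gear catchability: absolute (assessment) over swept-area numbers."""
    if N_swept <= 0:
        raise ValueError("swept-area standing stock must be > 0")
    qM = N_lca / N_swept
    if qM > 1:
        logger.warning("survey catchability %.3f > 1 (herding exceeds escapement)", qM)
    return float(qM)


# ---------------------------------------------------------------------------
# catches, revenue, costs
# ---------------------------------------------------------------------------

def catches(index, midpoints, qM: float, f, weight_fn, species: str = "",
            f_cap: float = 1.0) -> CatchMatrix:
    """Catch matrix from relative abundance indices and spatial mortality.

    ``index`` is the (cells x classes) survey abundance index; standing
    numbers are ``qM * index``; catch is ``n * min(f, f_cap)`` (harvest rate
    capped so catches never exceed standing numbers); harvested biomass uses
    the length-weight law evaluated at the class midpoint.
    """
    index = np.asarray(index, dtype=float)
    f = np.asarray(f, dtype=float)
    midpoints = np.asarray(midpoints, dtype=float)
    if index.shape != f.shape:
        raise ValueError("abundance index and f must be aligned on the grid")
    over = f > f_cap
    if over.any():
        cells = np.unique(np.nonzero(over)[0])
        logger.warning("harvest rate > %.2f capped in %d cell(s): %s",
                       f_cap, cells.size, cells[:10].tolist())
    n = qM * index
    c = n * np.minimum(f, f_cap)
    w_kg = weight_fn(midpoints) / GRAMS_PER_KG
    h = c * w_kg[None, :]
    return CatchMatrix(species=species, midpoints=midpoints, standing=n,
                       numbers=c, biomass_kg=h)


def revenue(catch: CatchMatrix, prices: PriceSchedule) -> float:
    """Total revenue in euros: sum over classes of kg landed times price."""
    p = prices.prices(catch.midpoints)   # raises on unpriced class
    return float(np.sum(catch.biomass_kg.sum(axis=0) * p))


def fit_cost_model(records) -> CostModel:
    """OLS of total fuel cost on (1, pattern score, fuel price).

    ``records`` is a DataFrame-like with columns PS, E, TC (one row per
    year); at least 4 records are required to fit 3 parameters.
    """
    import pandas as pd
    import statsmodels.api as sm

    df = pd.DataFrame(records)
    if len(df) < 4:
        raise ValueError("at least 4 records are required to fit the cost model")
    X = sm.add_constant(df[["PS", "E"]].astype(float), has_constant="add")
    singular = np.linalg.matrix_rank(X.to_numpy()) < 3
    if singular:
        logger.warning("cost model design matrix is singular (collinear PS/E)")
    fit = sm.OLS(df["TC"].astype(float), X).fit()
    params = fit.params
    return CostModel(
        beta0=float(params["const"]), beta_ps=float(params["PS"]),
        beta_e=float(params["E"]), fitted=True,
        stderr=dict(fit.bse), tvalues=dict(fit.tvalues),
        pvalues=dict(fit.pvalues), singular=singular,
    )


def predict_cost(model: CostModel, ps: float, fuel_price: float) -> float:
    """TC = beta0 + beta_ps*PS + beta_e*E."""
    return model.beta0 + model.beta_ps * ps + model.beta_e * fuel_price


def gains(revenue_eur: float, total_cost_eur: float) -> float:
    return revenue_eur - total_cost_eur


def total_F(catch: CatchMatrix) -> float:
    """Overall fishing mortality: total catch over total standing numbers."""
    denom = catch.standing.sum()
    if denom <= 0:
        raise ValueError("total standing abundance is zero; F undefined")
    return float(catch.numbers.sum() / denom)


# ---------------------------------------------------------------------------
# fleet-level evaluation context
# ---------------------------------------------------------------------------

class FleetEconomics:
    """Bundles everything needed to score an effort pattern with G = R - TC.

    Parameters
    ----------
    grid : GridSpec
    species_index : dict species -> (cells x classes) survey abundance index
    species_midpoints : dict species -> class midpoints (mm)
    species_params : dict species -> SpeciesParams
    prices : dict species -> PriceSchedule
    cost_model : CostModel
    fuel_price : float
        Scenario fuel price E held constant during optimization.
    harbors : HarborSet
    weight_sex : str
        Sex whose length-weight law converts class midpoints to weights
        (cohort matrices are sex-summed; default female).
    """

    def __init__(self, grid, species_index, species_midpoints, species_params,
                 prices, cost_model, fuel_price, harbors, weight_sex="F"):
        from trawlsim.grid import mean_distance_to_harbors

        self.grid = grid
        self.species_index = {s: np.asarray(v, dtype=float)
                              for s, v in species_index.items()}
        self.species_midpoints = {s: np.asarray(v, dtype=float)
                                  for s, v in species_midpoints.items()}
        self.species_params = species_params
        self.prices = prices
        self.cost_model = cost_model
        self.fuel_price = fuel_price
        self.harbors = harbors
        self.dist3 = mean_distance_to_harbors(grid, harbors, k=3)
        self._sel = {}
        self._price_vec = {}
        self._w_kg = {}
        for s, mids in self.species_midpoints.items():
            p = self.species_params[s]
            self._sel[s] = selectivity(mids, p.L50, p.L75)
            self._price_vec[s] = prices[s].prices(mids)
            sx = p.sex(weight_sex)
            self._w_kg[s] = weight_at_length(mids, sx.a, sx.b) / GRAMS_PER_KG

    def catch_for(self, species: str, pattern) -> CatchMatrix:
        p = self.species_params[species]
        f = spatial_f(p.q, self._sel[species], pattern.counts)
        mids = self.species_midpoints[species]
        w_kg = self._w_kg[species]
        return catches(self.species_index[species], mids, p.qM, f,
                       lambda L: w_kg * GRAMS_PER_KG, species=species)

    def evaluate(self, pattern) -> dict:
        """Revenue, cost, gains, pattern score and F_s for one effort pattern."""
        from trawlsim.grid import pattern_score

        R = 0.0
        F = {}
        for s in self.species_index:
            cm = self.catch_for(s, pattern)
            R += float(np.sum(cm.biomass_kg.sum(axis=0) * self._price_vec[s]))
            F[s] = total_F(cm)
        ps = pattern_score(pattern, self.harbors, dist3=self.dist3)
        tc = predict_cost(self.cost_model, ps, self.fuel_price)
        return {"R": R, "TC": tc, "G": R - tc, "PS": ps, "F": F}

    def gains_of(self, pattern) -> float:
        return self.evaluate(pattern)["G"]
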