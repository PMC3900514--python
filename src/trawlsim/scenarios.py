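"""Effort-management scenario simulation.

Two scenario families over a baseline effort pattern: global scaling of the
total number of fishing points with cell probabilities fixed, and nursery-box
closures that zero the closed cells' probabilities and renormalize the rest.
Each run proposes multinomial effort patterns and hill-climbs on fleet gains;
the optimized pattern is then scored by gains, next-year biomass (via the
trained recurrent nets), overall fishing mortality per species, and pattern
score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from trawlsim.effort import EffortPattern

logger = logging.getLogger(__name__)

SCALING_LEVELS = (0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3)


@dataclass(frozen=True)
class BoxDefinition:
    """A named set of grid cells closed to trawling."""

    label: str
    cells: tuple

    def __post_init__(self):
        object.__setattr__(self, "cells", tuple(int(c) for c in self.cells))

    def validate(self, grid):
        cells = np.asarray(self.cells)
        if cells.size and (cells.min() < 0 or cells.max() >= grid.n_cells):
            raise ValueError(f"box {self.label}: cell ids outside the grid")


@dataclass
class ScenarioConfig:
    kind: str                      # "effort_scaling" | "box_closure"
    level: float = 1.0             # scaling factor (effort_scaling only)
    boxes: list = None             # list of BoxDefinition (box_closure only)
    runs: int = 100
    stop_k: int = 100
    seed: int = 0
    fuel_price: float = 1.0

    def __post_init__(self):
        if self.kind not in ("effort_scaling", "box_closure"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "box_closure" and not self.boxes:
            raise ValueError("box_closure scenario needs at least one box")
        if self.kind == "effort_scaling" and self.boxes:
            raise ValueError("exactly one scenario type may be active")
        if self.runs < 1 or self.stop_k < 1:
            raise ValueError("runs and stop_k must be >= 1")


@dataclass
class RunResult:
    pattern: EffortPattern
    G: float
    R: float
    TC: float
    PS: float
    F: dict
    B_next: dict
    iterations: int
    seed: int


def baseline_probabilities(observed: EffortPattern) -> np.ndarray:
    """Per-cell probabilities from observed fishing-point frequencies."""
    counts = np.asarray(observed.counts, dtype=float)
    tf = counts.sum()
    if tf <= 0:
        raise ValueError("observed pattern has no fishing points")
    return counts / tf


def closure_transform(p: np.ndarray, box: BoxDefinition) -> np.ndarray:
    """Zero the box cells and renormalize the remaining probabilities.

    Redistributes the closed cells' effort share proportionally over the
    open cells.
    """
    p = np.asarray(p, dtype=float)
    cells = np.asarray(box.cells, dtype=int)
    inside = p[cells].sum() if cells.size else 0.0
    if inside >= 1.0 - 1e-12:
        raise ValueError(f"box {box.label} covers all fishing effort")
    out = p.copy()
    out[cells] = 0.0
    out /= 1.0 - inside
    return out


def merge_boxes(boxes) -> BoxDefinition:
    cells = sorted({c for b in boxes for c in b.cells})
    label = "+".join(b.label for b in boxes)
    return BoxDefinition(label=label, cells=tuple(cells))


def sample_pattern(p: np.ndarray, tf: int, rng, grid, year: int = 0) -> EffortPattern:
    """One multinomial draw of tf fishing points over the grid cells."""
    p = np.asarray(p, dtype=float)
    if tf < 0:
        raise ValueError("Tf must be >= 0")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    counts = rng.multinomial(int(tf), p)
    return EffortPattern(grid=grid, year=year, counts=counts)


def hill_climb_run(start: EffortPattern, p: np.ndarray, tf: int, gains_fn,
                   stop_k: int = 100, rng=None, seed: int = 0) -> tuple:
    """Gain-maximizing stochastic search over multinomial effort patterns.

    Proposals are fresh multinomial draws; a proposal is accepted iff its
    gains strictly exceed the incumbent's.  The run ends when ``stop_k``
    consecutive proposals fail to improve.  Returns (incumbent pattern,
    incumbent G, iterations, accepted-G trace).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    incumbent = start
    g_inc = gains_fn(incumbent)
    trace = [g_inc]
    iterations = 0
    rejected = 0
    while rejected < stop_k:
        proposal = sample_pattern(p, tf, rng, start.grid, year=start.year)
        iterations += 1
        g_new = gains_fn(proposal)
        if g_new > g_inc:
            incumbent, g_inc = proposal, g_new
            trace.append(g_inc)
            rejected = 0
        else:
            rejected += 1
    return incumbent, g_inc, iterations, trace


def run_scenario(config: ScenarioConfig, observed: EffortPattern, economics,
                 biomass_predictor=None) -> pd.DataFrame:
    """Simulate one scenario configuration.

    Parameters
    ----------
    config : ScenarioConfig
    observed : EffortPattern
        Baseline (last observed year) pattern; supplies Tf and the cell
        probabilities.
    economics : FleetEconomics
        Deterministic gains evaluation for candidate patterns.
    biomass_predictor : callable, optional
        ``f(EffortPattern) -> dict species -> next-year biomass (tons)``
        built from the trained nets; omitted entries yield NaN columns.

    Returns a tidy DataFrame with one row per run (G, R, TC, PS, F_<sp>,
    B_<sp>, iterations) plus the run seeds; reproducible given (config,
    seed).
    """
    p = baseline_probabilities(observed)
    tf = observed.Tf
    if config.kind == "effort_scaling":
        tf = int(round(config.level * tf))
        closed = np.array([], dtype=int)
        label = f"scaling_{config.level:g}"
    else:
        box = merge_boxes(config.boxes)
        box.validate(observed.grid)
        p = closure_transform(p, box)
        closed = np.asarray(box.cells, dtype=int)
        label = f"closure_{box.label}"

    species = list(economics.species_index)
    rows = []
    results = []
    master = np.random.SeedSequence(config.seed)
    for run, child in enumerate(master.spawn(config.runs)):
        rng = np.random.default_rng(child)
        start = sample_pattern(p, tf, rng, observed.grid, year=observed.year)
        pattern, _, iters, _ = hill_climb_run(
            start, p, tf, economics.gains_of, stop_k=config.stop_k, rng=rng)
        if closed.size and pattern.counts[closed].any():
            raise AssertionError("closed-box cell received effort")
        ev = economics.evaluate(pattern)
        b_next = biomass_predictor(pattern) if biomass_predictor else {}
        res = RunResult(pattern=pattern, G=ev["G"], R=ev["R"], TC=ev["TC"],
                        PS=ev["PS"], F=ev["F"], B_next=b_next,
                        iterations=iters, seed=int(child.entropy))
        results.append(res)
        row = {"run": run, "scenario": label, "G": ev["G"], "R": ev["R"],
               "TC": ev["TC"], "PS": ev["PS"], "Tf": pattern.Tf,
               "iterations": iters}
        for s in species:
            row[f"F_{s}"] = ev["F"][s]
            row[f"B_{s}"] = b_next.get(s, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["results"] = results
    df.attrs["baseline"] = economics.evaluate(observed)
    return df
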