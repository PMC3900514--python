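# trawlsim

Spatially explicit bio-economic simulator for demersal trawl fisheries.

The package chains six stages over a regular lon/lat grid (6'×6' cells by
default):

1. **`trawlsim.synth`** — synthetic input generation: bathymetry pixels,
   SST layers, harbors, stratified-random survey hauls (five depth strata,
   haul counts proportional to stratum area), harbor-to-harbor vessel ping
   streams with trawling-speed segments over high-abundance grounds, price
   schedules and fleet fuel-cost records. The generating truth (mixture
   parameters, abundance surfaces, catchability, cost plane, fishing-state
   ping counts) is retained for testing only.
2. **`trawlsim.grid`** — grid geometry, inverse-distance-weighted
   interpolation of station values (cells with no station within the radius
   are excluded), per-cell depth mean/sd from 1' pixels, Chebyshev
   neighborhood means, and the pattern score
   `sum(log10(points per cell) × mean distance to the 3 nearest harbors)`
   used as a fuel-consumption proxy.
3. **`trawlsim.lfd`** — stratified abundance indices from haul records, EM
   decomposition of binned length-frequency distributions into normal
   cohort components (3 components for DPS and HKE, 2 for MUT, sexes fitted
   separately), Kolmogorov–Smirnov fit diagnostics, posterior allocation of
   station abundances to cohorts, and biomass conversion through the
   length-weight power law.
4. **`trawlsim.effort`** — vessel-ping effort mapping: per-trip linear
   track interpolation at 10-minute steps, a trawling-speed window
   (2.0–4.5 kn by default) to flag fishing pings, and per-cell fishing-point
   counts as annual effort layers.
5. **`trawlsim.elman`** — an Elman recurrent perceptron (logistic
   activations, context units copying the hidden state) that predicts
   next-year per-cell cohort abundances from four lag years of cohort,
   neighbor-mean, effort, depth and SST features; trained by gradient
   descent through the unrolled lag steps with random restarts, scored by
   held-out Pearson correlation, and introspected with Garson relative
   importance (percentages summing to 100).
6. **`trawlsim.economics` / `trawlsim.scenarios`** — the deterministic
   engine (logistic trawl selectivity fixed by the L50/L75 quantile
   conditions, spatial fishing mortality `f = q·S_l·e_c`, catches, revenue
   from size-band prices, the linear fuel-cost model `TC = β0 + β_PS·PS +
   β_E·E`, gains `G = R − TC`, overall F per species) and the
   effort-management simulator: global effort scaling (70%…130%) and
   nursery-box closures, each explored by multinomial effort-pattern
   proposals with strict gain-improving acceptance that stops after 100
   consecutive rejections.

`trawlsim.pipeline.run_pipeline` glues the stages together on a generated
bundle; `make_biomass_predictor` converts trained nets into the next-year
biomass indicator used to score optimized patterns.

Lengths are millimetres throughout; the length-weight law returns grams;
harvested biomass is kilograms; money is euros.

## CLI

```bash
# write a synthetic world bundle (CSV tables + JSON ground-truth sidecar)
trawlsim synth --seed 1 --outdir world/

# train the predictor for one species on a synthetic world
trawlsim train --species MUT --restarts 20 --seed 1 --out mut_net.json

# simulate effort-management scenarios
trawlsim simulate --scenario scaling --level 0.7 --runs 100 --seed 1 --out runs.csv
trawlsim simulate --scenario closure --boxes dps_box.csv,hke_box.csv --seed 1
```

`--config` accepts a YAML file overriding any `SyntheticWorldConfig` field
(grid size, years, fleet size, speed windows, fuel-record noise, ...).
Box files are CSVs with a `cell_id` column.

## Notes

- The K–S statistic is used descriptively: the binned ECDF is compared to
  the fitted mixture CDF at the class edges, with no correction for
  estimated parameters.
- Component-mean standard errors come from the inverse observed information
  of the binned likelihood (`mixture_standard_errors`), which accounts for
  component overlap.
- Cohort "length" units follow the source tables numerically and are
  treated as mm everywhere; for DPS they are plausibly mm of carapace
  length even where tables are headed in cm.
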