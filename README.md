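# tempmort

Two-stage distributed-lag non-linear (DLNM) analysis of the association
between daily mean temperature and mortality, with an attributable-burden
decomposition — driven end to end by a synthetic multi-city data generator
with a known ground-truth exposure–lag–response surface.

The pipeline:

1. **Synthetic panels** (`tempmort.synthetic`) — multi-city daily series
   (deaths by stratum, temperature, humidity, PM2.5, O3) simulated from
   city-specific climates and a known U/J-shaped risk surface with acute
   heat and prolonged cold lag structure. Plain-CSV I/O with schema
   validation.
2. **Spline bases** (`tempmort.splines`) — quadratic B-splines with
   percentile-anchored knots for the exposure axis, natural cubic splines
   (log-spaced knots) for the lag axis, plus confounder and seasonal/time
   bases.
3. **Cross-basis** (`tempmort.crossbasis`) — the exposure × lag tensor
   design matrix, reduction of fitted coefficients to the overall
   cumulative exposure–response curve, and centered RR curve / lag-curve
   prediction.
4. **First stage** (`tempmort.cityfit`) — per-city, per-stratum Poisson
   (or quasi-Poisson) regression of daily deaths on the cross-basis,
   confounder splines, a time spline (df per year) and day-of-week terms.
5. **Second stage** (`tempmort.meta`) — multivariate random-effects
   meta-analysis of the reduced coefficients (REML with a
   Cholesky-parameterized between-city covariance; method-of-moments
   fallback) and per-city BLUP shrinkage.
6. **Attribution** (`tempmort.attribution`) — minimum-mortality
   temperature/percentile search on a 0.1-percentile grid, backward
   attribution of deaths relative to the MMT, decomposition into
   extreme/moderate cold/heat by the 1st/99th percentile cutoffs, and 95%
   empirical confidence intervals by Monte Carlo resampling of the
   coefficients.
7. **Pipeline** (`tempmort.pipeline`) — end-to-end orchestration across
   cities and strata, a sensitivity grid (max lag, time df, confounder df,
   pollutant adjustment), deterministic named seed streams, CSV/JSON
   outputs.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the simulation-based acceptance suite
(basis oracles, reduction identities, attribution brute-force equivalence,
conservation, null calibration, ground-truth recovery, meta identities,
sensitivity stability, bitwise reproducibility). The full suite takes a few
minutes on one CPU; most of the time is the 100-replicate null calibration
and the 72-configuration sensitivity grid.

## CLI

```bash
# generate a synthetic 4-city, 6-year panel with known ground truth
tempmort simulate --out panel.csv --seed 1234

# end-to-end run over all strata in the panel
tempmort run --input panel.csv --out results/ --seed 1

# single-stratum attribution, first-stage fits, pooling, sensitivity grid
tempmort attribute --input panel.csv --out results/ --stratum total
tempmort fit --input panel.csv --out fits.csv
tempmort pool --input panel.csv --out pooled.json
tempmort sensitivity --input panel.csv --out results/
```

Outputs are plain CSV tables (`tables/attribution_<stratum>.csv` mirrors a
per-city MMP/MMT + AF table with eCIs, `curves/` holds RR curves) plus a
`manifest.json` recording knots, degrees of freedom, seeds and convergence
diagnostics. `tempmort run` also accepts a YAML config (`--config`) whose
keys mirror `tempmort.pipeline.RunConfig`.

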