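# weeddyn

Trait-based demographic modelling of annual arable weeds.

The package combines three pieces:

1. **A weed-traits database layer** (`weeddyn.wtdb`) — tidy one-row-per-record
   storage of trait/parameter observations (emergence calendars, hyperbolic
   yield-loss parameters, allometric fecundity coefficients, seed weight,
   seedbank half-life, …) with per-species aggregation, a correlation matrix
   over species-level values, and the density causing 5% crop yield loss
   (D5%) derived from the yield-loss hyperbola.
2. **A generic single-season life-cycle model** (`weeddyn.lifecycle`) — a
   virtual annual weed described by just two traits (maximum height, 1000-seed
   weight) runs seedbank → seedlings → mature plants → fresh seed → seedbank
   under a management scenario (herbicide kill rate × fertility level) and
   returns the population growth rate λ. Demographic parameters are predicted
   from the two traits via three empirical regressions
   (`weeddyn.relationships`); the biomass coefficient is calibrated so the
   shortest (10 cm) plant is exactly on the viability boundary under maximum
   stress (high herbicide, high fertility).
3. **Landscape analysis** (`weeddyn.landscape`, `weeddyn.sensitivity`) — λ
   swept over a 20 × 2000 grid of height (10–200 cm) × seed weight
   (0.01–20 mg) for four scenarios, λ = 1 fitness contours (marching
   squares), projection of real/virtual species at their exact trait values,
   viability summaries per status group, and a one-at-a-time ×1.05
   sensitivity report.

`weeddyn.synth` generates every input the pipeline needs (virtual trait
databases with the default regression structure plus configurable noise, and
species pools rejection-sampled against the model's own fitness surface), and
packages a fixture transcribing the published min/max ranges for 19 common
European weeds (endpoint-only; never confused with raw records).

## Command line

```bash
weeddyn calibrate --out cal.json                      # biomass coefficient
weeddyn sweep --config cal.json --scenario high-high --out run   # surface + contours
weeddyn project --config cal.json --species species.csv --out proj
weeddyn sensitivity --config cal.json --height 150 --seed-weight 10 --out sens.csv
weeddyn simulate --what wtdb --seed 1 --out wtdb.csv
weeddyn simulate --what pools --config cal.json --seed 1 --out pools.csv
weeddyn fit --db wtdb.csv --out models.json           # refit the regressions
```

Scenarios are named `<herbicide>-<fertility>`: `low-low`, `low-high`,
`high-low`, `high-high` (mortality 0.5 / 0.96). Species lists are CSV with
columns `name,height_cm,seed_weight_mg,status` where status is `common` or
`rare_declining`. Every command writes a `*.manifest.json` reproducibility
record (config snapshot, input digests, outputs).

## Notes on conventions

- The competition regression (ln D5% vs height) is applied with a negative
  slope of the printed magnitude (0.020), so taller weeds need fewer plants
  for a 5% yield loss; the sign is a field on `CompetitionHeightModel`.
- The low-fertility competitive adjustment and the biomass–yield-loss curve
  are pluggable (`LifecycleParams.fertility_fn` / `biomass_fn`); defaults are
  a logistic in height relative to the crop (shifted by ln seed weight) and a
  calibrated linear-through-origin relationship.
- Trait inputs outside the fitted domains (10–200 cm, 0.01–20 mg) are clamped
  with a warning; predictions can be extrapolated with `clamp=False`.
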