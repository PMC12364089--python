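# frailtyflow

A stock-flow (system-dynamics style) simulator of frailty onset and
progression in a population aged 50 and over. The population is stratified
into four age bands (50-64, 65-74, 75-84, 85+) and four ordered frailty
states derived from a cumulative-deficit electronic frailty index (Fit,
Mild, Moderate, Severe), giving 16 subgroups, 48 stocks (alive / died /
left per subgroup) and 72 flows (entry, death, de-registration, adjacent
frailty progression, ageing).

The package covers the full modelling workflow:

- **`frailtyflow.domain`** — age bands, frailty states, subgroup indexing,
  eFI scoring and categorisation.
- **`frailtyflow.engine`** — model construction and deterministic annual
  simulation with synchronous competing outflows, an irreversible frailty
  chain and a one-directional ageing chain. Time-dependent rates are cubic
  polynomials in model time, frozen beyond the calibration window.
- **`frailtyflow.calibration`** — estimation of all 72 flow specifications
  from annual cohort observation tables: per-year transition proportions,
  polynomial OLS with forward nested F-test degree selection.
- **`frailtyflow.validation`** — per-cell and overall (equal-weighted)
  MAPE tables against observed data, entry/de-registration rescaling for
  external cohorts, and initial-prevalence scaling.
- **`frailtyflow.projection`** — national scale-up: a closed model where
  people enter only by turning 50 (from population projections) and leave
  only by dying, plus prevalence summaries.
- **`frailtyflow.synthetic`** — seeded synthetic cohort generator
  (multinomial competing outcomes, Poisson entries) with known ground
  truth, used to test calibration and validation end to end.
- **`frailtyflow.io` / `frailtyflow.cli`** — tidy-CSV and YAML/JSON file
  formats and the command-line interface.
- **`frailtyflow.datasets`** — small packaged CSV transcriptions of the
  published cohort shares, MAPE grids and projection summaries used by the
  tests and the acceptance report.

## Command line

```sh
# generate a seeded synthetic cohort (observations + ground truth)
frailtyflow synth --seed 7 --years 12 --cohort-size 100000 --out-dir work/

# fit flow specifications from an observation table
frailtyflow calibrate --observations work/observations.csv \
    --out work/params.yaml --report work/calibration_report.csv

# simulate forward from the observed initial conditions
frailtyflow simulate --params work/params.yaml \
    --observations work/observations.csv --horizon 12 --out work/traj.csv

# score a simulation against the observations (prints the overall MAPE %)
frailtyflow validate --observations work/observations.csv \
    --params work/params.yaml --out work/mape.csv

# closed national run driven by age-50 entrants
frailtyflow project --params work/params.yaml --projection projections.csv \
    --split fit --from 2006 --to 2027 --out work/national.csv

# prevalence summary of the packaged projection table
frailtyflow report --year 2017
```

The projection CSV has columns `year,entrants_50` and, for initialising
the national run, extra rows with `band,population` filled in.

## File formats

- Observations (long CSV): `year,band,state,alive_start,deaths,deregs,entries,ageing_out,progression_out`,
  one row per subgroup-year; band/state labels are exactly `50-64`, `65-74`,
  `75-84`, `85+` and `Fit`, `Mild`, `Moderate`, `Severe`.
- Parameters (YAML or JSON): `flows:` with one block per flow family
  (`death`, `dereg`, `entry`, `ageing`, `progression`), keyed by
  `"band/state"`, each `{kind: constant, p: ...}` (or `rate:` for entries)
  or `{kind: polynomial, beta: [b0,b1,b2,b3], t_max: ...}`.
- MAPE table (CSV): `band,state,variable,mape` with an `overall` footer row.
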