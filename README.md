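# multicup

Simulation and analysis toolkit for supersaturating weakly basic drugs:

* a deterministic **three-cup transfer dissolution model** (gastric,
  duodenal, jejunal vessels connected by first-order programmed pumps, with
  octanol absorptive phases) and a **single-vessel pH-shift test**;
* a **mechanistic synthetic-data generator** for aqueous
  supersaturation/precipitation curves, organic-phase absorption curves and
  oral/i.v. plasma profiles with known ground truth;
* pH-dependent solubility modelling (modified Henderson–Hasselbalch),
  degree-of-supersaturation metrics, single/double **Weibull** dissolution
  models with AIC selection, non-compartmental PK;
* a complete **Level-A IVIVC engine**: polyexponential unit-impulse-response
  fitting, non-negative staircase deconvolution, time-scaled correlation
  fitting (`Fabs = AbsScale · Diss(Tscale·t − Tshift)`), closed-form
  convolution prediction, and prediction-error qualification
  (mean |PE| ≤ 10 %, individual |PE| ≤ 15 %).

## Library quick start

```python
import numpy as np
from multicup import DGIMConfig, simulate_dgim
from multicup.synthetic_data import default_scenario, default_kinetics

cfg = DGIMConfig()                       # 300/50/100 mL, th = 8 min
grid = np.arange(0.0, 180.0 + 1e-9, 1.0)
sim = simulate_dgim(cfg, default_scenario("PVPVA"),
                    default_kinetics("PVPVA"), grid)
sim.duodenal_aq      # aqueous concentration (µg/mL) vs minutes
sim.absorbed_fraction  # combined organic-phase fraction of dose
```

The IVIVC chain lives in `multicup.ivivc` (`fit_uir`, `deconvolve`,
`fit_correlation`, `predict_fabs`, `convolve_predict_plasma`, `pe_report`,
`validate_ivivc`); time is minutes in vitro and hours in vivo, with
explicit conversion via `TimeSeries.to_unit` and
`DoubleWeibullParams.with_time_scale(1/60)` at the boundary.

## CLI

```sh
multicup --outdir out simulate-dgim --group control
multicup --outdir out fit-solubility solubility_table.csv --exclude-biased-acidic
multicup --outdir out --seed 7 run-pipeline
```

Subcommands: `simulate-dgim`, `simulate-usp2`, `fit-solubility`,
`ds-metrics`, `fit-dissolution`, `nca`, `fit-uir`, `deconvolve`,
`fit-ivivc`, `predict`, `validate`, `run-pipeline`. Global flags:
`--seed`, `--config`, `--outdir`, `--log-level`. `run-pipeline` executes
the full chain (simulate → solubility fit → DS metrics → Weibull fits →
UIR/deconvolution → correlation on the training groups → external-group
prediction → PE report) and persists every intermediate as CSV plus a JSON
manifest that fully determines a rerun.

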