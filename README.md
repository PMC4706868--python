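# ocgapfill

Neural-network gap filling for satellite ocean-color fields.

Daily satellite chlorophyll-a (Chl-a) maps are full of holes — clouds, swath
geometry, and sun glint leave large parts of the ocean unobserved every day —
yet ocean forecast and biogeochemical models need continuous fields.  Because
Chl-a variability is largely entrained by the physics of the upper ocean,
a gap can be estimated from *physically related but independently observed*
quantities: sea-surface height, salinity and temperature, and upper-ocean
temperature/salinity profiles.  `ocgapfill` implements that idea end to end
for researchers working with gridded ocean-color products: it trains an
ensemble of small neural networks to emulate the physics→Chl-a mapping and
uses the ensemble to fill every grid cell where the predictors are known.

## The model

The observed field is treated as a stochastic mapping Y = M(X) + ε, where X
collects the upper-ocean state and metadata, and ε aggregates subgrid
variability plus observation noise.  M is emulated by a single-hidden-layer
perceptron with a linear output,

```
y_q = a_q0 + Σ_j a_qj · tanh(b_j0 + Σ_i b_ji · x_i),       j = 1..k
```

with 23 inputs and one output (Chl-a, mg/m³).  The inputs are the year,
cyclical encodings sin/cos(2π·day/366), sin/cos(lon), sin(lat), then SSH (m),
SSS (g/kg), SST (°C), and 7-level salinity and temperature profiles from the
top 75 m.  Training minimizes the mean squared error
E = (1/N) Σ (Yᵢ − NN(Xᵢ))² on every second record of the flattened
(time, lat, lon) stream, with the other half steering early stopping.

Because a single network settles in one local minimum and its derivative is
an ill-posed estimate, an **ensemble** of identically architected networks is
trained from different random initializations: the ensemble mean is the
filled value, the member spread is an uncertainty indicator, and the
ensemble-averaged Jacobian |∂y/∂xᵢ| ranks the physical drivers of the field.
The diagnostics module adds bias/RMSE/correlation scoring (bias = obs − pred),
the Chl-a ≤ 1 mg/m³ filtered variants, binned error statistics, daily global
metric series, spatial bias maps, a hidden-layer-size sweep, and the
decomposition RMSE = ε_app + ε, where ε_app is measured by training a
one-input network to emulate the identity mapping.

A bundled synthetic-ocean generator (`ocgapfill.synth`) produces gridded
physical fields, a known nonlinear Chl-a mapping with a right-skewed marginal
(~0.2% of values above 1 mg/m³), additive noise, and controllable gaps, so
the whole pipeline can be exercised and scored against known truth.

## Worked example

```python
import numpy as np
from ocgapfill import (
    Architecture, SynthConfig, TrainingOptions, assemble_records, compute_metrics,
    fill_gaps, generate_dataset, predict_records, train_gapfill_ensemble,
)

cfg = SynthConfig(n_days=120, seed=0)          # 18 x 36 grid, sigma = 0.1 mg/m^3
g = generate_dataset(cfg)
records = assemble_records(g)

ens = train_gapfill_ensemble(
    records, arch=Architecture(23, 10, 1), n_members=3, base_seed=0,
    opts=TrainingOptions(max_epochs=60, patience=20),
)

labelled = records[np.isfinite(records["chla"])].copy()
labelled["pred"] = predict_records(ens, labelled)
m = compute_metrics(labelled["pred"], labelled["chla"])
print(f"bias = {m.bias:.4f} mg/m3, RMSE = {m.rmse:.4f} mg/m3, CC = {m.cc:.3f}")

filled = fill_gaps(ens, g)
prov = filled.data["provenance"].to_numpy()
print(f"observed {(prov == 0).sum()}, filled {(prov == 1).sum()}, "
      f"unfillable {(prov == 2).sum()} cell-days")
```

prints

```
bias = -0.0009 mg/m3, RMSE = 0.0988 mg/m3, CC = 0.858
observed 40171, filled 16927, unfillable 382 cell-days
```

The RMSE sits at the injected noise level σ = 0.1 mg/m³ — the irreducible
error of the stochastic mapping — and the near-zero bias shows the systematic
component has been removed.  Every ocean cell-day is accounted for: observed
values are kept untouched, cells with complete predictors are filled with the
ensemble mean, and cells missing a predictor are flagged unfillable.
Ranking the inputs by the ensemble-averaged |Jacobian| recovers the
generator's configured drivers, `['sst', 'sal_3', 'sss']`.

The same workflow is available from the shell:

```bash
ocgapfill simulate --out ocean.nc --days 120 --seed 0
ocgapfill train --input ocean.nc --out-dir ens --members 3 --hidden 10 --seed 0
ocgapfill fill --input ocean.nc --ensemble ens --out filled.nc
ocgapfill evaluate --input ocean.nc --ensemble ens --out-dir reports
ocgapfill sensitivity --input ocean.nc --ensemble ens --out sensitivity.csv
ocgapfill sweep-k --input ocean.nc --k-values 3,10,30 --seed 0 --out sweep.csv
```

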