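# Methods

This note records the model, the design decisions taken where more than one
reasonable choice existed, the synthetic-data conditions under which the
package validates itself, and the limits of what those validations show.

## The stochastic-mapping view

Chlorophyll-a concentration at a grid cell is treated as a function of the
physical state of the upper ocean at that cell, plus an irreducible residual:

    Y = M(X) + ε.

X is a 23-component vector (metadata plus physical predictors, below); ε
aggregates everything the predictors cannot resolve — subgrid physical,
chemical and biological variability at scales finer than the grid and the
daily average, and observation noise in both X and Y.  The additive form is
an assumption: it implies the residual distribution does not depend on X,
which is known to be optimistic (noise grows with Chl-a; a heteroscedastic
noise option exists in the generator for exactly this reason).  Under this
view the best achievable test RMSE of any emulator of M is ≈ std(ε), and a
model that reaches it has extracted all the information the predictors carry.

## Input encoding

One network serves the whole globe and all days, so position and season
enter as inputs, encoded to respect their topology:

| # | input | encoding |
|---|-------|----------|
| 1 | year | raw calendar year |
| 2–3 | day of year t | sin, cos of 2π·t/D |
| 4–5 | longitude | sin, cos (radians) |
| 6 | latitude | sin (radians) |
| 7–9 | SSH (m), SSS (g/kg), SST (°C) | raw |
| 10–16 | salinity profile, 7 levels | raw, g/kg |
| 17–23 | temperature profile, 7 levels | raw, °C |

Decisions worth stating:

- **Day denominator D.** Both 365 and 366 are defensible; the package
  defaults to D = 366 and exposes `day_denominator` everywhere.  The
  difference is a phase error below 0.02 radians and is immaterial in
  practice, but the default is fixed so runs are comparable.
- **Latitude uses only the sine.**  Unlike day and longitude, latitude is
  not periodic over its sampled range, and sin(lat) is already monotone on
  [−90°, 90°], so a single component suffices.
- **The year is fed raw** and z-scored like every other input.  Over a
  training set that spans a single year the column is constant; the
  standardizer then forces its scale to 1 (with a warning), which maps the
  column to exactly zero and removes it from the fit — the desired behavior,
  since a constant carries no information.
- **Profile levels are positional.**  Level 1 is the shallowest, level 7 the
  deepest of the top 75 m; the synthetic generator uses depths
  5, 15, 25, 35, 45, 60, 75 m.  Nothing downstream depends on the depths,
  only on the ordering.
- **Standardization.**  Inputs and the target are z-scored with constants
  fitted on the training split only; predictions are mapped back to mg/m³.
  Whether to scale at all is a free choice — the network family is invariant
  to affine input maps — but first-order optimizers are not, and scaling
  makes the Jacobian components of differently dimensioned inputs
  comparable.

## Network and training

The emulator is a single-hidden-layer perceptron with tanh units and a
linear output; the operational shape is 23:30:1 and the identity-mapping
probe is 1:30:1.  There is deliberately no output nonlinearity and no
clipping: negative predictions are possible and are reported as such
(downstream users may clamp).

Training minimizes the mean squared error with mini-batch Adam
(default batch 2048, learning rate 5·10⁻³, β₁ = 0.9, β₂ = 0.999), seeded and
fully deterministic: weights initialize from a zero-mean normal scaled by
1/√(fan-in + 1), and the batch shuffling RNG derives from the same seed.
The optimizer is an implementation choice, not part of the method's
contract — any competent first-order scheme reaches the same noise floor;
only the achieved test error matters.

**Early stopping** is the primary regularizer: after every epoch the error
on the held-out test half is recorded, and the returned weights are those of
the best epoch (so the returned model is never worse than the initial one).
Default patience is 50 epochs without improvement; experiment presets use
shorter budgets, listed below.  An optional `target_error` bound stops
training once the test error reaches a prescribed ε²; it is off by default
because ε is generally unknown a priori.

**Jacobian.**  The derivative of the network output with respect to its
inputs is computed analytically,

    ∂y_q/∂x_s = Σ_j a_qj · (1 − t_j²) · b_js,   t_j = tanh(b_j0 + Σ_i b_ji x_i),

and is verified against central finite differences (step 10⁻⁵, agreement
required to 10⁻⁶) as a standing test.

## Ensembles

Members share the architecture and the training data and differ only by
initialization seed (base_seed + member index); no bagging.  Each member
lands in a different local minimum of the error surface; averaging their
outputs cancels part of the random error (the ensemble-mean MSE is never
above the average member MSE — an algebraic identity asserted to 10⁻¹² in
the tests), and averaging their Jacobians regularizes an otherwise ill-posed
derivative-of-a-fit.  The default ensemble size is six; the validation
experiments use two or three members, which is already enough to exhibit
both effects.  The member spread reported with predictions is the population
standard deviation (ddof = 0) across members.

Sensitivity reports average |∂y/∂xᵢ| over an evaluation set (default: the
test half) and then over members, in **standardized input space** by
default — comparing a °C-derivative against a g/kg-derivative is meaningless
before scaling.  A `physical_units` flag converts to mg/m³ per physical unit.

## Evaluation conventions

- **Bias = mean(observed − predicted)**: positive bias means the model
  underestimates.
- **Threshold filtering** keeps records with observed Chl-a ≤ 1.0 mg/m³
  (boundary inclusive).  The few points above the threshold sit in
  high-noise coastal regimes and dominate unfiltered statistics, so every
  diagnostic has filtered and unfiltered variants.
- **Binned statistics** bin by *observed* Chl-a, half-open bins [lo, hi)
  with the last bin closed; out-of-range records go to an explicit overflow
  row so counts always sum to N.  Default edges: 20 equal bins on
  [0, 2] mg/m³, always user-settable.
- **Global means are unweighted** over valid grid points; cos-latitude area
  weighting is available (`area_weighted=True`) but off by default so the
  numbers match the per-record statistics the training itself optimizes.
- **Correlation is reported as NaN** when either series is constant.
- **Hidden-size sweep** ties break toward the smaller k (parsimony).
- **Uncertainty decomposition** RMSE = ε_app + ε: ε_app is the test RMSE of
  a one-input network trained to emulate the identity mapping on the target
  variable — the error the network family itself contributes; ε is the
  remainder, attributed to the data.  ε_app is capped at the total RMSE so
  both components stay nonnegative.

## The synthetic ocean

The generator exists so every claim above can be tested against known truth
without any satellite archive.  It emulates the *statistical* structure the
method assumes, not ocean physics:

- **Grid and calendar**: 1°-style cell-centered regular grid, default
  18 × 36 (10° cells) over two 365-day years; fixed pseudo-continents cover
  ~26% of cells.
- **Physical fields** are sums of latitudinal gradients, hemisphere-
  antisymmetric seasonal cycles, and smooth random anomalies (sums of eight
  seeded traveling waves), clipped to plausible ranges (SST −2..32 °C,
  SSS 30..38 g/kg, |SSH| ≤ 1 m).  The anomalies are essential: they give
  each predictor variance that metadata alone cannot explain, so a trained
  network must actually use the physical inputs.
- **The chlorophyll mapping** is closed-form and log-linear in bounded
  predictor responses:

      chla_true = 0.15 + exp(−3.59865 + 1.45879 · u),
      u = 1.5·tanh((16 − SST)/12) + 0.3·(35 − SSS)/1.5 + 0.3·(35 − sal₃)/1.5,

  cold/fresh water is productive, warm/salty water oligotrophic.  The
  calibration constants were chosen once, by quantile matching on the
  default configuration, to give a right-skewed marginal with median
  ≈ 0.23 mg/m³, std ≈ 0.17, and ≈ 0.2% of values above 1 mg/m³.  The
  positive offset (0.15) keeps the left tail more than two noise standard
  deviations above zero, so the positivity clip at 0.001 mg/m³ truncates
  almost nothing and the injected noise survives intact (measured residual
  std ≈ 0.98σ); without the offset a realistic low-chlorophyll tail would
  silently shave ~12% off the noise and corrupt every noise-floor
  measurement.  The weights make SST the dominant driver of the
  *mean absolute standardized derivative* — the quantity the sensitivity
  ranking measures — by a factor ≈ 1.7 over the next input, which is what
  makes dominant-predictor recovery a well-posed test.
- **Noise and gaps**: additive Gaussian noise (default σ = 0.1 mg/m³, with
  an optional heteroscedastic term growing with chla), i.i.d. Bernoulli
  chlorophyll gaps (default 30%), and a small SSS gap fraction (2%) so some
  gaps are genuinely unfillable.  The noise-free truth is stored alongside
  for scoring.
- **Interannual drift** (for generalization experiments) slides the SST
  pivot of the mapping by a configured number of °C per year, so the
  physics→Chl-a relationship itself changes between years — the failure
  mode a short training period cannot defend against.

What the generator does **not** emulate: ocean dynamics, bio-optics,
multiplicative/log-normal observation error, spatially coherent cloud
masks, swath geometry, seasonal sampling biases, or realistic coastal
regimes.  Passing tests therefore demonstrate that the machinery is correct
and that the method behaves as designed *when its assumptions hold*; they do
not certify accuracy on real satellite archives.

## Validation experiments and problem sizes

Each experiment in `ocgapfill.experiments` regenerates its data from a seed
and runs the full pipeline.  Sizes are fixed design choices:

| experiment | conditions | expected behavior |
|---|---|---|
| identity mapping | 10⁵ scalars, 1:30:1 | test RMSE ≤ 0.002 mg/m³, CC ≈ 1 |
| Jacobian oracle | 100 random nets/inputs | ≤ 10⁻⁶ deviation from central differences |
| noise floor | default ocean (730 d), 3 members, k=10 | test RMSE in [0.9, 1.3]σ; CC vs truth ≥ 0.9; Jensen gap ≥ 0 |
| sensitivity recovery | 10 reps, 180 d, 3 members, k=8 | SST ranked first ≥ 9/10 |
| hidden-size sweep | 180 d, σ=0.02, k ∈ {1,3,6,12,24} | steep fall from k=1, then flat; ≥ 20% gain over k=1 |
| generalization | 3 yr, drift 3 °C/yr, k=10 | 2-yr-trained validation CC > 1-yr-trained |
| conservation | 40 d, 2 members, k=5 | cells conserved per day; reruns bit-identical |

`scripts/acceptance.py` runs all of them from one seed and writes the
measured numbers; the test suite asserts the expectations above at the same
sizes.

## Numerical and degenerate-input conventions

- All randomness flows through `numpy.random.Generator` seeded from
  explicit integers; identical configuration ⇒ bit-identical outputs
  (weights, filled fields, reports).
- Constant input columns standardize to zero (scale forced to 1, with a
  warning); constant targets are an error for the identity probe.
- Non-finite training loss aborts with a diagnostic rather than returning a
  silently broken model.
- Model and ensemble files are JSON; floats round-trip losslessly via
  shortest-repr decimal encoding.  Gridded I/O is classic NetCDF
  (`xarray`'s scipy backend) plus a flat 27-column CSV record dialect.

## Known limitations

- The alternating record split interleaves train and test in space and
  time, so the test half is not independent at synoptic scales; test error
  therefore measures interpolation, not extrapolation skill.  The by-year
  split and the generalization experiment exist to probe the latter.
- Negative filled values are possible near the low end of the target range.
- The ensemble spread underestimates total uncertainty: it captures
  initialization variance only, not data noise.
- Sensitivity rankings inherit the collinearity of the inputs: strongly
  correlated predictors (e.g. surface temperature vs shallow profile
  temperature) can trade sensitivity between them; rankings are stable for
  dominant inputs but not for closely matched minor ones.
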