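# Methods

## Forward model of the thermally modulated sensor

One recording is the output voltage of a resistive divider,
`V_OUT = V_C · R_L / (R_S + R_L)`, sampled while the heater voltage ramps
linearly over 0–5 V (501 points at 0.01 V). The supply is `V_C = 5 V` and
resistances are expressed in load-resistor units (`R_L = 1`), since only
the ratio `R_S/R_L` enters the divider.

The sensing-film resistance under a gas mixture is modelled as

```
R_S(v) = R_air(v) / (1 + Σ_g A_g · σ((v − v_on_g)/w_g) · (c_g/c_ref)^β_g)
```

with `σ` the logistic function and `R_air` the clean-air baseline,
log-linear between a cold-heater value `r_air_high = 50` and a hot-heater
value `r_air_low = 8`. This is the minimal form that reproduces the
qualitative phenomenology of a temperature-ramped tin-oxide sensor: no
response below the reaction onset temperature, a gas-specific onset
position and steepness, growth with concentration that saturates through
the divider bound, and strict monotonicity (more reducing gas → lower
resistance → higher output). It is a phenomenological stand-in, not a
kinetic surface-reaction model; no claim is made that its parameters map
onto physical rate constants.

Parameters and defaults (units in volts unless noted):

| parameter | ethanol | acetone | meaning |
|---|---|---|---|
| `v_onset` | 1.6 | 2.4 | half-rise heater voltage of the onset gate |
| `width` | 0.5 | 0.35 | logistic onset width |
| `beta` | 0.6 | 0.6 | concentration exponent (dimensionless) |
| `amplitude` | calibrated | calibrated | conductance gain at `c_ref = 0.5 %` |

Ethanol onsets earlier and more gradually; acetone later and more steeply.
The amplitudes are never hand-set: `calibrate_amplitudes` inverts the
divider in closed form at the ramp end (where the response is maximal,
since both the falling baseline and the rising gate drive `R_S` down
monotonically) so that noise-free single-gas sweeps at 0.5 % peak exactly
at 4.65 V (acetone) and 4.13 V (ethanol).

Measurement noise is additive Gaussian on the output voltage, default
sd 0.02 V, clipped to the physical range `[0, V_C]`. The synthetic design
replicates the factorial study layout: 13 serial dilutions per analyte
(`2^-7 % … 2^-1 %`, ratio √2), all 169 combinations, optional replicates.

What the generator does **not** emulate: humidity and temperature drift,
sensor hysteresis and ageing, headspace mass-transfer kinetics, correlated
or heteroscedastic noise, and inter-replicate variability beyond the noise
draw. Passing tests therefore demonstrate that the algorithm recovers
concentrations when the sweep family is smooth, monotone in concentration
and corrupted by white voltage noise — they do not certify performance on
laboratory recordings, whose nuisance structure is richer.

## Spline compression

Cubic (degree 3) clamped B-splines throughout: 6 total knots ↔ 8
coefficients holds only for cubics, and cubics are the standard practical
choice. The initial vector has interior knots every 0.1 V (51 knots on the
default ramp). Fitting is linear least squares on the B-spline design
matrix; the implementation solves the normal equations by Cholesky with one
iterative-refinement step, which at ~1200 refits per compressed sweep is an
order of magnitude faster than dense QR while matching it to the 1e-9
agreement the tests require against an independent Cox–de Boor +
`numpy.linalg.lstsq` oracle.

Greedy elimination: at each step every interior knot is tentatively removed
and the spline refitted; the knot with the smallest resulting residual sum
of squares is dropped permanently; ties break to the leftmost candidate.
Removal criterion is the full-refit SSE (not a score on the initial fit).
Because each removal restricts the fit to a subspace, the SSE path is
non-decreasing — asserted along every elimination in the tests. Degenerate
inputs: an empty knot span raises a fit error naming the span; a target
below 2 knots is rejected; a target equal to the start is a no-op.

Knot elimination runs independently per sweep by default, mirroring
per-curve compression of each recording. Different sweeps may therefore
keep different knots, which makes the feature map only piecewise-smooth in
concentration; an optional consensus mode (`--shared-knots`) eliminates
knots against the summed SSE of a calibration set and fits all sweeps on
the one shared vector. The per-sweep default was kept because the recovery
experiments pass with it; the shared mode exists for feature-space
consistency on harder data.

The 8 features are the coefficient **ordinates** only: the network has 8
input neurons, and the paired abscissae (Greville points) are determined by
the knots, carrying no independent information for fixed knots. They are
exposed separately via `BsplineModel.greville_abscissae`.

## Network quantifier

Targets are `log2` of the mass fractions, which makes the √2-ratio dilution
ladder equidistant (0.5 % → −1, …, 0.0078125 % → −7) and turns
multiplicative concentration errors into additive target errors. Inputs
are standardised with learning-set mean/sd; targets are mapped per-output
to [−1, 1] with learning-set min/max so that saturating activations work
in their active range. The "Exp" activation is the decaying exponential
`e^(−x)` (the convention of the modelling software family this mirrors;
unbounded-above alternatives destabilise BFGS).

Weights initialise uniform(−0.5, 0.5) scaled by `1/√fan-in` from a
per-restart seed. BFGS (analytic gradients) minimises the summed squared
error over the learning set, default `maxiter = 200`, `gtol = 1e-8` —
enough for the ~50–100-parameter networks here; the linear-recovery test
uses a tighter budget because exact interpolation is the assertion. At
every iteration the test-set MSE is evaluated and the best snapshot kept
(early stopping by monitoring, never touching validation). Reported errors
are MSE per sample per output **on the scaled-target scale**; no absolute
comparability with any external software's internal error scale is claimed.

Grid search: hidden sizes 2–9 × four activations × restarts (desk default
20 → 640 candidates; 1000 → the full 32,000-network enumeration). Selection
is the global minimum validation error; `prefer_smallest_within=tol`
optionally restricts to the smallest hidden size whose best validation
error is within a relative `tol` of the optimum (a parsimony rule). A
restart with a non-finite loss counts as failed; a fully failed cell is
excluded from selection.

## Evaluation

Primary metrics (MAE, RMSE, R²) are computed on the linear mass-% scale —
the scale on which the errors have physical units — per analyte and per
subset, with the log2-scale counterparts as secondary columns. R² of a
constant-truth cell (possible in tiny subsets) is flagged as NaN rather
than failing the report. The invariant `RMSE ≥ MAE` is checked on every
populated cell.

## Problem sizes and measured behaviour

The recovery experiments in the test suite run the full desk-scale study:
169 sweeps (13×13, one replicate), per-sweep compression, 640-candidate
grid search, once noise-free and once at sd 0.02 V, about two minutes each
on one CPU. The acceptance tests assert validation `R² > 0.99` (noise-free)
and `> 0.9` (noisy) for both analytes and that Lin hidden activations show
a higher mean validation error than Tanh — all quantities computed at run
time by the suite itself.

## Known limitations

- The forward model's functional form is invented plumbing; only its
  qualitative shape and the calibrated peak voltages are anchored.
- Per-sweep knot selection makes features piecewise-smooth in
  concentration; very low noise and small hidden layers can expose this as
  validation-error jitter (the consensus mode removes it).
- The greedy elimination is locally optimal per step, not globally optimal
  over knot subsets; the exhaustive oracle in the tests checks the step,
  not the path.
- Zero concentrations are representable in the simulator (air baselines)
  but excluded from training, whose targets are logarithmic.
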