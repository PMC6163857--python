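# Methods

## Growth model

Each well holds one strain described by four parameters: maximum specific
growth rate `mu_max` (h⁻¹), lag time (h), initial density `x0` and carrying
capacity `x_max`, all densities as OD600-equivalents. Growth is a hard-lag
exponential with a hard cap:

```
x(t + dt) = min(x(t) · exp(mu_max · g), x_max),
g = max(0, (t + dt) − max(t, lag))
```

The lag is a pure delay (no Baranyi-style adjustment function) and
stationary phase a cap rather than a substrate ODE. Both choices keep the
model closed-form: the update is exact for any step size, which makes
simulation results provably independent of the integration step (tested),
and makes every controller property checkable against hand arithmetic.
Substrate, acetate inhibition, oxygen transfer and temperature are out of
scope. The chemostat solution `x0·exp((mu−D)t)` is included only for the
cultivation-mode contrast (batch / chemostat / turbidostat) and ignores
substrate limitation.

Default capacity is `x_max = 3.0` OD600: an 8 h rich-medium preculture of
*E. coli* typically saturates at OD 2.5–3.5, and the batch arm relies on
precultures reaching capacity.

## Measurement model

A cycle's reading withdraws `sample_vol` (20 µL) from the well, dilutes it
1:5 and reads OD600:

```
raw      = (x_true / d) · (1 + ε_m) + ε_a,   truncated at 0
reported = raw · d
```

with `ε_m ~ N(0, mult_cv)` and `ε_a ~ N(0, add_sd)` on the raw scale
(defaults 0.02 and 0.01). The additive term back-calculates to 0.05 OD on
culture scale, an intentional error floor that dominates at low density —
reproducing the early-cycle growth-rate misestimation typical of plate
readers near their detection limit. The reported SD is
`sqrt(mult_cv²·x² + add_sd²·d²)`, verified by Monte Carlo. Sampling removes
volume, not concentration. Readings outside `[reader_min, reader_max]` on
the raw scale are flagged; the turbidostat controller uses them regardless
(as the hardware does), while the batch arm's mean excludes them.

## Controller

Growth rate, forecast and required biomass follow the three-equation law in
the README. Implementation details that the equations leave open:

* **First cycle.** Two readings are needed for a growth rate, so the first
  cycle never dilutes; only the sampling volume is replaced.
* **Belief bookkeeping.** The next cycle's `X_{k-1}` is
  `reported · factor_achieved` of the plan just executed. For performed
  dilutions `factor_achieved = (V−s−r)/V` is the physically correct
  concentration factor, so growth-rate estimates after a dilution are exact
  (noise aside). For "no dilution" cycles the bookkeeping factor is 1.0 —
  the growth-rate equation is applied directly to successive measured ODs,
  as on the reference platform — so µ is then underestimated by
  `ln(V/(V−s))/Δt ≈ 0.125 h⁻¹`, the passive sample-replacement dilution the
  bookkeeping ignores. The controller recovers one cycle later.
* **Smoothing.** µ is the estimate from the two most recent readings; an
  exponential-smoothing weight on the previous estimate is exposed
  (`mu_smoothing`) but defaults off, matching the platform's behavior and
  its observed sensitivity to low-OD noise.
* **Volume arithmetic.** `r = (V−s) − f·V`, rounded half-away-from-zero to
  the pipette resolution (1 µL default), clamped to
  `[0, V−s−min_residual_vol]`; requests outside the achievable factor band
  `[min_residual/V, (V−s)/V]` are clamped and flagged. Rounding to the
  nearest achievable removal is equivalent to minimizing the achieved-factor
  error; at an exact half-step tie, half-away-from-zero takes the larger
  removal. Setting `pipette_resolution = 0` disables quantization.
* **Harvest rule.** All wells within ±`harvest_tol` (0.05) of the setpoint,
  evaluated on reported ODs.
* **Cycle-time adaptation** (standalone utility): choose T so the fastest
  well grows at most `max_fold_growth` (4×) per cycle and the slowest well
  still satisfies `mu ≥ ln(V/(V−s))/T`, clamped to [0.25 h, 2 h]; the
  sustainability constraint wins conflicts because washout is
  irrecoverable.

### Precision limit of bolus dilution

The achievable dilution factors form a lattice of spacing `1/V` (pipette
resolution 1 µL), so the factor error after rounding is at most `0.5/V`, and
the harvest-density error after one cycle of growth is at most
`0.5/V · X_measured · e^{µΔt}` — about 0.009 OD at the defaults for
µ ≈ 1.3 h⁻¹. The growth factor `e^{µΔt}` amplifies the quantization error;
no controller honoring the divide-by-measured dilution law can do better.
This is the precision floor seen in noise-free simulations (harvest spreads
of ~0.005–0.015 OD).

### Noise propagation at the setpoint

Writing `δ` for the relative reading error, one control cycle maps the log
density error to `−2δ_k + δ_{k-1}`: the reading error enters once through µ̂
and once through the measured divisor of the dilution factor. At
stationarity the true harvest density therefore has relative SD
`√5 · σ_rel ≈ 15%` at the default noise (σ_rel ≈ 6.6% at OD 0.8). Over 96
wells this yields typical harvest-density ranges of ~0.6 OD — tighter than
the batch arm's ~0.83 in about 90% of replicates, but not overwhelmingly so.
Harvest synchronization in the noisy regime is limited by the reader, not by
the control law's convergence.

## Batch arm

Preculture each well `preculture_hours` (8 h, usually into capacity, which
absorbs lag and starting-density differences), inoculate a fresh
200 µL main culture with 10 µL (exactly 1:20), and monitor the plate-mean
reported OD: hourly below 0.4, half-hourly from 0.4, harvest at 0.7.
Boundary values trigger the higher-urgency action. The main culture carries
no residual lag (the preculture's purpose); a `max_hours` stop (12 h) bounds
non-harvesting runs. The 200 µL main volume was chosen so the stated 1:20
inoculation ratio is exact with a 10 µL inoculum; it deliberately differs
from the turbidostat arm's 170 µL working volume, which the source protocol
likewise does not reconcile.

## Experiment engine

Wells are processed in row-major plate order; all dilutions within a cycle
are treated as simultaneous (intra-cycle pipetting time neglected). The
first sample is taken directly after inoculation (t = 0). Runs that exhaust
`max_cycles` (24) without the harvest signal return full logs flagged
not-harvested, with the final densities reported — supporting parameter
sweeps instead of erroring. Synchronization metrics use the true simulated
densities: `harvest_spread = max − min` and `band_fraction`, the fraction of
wells inside the optimal harvest band (default 0.7–1.4, the mid-exponential
window for competence; comparisons can narrow it).

`compare_strategies` runs both arms per replicate on the same plate and the
same noise seed, drawing a fresh plate per replicate when a generator spec
is given.

## Synthetic plates

`generate_synthetic_plate` draws `mu_max ~ U(0.9, 1.5)` h⁻¹,
`lag ~ U(0, 1)` h and `x0 ~ U(0.05, 0.2)` OD per well — the heterogeneity
(fast/slow growers, staggered lags, unequal inocula) that motivates per-well
dilution control, at magnitudes typical of *E. coli* K-12 strain libraries
in rich medium. It does not emulate well-to-well optical crosstalk,
evaporation, substrate depletion, growth-rate drift over time, or correlated
reader errors; passing tests demonstrate the control logic and its noise
response, not reader physics. Replicated comparisons use an inner step of
0.25 h where only endpoint metrics matter — legitimate because the growth
update is exact at any step size.

## Replay

`replay_controller` runs the identical per-well state machine
(`WellController`) over a recorded OD log, grouped by reading time, wells in
file order. Because simulation and replay share that class, replaying a
simulated run's own readings reproduces its dilution log bit-identically —
which is why all CSVs serialize floats at full `repr` precision and are
parsed with round-trip float conversion. First readings produce
sample-replacement-only rows; single-reading wells therefore never dilute.

## Known limitations

* The growth model is exponential-with-cap; controllers tuned here may
  behave differently on substrate-limited or diauxic cultures.
* The quasi-turbidostat's harvest signal requires *every* well in the
  tolerance band simultaneously; under default noise with 96 wells the
  signal essentially never fires and runs end at `max_cycles` with wells
  oscillating tightly around the setpoint. Real deployments would widen the
  tolerance, smooth µ, or harvest per-well.
* Liquid-handling errors (pipetting CV, carryover) are not modelled; only
  volume quantization is.
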