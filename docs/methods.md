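# Methods

## Model

The package simulates seizure generation and spread on a two-dimensional
sheet of cortical tissue with a neural-mass extension of the Epileptor-2
model.  Five fields live on the grid:

* `[K]_o(x, y, t)` — extracellular potassium (mM),
* `[Na]_i(x, y, t)` — intracellular sodium (mM),
* `V(x, y, t)` — mean membrane-potential deflection (mV),
* `x_D(x, y, t)` — synaptic resource fraction (Tsodyks–Markram
  depression),
* `phi(x, y, t)` — presynaptic firing rate (Hz), algebraically slaved to
  the somatic rate.

The ionic balances are

    d[K]_o/dt  = D_K lap([K]_o) + ([K]_bath - [K]_o)/tau_K
                 - 2 gamma I_pump + delta_K theta
    d[Na]_i/dt = ([Na]_i0 - [Na]_i)/tau_Na - 3 I_pump + delta_Na theta

with the Na/K pump `I_pump = rho / ((1 + exp(3.5 - [K]_o)) (1 +
exp((25 - [Na]_i)/3)))` — a saturating product of sigmoids increasing in
both concentrations.  The membrane potential is a leaky integrator
`tau_m dV/dt = -V + u` driven by the input current (carried as u/g_L in
mV)

    u = gK_leak/gL (V_K - V_K0) + Gsyn/gL theta (x_D - c_IE) + sigma/gL xi

where `V_K = 26.6 ln([K]_o/130)` is the potassium Nernst potential and
`V_K0` its value at the initial 3 mM.  The somatic rate is a rectified
sigmoid `nu = nu_max [tanh((V - V_th)/k_v)]_+` and the synaptic resource
depresses as `dx_D/dt = (1 - x_D)/tau_D - delta_x x_D theta`.

Spatial coupling enters through two competing mechanisms:

1. **potassium diffusion** — the `D_K lap([K]_o)` term;
2. **axo-dendritic spread** — the screened-Poisson problem
   `lambda^2 lap(phi) = phi - nu`, equivalent to convolving the somatic
   rate with the exponentially decaying connectivity kernel
   `exp(-r/lambda)`.

`theta`, the rate that loads the ion balances and drives the synapses, is
`nu` in the diffusion-only variant (model 1, connectivity solve off) and
`phi` in the synaptic variant (model 2, diffusion term off); model 3
activates both.  This single switch is what lets the two propagation
hypotheses be compared inside one code path.

### Mechanism of a discharge

Bath potassium above baseline slowly charges `[K]_o` toward a stall level
just under 4 mM where relaxation balances the pump.  There the tissue sits
~3 standard deviations of the voltage noise below the firing threshold;
a noise excursion ignites the excitation disk (whose synaptic gain
`Gsyn/gL = 5` makes firing self-amplifying), firing pumps potassium out at
`delta_K theta`, and the potassium–excitability feedback sustains a
tens-of-seconds ictal discharge built of short depression-limited bursts.
Sodium accumulates on the slower `tau_Na` scale, the pump strengthens, and
the discharge terminates; the sodium recovery time sets the inter-
discharge interval.  The discharge spreads outward as a slow potassium
wave whose speed is set by the active mechanism: tenths of µm/s–scale
diffusion versus the millimetre-scale connectivity kernel.

## Numerics

* Cell-centred 80 x 80 grid over 6 x 6 mm (dx = 0.075 mm); cell (i, j)
  centred at ((j+1/2) dx, (i+1/2) dx).
* Five-point flux-form Laplacian with zero-flux (Neumann) boundaries;
  total potassium is conserved to machine precision under pure diffusion
  (verified to < 1e-9 relative over 1e4 steps).
* Explicit Euler–Maruyama stepping at dt = 1 ms.  The diffusion stability
  number `D_K dt/dx^2` is checked at startup (bound 1/4; the default
  configuration sits at 7e-5).
* The connectivity system `(I - lambda^2 L) phi = nu` has a
  geometry-fixed matrix, assembled once and LU-factorized
  (`scipy.sparse.linalg.splu`); a Jacobi iteration over the same matrix is
  kept as an independent reference path and cross-checked against a dense
  direct solve to 1e-8 relative on small grids.  While the whole sheet is
  silent (`nu = 0` everywhere) the solve is skipped — `phi = 0` is then
  exact — which removes most of the cost of the long inter-discharge
  stretches.
* Noise: one standard-normal draw per step enters `u` scaled by
  `sigma/gL` (default 25 mV).  In the default *homogeneous* mode the draw
  is shared by every cell (the configuration used for the standard runs);
  *inhomogeneous* mode draws i.i.d. per cell.  With the per-step
  convention at dt = 1 ms the stationary voltage-noise standard deviation
  is `sigma sqrt(dt / (2 tau_m - dt))` ≈ 5.7 mV.  A `step_invariant`
  convention (amplitude rescaled by sqrt(1 ms/dt)) is available for step-
  size studies; the per-step convention at 1 ms is the reference because
  it reproduces the burst statistics of the model (discharge durations
  and intervals) without adjustment.
* `x_D` is clamped to [0, 1] after each step: at rates near `nu_max` the
  explicit update can overshoot the resource-fraction range.  The two
  concentrations are floored at 0.05 mM for the same reason: under strong
  disinhibition the pump can run near its maximum long enough for the
  explicit potassium update to undershoot zero, where the Nernst
  logarithm is undefined.
* Non-finite values abort the run naming the field and cell; the hot loop
  checks every 500 steps, the public single-step API every step.
* Lesions are rasterized cell sets.  Connectivity never crosses a lesion
  (Dirichlet rows `phi = 0` plus severed stencil edges, so the operator
  restricted to intact cells stays symmetric); potassium diffusion
  crosses by default and is severed only when `blocks_diffusion` is set.
  This separation is what the complete-lesion experiment manipulates.

## Measurements

* **Discharge detection**: hysteresis on the probe potassium trace —
  onset at an upward crossing of 4 mM (the level at which discharges
  initiate), offset 0.5 mM lower, events closer than 5 s merged.  The
  hysteresis band rejects burst-scale chatter around threshold.
* **Discharge timing statistics** (durations, intervals, onset
  potassium) come from the *activity envelope* instead: the firing rate
  averaged over 2 s, with a discharge spanning the excursion from 10 Hz
  up to the fall below 2 Hz, 20 s merging, and a 5 s minimum duration
  separating ictal discharges from isolated interictal bursts.  A
  duration refers to the high-rate phase; the potassium excursion at the
  centre can outlast it by minutes when clearance is slow (no diffusion),
  so a potassium-based duration measures clearance, not activity.
* **Wavefront speed**: along a radial ray from the excitation centre
  (sampled every 0.25 s), each position's own trace is segmented into
  discharges and the onset of its k-th event is the k-th wave's arrival.
  Indexing arrivals per position keeps successive waves separable even
  when a slow wave is still travelling while the next ignites at the
  centre.  The arrival threshold is 5 mM — midway between the quiescent
  stall just under 4 mM (which ambient fluctuations occasionally graze,
  producing spurious simultaneous crossings at the ignition level) and
  the wave peak of 8 mM and above; the front is steep, so the fitted
  speed is insensitive to the level.  Speed is the slope of position
  against arrival time over 0.5–2.5 mm from the centre — inside
  that range the profile travels with a steady shape; closer in, the
  initiation disk distorts it, farther out the boundary does.  The slope
  is fitted with the Theil–Sen estimator, so a minority of corrupted
  arrivals (a position triggered early by a stray excursion) cannot drag
  it; on clean fronts it coincides with least squares.  The estimator
  recovers synthetic front speeds over 0.01–10 mm/s within 2%.
* **Envelope speed**: the firing-rate ray is averaged over a sliding 2 s
  window (long against single bursts, short against the potassium wave)
  and the outer front of the averaged activity (threshold 10 Hz, about
  half the typical time-averaged intra-discharge rate) is fitted the same
  way over 0.5–2.9 mm.  Per-position excursions must last at least 5 s —
  the same sustained-activity criterion that defines a discharge —
  because spatially synchronized preictal bursts cross the threshold
  everywhere within a second or two and would otherwise register as a
  near-infinite-speed front.  This is the slow wave an intrinsic-optical-
  style signal would see: the envelope of fast bursts, travelling with
  the discharge, not with the bursts.
* **Onset potassium**: discharge onsets are re-detected independently of
  the potassium detector, from the 1-s-averaged firing rate crossing
  10 Hz (20 s refractory), and `[K]_o` is read at those times — avoiding
  circularity between detector threshold and measured threshold.
* **Synchrony**: fast-burst onsets (raw voltage threshold) and discharge
  onsets (smoothed-rate threshold) are matched pairwise across probes;
  on a propagating seizure the discharge delays are seconds per
  millimetre while burst delays stay at the sampling scale.

## Study conditions and problem sizes

The standard runs use the default domain and parameter table exactly:
model 1 for 300 s (first and second wave, ~2–3 discharges) and model 2
for 550 s (two discharges, one full interval), each seed-averaged over
three seeds — the acceptance script derives per-run seeds from its
`--seed` argument.  The test suite uses 480 s for the synaptic variant,
which still contains the second onset under the observed interval
spread.  Parameter scans use the narrow-strip preset (6 x 0.6 mm, 80 x 8
cells, excitation disk at one end), which preserves dx and the disk size;
strip fronts are planar rather than radial and run somewhat faster than
on the full sheet, so the strip is used only for orderings and
sensitivities, never for the headline speeds.

## Design choices on open points

* **Rate entering depression and synapse in the diffusion-only variant**:
  with the connectivity equation switched off, `phi` is undefined; the
  somatic rate replaces it everywhere it appears (ion loading, resource
  depression, synaptic drive), keeping the variant a pure point-model-
  plus-diffusion.
* **`V_K0` reference**: computed from the initial 3 mM concentration, not
  the bath — the potassium depolarization is measured relative to where
  the tissue started, so a raised bath is itself depolarizing.
* **Single `Gsyn` factor**: the inhibitory term `-c_IE Gsyn phi` uses the
  same per-cell `Gsyn` map as excitation (one synaptic-strength factor
  per cell, elevated inside the disk).
* **Initial `phi`**: solved from the initial rate field rather than
  zero-initialized; the connectivity equation is algebraic in time and
  admits no independent initial condition.
* **Observer drive**: the neuron-observer's input is the population
  `u/g_L` (mV) converted at a configurable 10 pA/mV.  The two submodels
  use different current conventions and no conversion is defined between
  them; the default gain puts the discharge-peak drive in the range that
  produces intra-burst spiking at realistic rates, and it is exposed as
  an explicit parameter rather than hidden.
* **Complete-lesion preset noise**: this configuration (fast potassium
  clearance, tripled potassium leak sensitivity, 4 mM peripheral bath)
  has a tonically firing excitation centre — its potassium stall sits far
  above threshold, so discharge generation needs no noise — while the
  peripheral quiescent state keeps only a ~7 mV margin.  At the standard
  25 mV noise amplitude the periphery ignites spontaneously within tens
  of seconds (verified on an isolated-periphery run), which would mask
  the diffusion-mediated recruitment the experiment is designed to show.
  The preset therefore sets `sigma/gL = 5` mV, keeping the periphery
  metastable; this is the one deviation from the standard amplitude and
  it is documented in the preset file itself.

## What the simulations do and do not show

The generator produces the model's own idealized tissue: square geometry,
isotropic connectivity with a single length scale, one excitable zone,
spatially uniform parameters outside it, and noise that is either
perfectly correlated or perfectly independent across space.  Passing
tests show that the implementation reproduces the model's dynamics —
threshold-gated discharges near 4 mM, depression-limited bursts,
diffusion-paced versus connectivity-paced fronts and their parameter
orderings — not that real cortex behaves this way.  In particular the
absolute front speeds inherit every simplification above, and the
diffusion-variant speed is additionally sensitive to the noise-crossing
statistics at the front (see the voltage-noise discussion): its measured
value should be read as order-of-magnitude support for the "diffusion is
too slow" conclusion rather than as a calibrated quantity.

## Known limitations

* Chloride and GABA reversal dynamics, intracellular potassium and
  extracellular sodium are held constant; the sensitivity estimates
  (26.6/[ion] mV/mM) justify this for the large pools only.
* The electric-drift (electrodiffusion) transport of potassium is not
  simulated; the package provides the closed-form magnitude estimate
  (`u_K V'`, micrometres per second at physiological fields) that shows
  why it is negligible.
* Axonal conduction delays are absorbed into the instantaneous
  connectivity solve; this is valid while delays are short against the
  10 ms membrane time constant.
* The observer neuron is driven one-way; there is no spike feedback onto
  the population.
* Explicit Euler is first-order: halving dt shifts discharge timings of
  individual realizations (they are noise-driven), though the summary
  statistics are stable.
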