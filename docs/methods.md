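# Methods

## Physical model

`magloss` computes the heating power that a dilute suspension of
single-domain superparamagnetic nanoparticles (a *magnetic fluid*) absorbs
from an AC magnetic field, in the linear-response (Debye) regime used for
magnetic fluid hyperthermia dosimetry.

### Relaxation

Each particle relaxes its magnetization through two parallel channels:

- Néel (internal moment flip over the anisotropy barrier):
  `tau_N = tau0 * exp(K_a V_p / k_B T)` with `V_p = (pi/6) d^3`;
- Brownian (rigid-body rotation in the carrier):
  `tau_B = 3 V_h eta / (k_B T)` with the hydrodynamic volume
  `V_h = (pi/6)(d + 2 delta)^3` including the surfactant shell `delta`.

The effective time is the harmonic combination
`tau = (1/tau_N + 1/tau_B)^-1`; the faster channel dominates.  The Néel
exponential saturates to `+inf` instead of overflowing, which degrades the
effective time gracefully to the Brownian channel for thermally blocked
cores.  The Néel/Brownian crossover diameter is found by a bracketed Brent
root search on `log(tau_N / tau_B)` over 1–100 nm (log space keeps the
residual finite where the exponential would overflow; `rtol = 1e-12`,
`xtol = 1e-20` m).

### Linear response and power

Per size class *i* and field axis, the chord susceptibility linearizes the
Langevin magnetization at the drive amplitude:

    alpha = mu0 V_p M_d H / (k_B T)
    chi   = (phi_d M_d / H) * (coth(alpha) - 1/alpha)

and the magnetization phasor is the first-order response
`M = chi h / (1 + j omega tau)`.  A rotating excitation drives the y axis in
quadrature (`h_x = H_x`, `h_y = j H_y`); alternating mode leaves one axis at
zero.  The time-averaged volumetric power is evaluated with complex
arithmetic,

    P = (mu0/2) Re( sum_i j omega (M_xi hx* + M_yi hy*) ),

summed over the size classes; the algebraically equivalent closed form
`(mu0/2) chi H^2 omega^2 tau / (1+(omega tau)^2)` per axis is coded
independently and used only as a test oracle.  Equal per-axis amplitudes in
rotating mode give exactly twice the alternating-mode power — a structural
superposition property of the two terms, which the tests assert exactly.

### Polydispersity

TEM sizing yields number-weighted diameters; power scales with the volume in
each class.  The suspension is discretized into size groups (default
3.5–14.5 nm in 1 nm steps, twelve classes) and the total volume fraction
`phi = M_s_fluid / M_d` (from fluid magnetometry) is distributed as
`phi_d_i = V_i * phi / sum(V)`, which conserves `phi` to machine precision
for any non-negative relative-volume vector.  Log-normal fits use weighted
maximum likelihood on log diameters (closed form — deterministic, no
optimizer), with volume weighting implemented as `count * d^3` weights;
arithmetic moments follow from `mean = exp(mu + sigma^2/2)`,
`std = mean * sqrt(exp(sigma^2) - 1)`.  Raw diameters are binned to the
group grid by nearest grid point, ties to the lower bin.  When empirical
group volumes are available they are preferred over the fitted curve, since
discretized fits can deviate from actual class volumes by tens of percent.

### SAR conventions

The model power P is per m³ of fluid.  Two normalizations are exposed:

- `per-magnetic-mass` (default): `SAR = P / (phi rho_m)` — per kg of
  magnetic material suspended in the fluid.  This matches the calorimetric
  estimator, which divides by `m_Fe`, the magnetic mass per unit fluid
  volume, so model and measurement are commensurable.
- `literal`: `SAR = P / rho_m`.  Kept because part of the literature
  normalizes by the bulk solid density alone; the two differ by the factor
  `phi`.

### Calorimetric estimator

`SAR = c rho (dT/dt)_max / m_Fe`.  The maximal derivative is
operationalized as the steepest least-squares straight line of fixed
duration (default 5 s) slid over the first 30 s of the record, rather than
pointwise finite differences, which amplify probe noise; the pointwise
variant is exposed for diagnostics.  The rolling regression is computed in
O(N) from prefix sums after centering both series (the slope is
shift-invariant; centering removes the catastrophic cancellation the raw
sums would suffer).  An optional `t0` trim drops pre-trigger samples.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `tau0` | 1e-9 | s | conventional Néel attempt time for iron-oxide nanoparticles |
| `delta` | 1e-9 | m | fatty-acid surfactant length on non-polar carriers |
| `K_a` | 4.7e4 | J/m³ | effective anisotropy of maghemite nanoparticles (standard literature value). Not measurable from size data alone; this is the model's main calibration knob. With mineral-oil viscosities it places the Néel/Brownian crossover near 12 nm; a 10 kJ/m³ bulk-like value would push it to ~20 nm |
| `M_d` | — | A/m | bulk saturation magnetization (400 kA/m for maghemite) |
| `rho_m` | 4860 | kg/m³ | maghemite density |
| `k_B` | 1.38e-23 | J/K | rounded value conventional in this literature |
| slope window / horizon | 5 / 30 | s | the maximal derivative occurs within the first few seconds; 5 s averages enough samples to suppress probe noise without flattening the early transient |

Temperatures are accepted in °C at every interface and converted to kelvin
internally; lengths, times and fields are SI inside, with display units
(nm, kA/m, kHz, W/g) only at the CLI/config boundary.

## Numerical choices

- **Langevin function**: `coth(a) - 1/a` suffers catastrophic cancellation
  for small `a`; below `a = 0.05` the odd-power series through `a^9` is used.
  Both representations agree to ~3e-14 relative at the switch, and the
  function is monotone and bounded in [0, 1).
- **Zero-field susceptibility**: at `H = 0` the chord degenerates; the
  analytic initial susceptibility `phi_d mu0 V_p M_d^2 / (3 k_B T)` is
  returned instead of dividing by zero.
- **Viscosity fit**: with exactly three points a Vogel–Fulcher–Tammann law
  `A exp(B/(T - T0))` is solved exactly in closed form; the solution is
  rejected (falling back to Arrhenius least squares) when the divergence
  temperature `T0` lands within 5 K of the 0–100 °C evaluation range.
  Evaluation outside that range is an error, not an extrapolation.
- **Validity guard**: linear response holds for cores below ~20 nm and
  inductions below ~10 mT; outside that envelope the sweep warns but still
  computes, since the envelope edges are soft.

## Synthetic data

No public dataset exists for this kind of fluid characterization, so the
`fixtures` module generates every input with known ground truth:

- **Diameter samples**: i.i.d. log-normal draws (default median 9 nm, shape
  0.25, 500 particles — a typical TEM sizing campaign).  They emulate the
  *statistics* of TEM sizing, not imaging artifacts: no segmentation error,
  no agglomerate exclusion, no resolution floor.
- **Group-volume vector**: a discretized log-normal (median 8.5 nm, shape
  0.28 in volume) rescaled to hit a quoted anchor exactly (default 1.611%
  at 7.5 nm) and to sum exactly to the total fraction (default 10.57%).
  This is a *synthetic surrogate* for an empirically measured vector: it
  honours the two known numbers and interpolates a plausible unimodal shape.
- **Heating curves**: `T(t) = T0 + slope0 * tau_c (1 - exp(-t/tau_c))` plus
  i.i.d. Gaussian noise (default 0.02 K at 50 Hz), with
  `slope0 = SAR * m_Fe / (c rho)` exactly the quantity the estimator must
  recover and `tau_c` a single heat-loss time constant.  Real calorimeters
  add probe lag, drift and multi-exponential losses that this generator does
  not model, so the closure tests demonstrate estimator correctness under
  the stated noise model — not field performance.

All generators are bit-reproducible under a fixed seed.

## Known limitations

- Linear response only: no high-field saturation dynamics, hysteresis
  (Stoner–Wohlfarth) or eddy-current losses; predictions degrade above
  ~10 mT or ~20 nm cores.
- Monodisperse anisotropy: one `K_a` for all size classes, and `K_a` is a
  calibration input rather than a measured quantity.
- No interparticle interactions (valid for dilute, well-stabilized fluids;
  at 10% volume loading dipolar effects may already bias real samples).
- The carrier property models interpolate 0–100 °C only, and concentration
  dependence of viscosity is not modelled.
- Calorimetry assumes the initial-slope (adiabatic) regime; no Box–Lucas
  heat-loss correction or probe-lag deconvolution.
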