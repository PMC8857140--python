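# Methods

`biofilmosc` simulates potassium-mediated electrochemical signaling and the
resulting oscillatory growth of *Bacillus subtilis* biofilms in microfluidic
flow cells, in one spatial dimension (a cross-section from the attachment
wall to the fluid interface, on a moving domain) and in two dimensions (a
flow cell with resolved Stokes flow and a level-set biofilm boundary).

## The model

### State variables

Extracellular glutamate `G` and potassium `K` (mM) diffuse through the
biofilm. The cellular state — internal glutamate `G_in`, internal potassium
`K_in`, the acclimated potassium level `K_acclimated`, membrane voltage `V`
(mV), potassium-gate openness `n`, and the fluorescent reporters `T` (ThT,
a hyperpolarization indicator) and `A` (APG, an extracellular-potassium
indicator) — is carried with the growing biomass.

### Membrane potassium exchange

Potassium crosses the membrane through three pathways, Hodgkin–Huxley
style:

- gate flux `J_gate = F·g_K·n⁴·(V − V_K)` with reversal
  `V_K = V_K0 + δ_K·K`;
- leak flux `J_leak = F·g_L·(V − V_L)` with reversal
  `V_L = V_L0 + δ_L·(K − K_acclimated)`;
- an active pump `J_pump = max(γ_K·K·(K_max − K_in), 0)` through which
  cells can only take potassium up.

`F` (mM/mV) converts between voltage and potassium changes; positive flux
means potassium released to the extracellular pool. The voltage obeys
`dV/dt = (−J_gate − J_leak − J_pump)/F`. The distinctive modelling choice
is *acclimation*: cells respond to the change in ambient potassium relative
to the level they have adjusted to (`K_acclimated` relaxes to `K` at rate
`η_K = 30/h`), not to the absolute concentration. A sudden rise in ambient
potassium therefore transiently raises `V_L`, depolarizes the cell, blocks
its glutamate uptake (the uptake term carries a sharp voltage gate
`1/(1+exp(V − V_th))`), and stresses it — which is how the potassium wave
propagates.

### Growth

The growth propensity is `M_grow = T_G/(T_G + T_V)` with
`T_G = G_in/(G_in + G_u)` and `T_V = η_V·(tanh(γ_V(V/V_low − 1)) + 1)`:
cells grow only when fed and not hyperpolarized. The grouping of the
`+1` inside the `η_V` factor is deliberate: the alternative grouping
(`η_V·tanh(·) + 1`) is negative at the homeostatic voltage −156 mV, which
contradicts the requirement that `M_grow` stay in [0, 1]; the alternative
remains available (`literal_tv`) for comparison. The 1D growth velocity is
cumulative, `U(x) = δ_grow ∫₀ˣ G_in·M_grow dx`, and the interface moves at
`dL/dt = U(L)`.

### Starvation response

Gate opening is driven by internal-glutamate depletion through a reversed
Hill term with exponent `m = 2` that is half-maximal at `G_in = G_l`;
starving cells open their gates, release potassium and hyperpolarize. The
gate *flux* uses the classical `n⁴` conductance; the opening *kinetics* use
the Hill exponent `m`. These are distinct constants and both are kept.

## Parameters and units

All tabulated constants live in `ParameterSet` with defaults in the
published units; everything is normalized internally to {mm, hour, mM, mV}
(only the four diffusivities change, mm²/day → mm²/hour). Three constants
the published table does not carry:

- `K_max` (pump threshold on internal potassium): default 300 mM, equal to
  the printed homeostatic initial `K_in`, so the pump sits exactly at its
  off threshold at the initial condition. This value is an inference, not a
  printed fact; the onset-size results are insensitive to it between 150
  and 300 mM.
- `mu` (fluid viscosity): 1 in internal units. With velocity-Dirichlet
  boundary conditions it only rescales the pressure field.
- `u0` (inlet centerline speed): 90 mm/h for single-biofilm flow-cell runs,
  10 mm/h for the multi-biofilm synchronization scenario.

## 1D numerics

Fixed nominal spacing `dx` (default 2 µm); interior nodes sit at `i·dx` and
one interface node tracks `L` exactly (last spacing kept within
(0.2, 1.2]·dx; new nodes inherit the previous interface value). One outer
step (default `dt = 5·10⁻⁴ h`) applies Lie splitting:

1. **Reactions**: Heun (RK2) sub-steps; the sub-step count comes from a
   parameter-only Jacobian bound (≈1300/h at defaults, dominated by
   `F·g_L·δ_L` and `δ_G·G0`) so that perturbed-parameter runs follow
   identical step schedules — essential for clean forward differences in
   the sensitivity protocol. A deterministic step-halving retry guards
   rare fast transients.
2. **Advection** of the cellular fields with `U ≥ 0`: first-order
   conservative upwind, `−∂(Uq)/∂x`, exactly as the equations are posed
   (positivity over accuracy). A non-conservative transport form
   `−U·∂q/∂x` is available (`advect_transport`); the conservative form's
   dilution term `−q·∂U/∂x` continuously depolarizes growing cells by
   ≈ +12 mV/h (V is negative), which keeps the quiescent state near the
   uptake cutoff and sustains a spike train at all sizes, whereas the
   transport form gives quiescent growth at −156 mV with a sharp
   size-gated onset but fewer oscillations per unit time. The conservative
   form is the default.
3. **Diffusion** of `G`, `K`: backward Euler with a Thomas solve; no-flux
   at the wall, and at the interface the boundary-layer closure
   `D·∂c/∂x = D_fl·(c_far − c_int)/B_L`.

Clamps after each step: `G_in ∈ [0, G_max]`, `n ∈ [0, 1]`, concentrations
and reporters ≥ 0. Spatial means are trapezoid (finite-volume) averages
over [0, L]. The inner loop is numba-compiled; a pure-numpy reference
right-hand side (`rhs_1d`) is retained and a test pins the two against each
other, plus against an off-the-shelf stiff integrator in the well-mixed
limit.

The closed configuration (no boundary exchange, growth off) conserves
`∫(K + K_in)` to machine precision by construction: the membrane terms
enter `K` and `K_in` with exactly opposite signs inside the same Heun
sub-steps, and the finite-volume diffusion is conservative.

### Initial conditions

1D: `G=30, K=8, G_in=20, K_in=300, K_acclimated=8 mM, V=−156 mV, n=0.1`
(2D: `V=−160 mV`). The reporters are not part of the printed state; they
start at their pointwise steady state for the initial `V` and `K` (they do
not feed back on the dynamics, so this only removes a decay transient from
their traces).

## Analysis procedures

- **Onset**: a local minimum of spatial-mean voltage ("mean voltage stops
  decreasing and begins to increase"), with a noise guard: the series must
  drop by ≥ 0.5 mV over the preceding half hour and rise by ≥ 0.5 mV over
  the following half hour (solver output is smooth; the guard suppresses
  sampling wiggles). Events with doubled width (2·L) below 300 µm are
  flagged unsustained and excluded from onset-size statistics.
- **Onset-size experiment**: 53 independent runs, initial width uniform on
  70 ± 25 µm (the model's only stochastic element, driven by one seed);
  replicates with no sustained onset before the 45 h horizon are reported
  as censored, and the mean is over uncensored replicates.
- **Period versus size**: periods between consecutive onsets, attributed
  to the size at the later onset. The period analysis pools *all* voltage
  minima: the 300 µm exclusion is an onset-statistics rule, and the
  period–size relation is precisely about oscillations across the size
  range, including small sizes.
- **Oscillation magnitude**: max − min of mean extracellular potassium
  over the analysis window (the proxy for oscillation strength).
- **Sensitivity**: one-sided forward difference with absolute step 0.001
  in the parameter's own tabulated units, on a 20 h run from width 300 µm;
  reported as `dO/dp · 0.1·|p|/O · 100` (percent change of the magnitude
  per 10% parameter change). The baseline magnitude is memoized (one
  baseline, thirty perturbed runs). Reporter parameters are excluded —
  they do not feed back on the dynamics.
- **2D wave speed**: each biofilm cell is assigned the time of its
  extracellular-potassium maximum within the first-oscillation window;
  regressing cell distance from the wave origin (earliest crest) on crest
  time gives the crest speed as the slope.

## 2D numerics

Cell-centered square grid over the 3 × 3 mm flow cell (10 µm reference
resolution; 30–50 µm for desk-scale runs). Biofilms are the φ < 0 region
of a level-set field.

- **Fluid**: `∇²P = 0`, then `μ∇²u = ∂P/∂x`, `μ∇²v = ∂P/∂y` (sparse
  direct solves). No-slip on walls and biofilm; parabolic inlet profile;
  outlet `∂u/∂x = 0, v = 0, P = 0`. The inlet pressure gradient is set to
  the Poiseuille-consistent value `−2μu0/H²`, which makes the
  empty-channel solution exact (verified against the closed form). The
  fluid is re-solved only when the interface has moved by a cell
  (quasi-steady coupling: flow equilibrates in seconds, growth in hours).
- **Transport**: one implicit (backward-Euler) operator over the whole
  grid with harmonic-mean face diffusivities between `D_biofilm` and
  `D_fluid` — the finite-volume enforcement of concentration and flux
  continuity at the interface. Advection uses the *advective* upwind form
  `u·∇c` rather than the divergence form: the Stokes-approximated velocity
  field is not discretely divergence-free, and the divergence form
  generates spurious sources and sinks where `∇·u ≠ 0` (observed as fluid
  concentrations far outside the inlet/interface range); the two forms
  coincide for incompressible flow. Reaction sources from the biofilm
  enter the same implicit step. A separate steady fluid-region solver
  exists for stand-alone transport questions and is verified against
  constancy and maximum-principle checks.
- **Growth**: `∇²Ω = δ_grow·M_grow·G_in` in the biofilm with `Ω = 0` on
  the interface and no growth through walls; `U = ∇Ω`. In the slab limit
  this reproduces the 1D growth law `dL/dt = δ_grow ∫ G_in·M_grow dx`
  exactly, which is the cross-module consistency anchor (tested). The
  literal pointwise form `Ω = δ_grow·∇²(M_grow·G_in)` is retained behind
  a switch for comparison; it makes the velocity a third-derivative
  quantity and does not recover the 1D law.
- **Level set**: `∂φ/∂t + F|∇φ| = 0` with Godunov upwinding and
  `F = ∇Ω·n` extended off the interface by nearest-cell values. CFL
  `dt·max|F| ≤ h/2` is enforced. Reinitialization (every 10 steps) uses
  Sussman iterations with interface-adjacent cells anchored to their
  sub-cell crossing distances (pairwise linear crossings, two-axis
  combination): a plain distance-transform rebuild quantizes slow
  interface motion to the grid and stalls growth, while the anchored
  scheme is exactly interface-preserving under repeated application.
  Newly grown cells inherit cellular fields from the nearest previous
  biofilm cell.

Per-biofilm statistics label the connected components of φ < 0 at each
output time, ordered by area (largest first).

## What the generated conditions emulate — and what they do not

All experiment generators use the published conditions: tabulated
parameters, printed initial conditions, 70 ± 25 µm initial-width jitter at
30 mM inlet glutamate for the onset experiment, width 300 µm/20 h for the
sensitivity protocol, 90 mm/h (single) and 10 mm/h (multi-biofilm) inlet
speeds. The 2D fixture shapes are idealized discs and half-discs rather
than digitized experimental footprints, and the multi-biofilm layout uses
one large wall-attached biofilm (radius 0.5 mm) with two smaller discs
(radius 0.28 mm) above and downstream of it, inside the potassium plume
the large biofilm releases — the large one is deeper than the glutamate
penetration length (≈ 0.26 mm) and initiates the oscillation, and the
placement lets each biofilm oscillate at its initial size, which is the
stated design intent of that scenario. Passing
tests show the mechanism (starvation-triggered potassium release,
acclimation-based propagation, growth arrest during hyperpolarization)
behaves as described; they do not calibrate the model against fluorescence
images, and single-cell heterogeneity, ammonium metabolism,
glutamate-dependent potassium uptake and the chamber's third dimension are
all outside the model.

## Known limitations

- With the tabulated constants, the quiescent growth propensity is
  `M_grow ≈ 0.51`, which places the glutamate supply–demand balance point
  at a doubled width near 330–390 µm; the implementation's mean onset size
  sits there (grid- and step-converged), below the 500–600 µm band the
  original study reports. The oscillation amplitude (~130 mM in mean
  potassium) and period (~6–7 h) are correspondingly larger/slower than
  the reported ~75 mM and ~3–4 h. The sensitivity *signs* are nonetheless
  reproduced for 26 of 30 parameters, and the percent magnitudes for
  several of the largest rows.
- The no-leak ablation (removing leak re-uptake from the potassium
  balances only) is linearly unstable as posed: the depolarization loop
  through `V_L = V_L0 + δ_L(K − K_acclimated)` with acclimation lag
  `1/η_K` has gain `g_L·δ_L·2/η_K = 4.8 > 1`, so voltage and potassium
  spike together and diverge. This joint spike *is* the qualitative
  signature the ablation exposes; the variant is analysed on a ≤ 2 h
  horizon and the integrator deliberately raises a stiffness error beyond.
- In 2D the resolved flow delivers far more nutrient than the 1D
  boundary-layer closure (`B_L = 0.5 mm`), so 2D biofilms must be deeper
  than ≈ 0.26 mm from the interface to starve; the single-biofilm scenario
  uses a 0.9 mm-across half-disc. The simulated potassium crest propagates
  at ~2 µm/min — the collective stress wave here is
  starvation-limited, far slower than the ~20–50 µm/min visually estimated
  in the original study, for the same baseline reason as above (cells sit
  too far from the starvation threshold to be triggered quickly by
  arriving potassium).
- First-order upwind advection is diffusive; level-set areas are
  cell-counted (quantized to one cell); the 2D reaction step is explicit
  within the implicit-transport splitting.
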