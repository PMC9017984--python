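# Methods

## Scope and shape

`mdbias` couples two forward mechanistic models: a steady three-compartment
Krogh-cone model of glucose delivery to resting skeletal muscle, and a
radial reaction–diffusion model of the perturbation a glucose-removing
microdialysis probe imposes on the interstitium. Downstream of these sit
the recovery-calibration bias (no-net-flux and internal reference), the
measured-concentration algebra and its inversion, and the apparent
permeability–surface (PS) product. There is no data fitting anywhere in
the pipeline except the one-parameter calibration of the endothelial
diffusion coefficient; the package is therefore organised as solver
functions returning rich result objects (`BiasSolution`,
`TransientSolution`, `CalibrationResult`, `PSResult`, each with a
`summary()`), not as fitted statistical models.

## Three-compartment model

Assumptions: purely diffusive glucose transport in plasma, endothelial
wall and interstitium; uniform volumetric metabolism M; a single capillary
supplying a cone whose radius tapers linearly from r_t,a (arterial) to
r_t,v (venous); steady state.

The axial plasma balance is integrated over the cone with the
per-capillary supply normalised so the whole-tissue balance
F·(C_a − C_v) = M closes exactly; the capillary length then cancels under
the x/L normalisation and never needs a value. The code asserts
C̄(1) = C_v rather than trusting any transcribed polynomial.

Radial drops (all exactly linear in M):

- plasma: M (r_t² − r_w²)/(8 D_p) — ≈1e-5 mM at rest, negligible;
- endothelium: M (r_t² − r_w²) ln(r_w/r_p)/(2 D_w) — ≈0.196 mM at rest,
  the dominant resistance;
- interstitium: M/(4 V_i D_i)·[r_w² − r² + 2 r_t² ln(r/r_w)] — ≈5e-4 mM,
  negligible because D_i is four orders of magnitude above D_w.

Scalar outputs (the quick IGC estimate, the representative endothelial
gradient, the probe-bias sink term) use the cone midpoint radius
r_t = (r_t,a + r_t,v)/2 = 25 µm and the axial midpoint ξ = 0.5; the full
chain and the quick estimate agree within ~0.02 mM at basal parameters.
The interstitial-drop illustration (25 µm beyond the wall) uses r_t,a,
where that distance fits inside the cone.

## Parameters

Internal units are strict SI (m, s, mol·m⁻³); mM ≡ mol·m⁻³. Conventional
units are converted only at the I/O boundary: perfusion in mL/100 mL/min
(÷6000 → s⁻¹), metabolism in µmol/100 mL/min (×1e-6/6e-3 → mol·m⁻³·s⁻¹).

Defaults (basal resting muscle): C_a = 5 mM, F = 4 mL/100 mL/min,
M = 0.8 µmol/100 mL/min, V_i = 0.2, D_i = D_p = 9.2e-10 m²/s,
D_w = 4.50e-14 m²/s, r_p = 2.5 µm, r_w = 3.1 µm, cone radii 28/22 µm.
Probe: R_0 = 0.5, f = 2 µL/min (3.3333e-11 m³/s — the unrounded pump
setting; its 3-digit display 3.33e-11 would shift β from 6.63e-7 to
6.62e-7 m/s), L = 16 mm, r_1 = 250 µm, C_p = 2 mM. D_i is used as given,
with no additional tortuosity factor. All defaults are overridable via
YAML/JSON config or keyword arguments.

## D_w calibration

The wall diffusivity is pinned by the observed ~15 min equilibration of
interstitial tracer after a plasma step. We integrate the time-dependent
radial diffusion equation over [r_p, r_t,mid] — endothelium with
diffusivity D_w and unit storage, interstitium with conductivity D_i·V_i
and storage V_i — with a unit concentration step at r_p and a no-flux
outer boundary, and report when the volume-averaged interstitial
concentration passes a threshold (default 95%; the criterion behind the
experimental "equilibrium" is not documented, so the threshold is an
exposed parameter and the guaranteed property is the calibration
round trip, not the absolute time). The wall dominates the resistance,
making the response near-exponential with
τ ≈ V_i (r_t²−r_w²) ln(r_w/r_p)/(2 D_w) ≈ 294 s, so 95% ≈ 3τ ≈ 15 min at
the default D_w. Inversion is by Brent root finding on log10 D_w;
round-trip accuracy is well under 1%.

## Steady probe-bias model

The probe is an infinite cylinder section of radius r_1 and membrane
length L (no tip end effects); capillaries are treated as a homogeneous
distributed source because their spacing (~50 µm) is small compared with
the probe (500 µm) and the screening length (~640 µm). The local resupply
is first-order: the extra extraction depresses plasma concentration
(timescale 1/(2F)) and steepens the wall gradient (timescale
(r_t²−r_w²) ln(r_w/r_p)/(2 D_w)); their sum A ≈ 2.2e3 s sets the
screening length λ = √(D_i V_i A) ≈ 0.64 mm.

The primary solution is the exact decaying solution of the modified
Helmholtz operator, C_i(r) = C_i,0 + B K_0(r/λ), with B fixed by the Robin
condition at the membrane. The flux sign convention is that inward
diffusion balances probe uptake, D_i V_i dC_i/dr|r1 = +β (C_i(r_1) − C_p),
which is the orientation consistent with a field rising from the probe to
the far field. A conservative finite-volume discretisation on a log-spaced
grid (Robin at r_1, Dirichlet at r_2) is retained purely as an independent
oracle; the two agree to <1e-5 relative at default resolutions.

Numerical choices: outer boundary r_2 = 50 r_1 = 12.5 mm ≈ 20λ, with a
hard error if r_2/λ < 8 (unconverged tail); log-spaced output grid (400
nodes by default); concentrations are not clamped — a negative field
triggers a warning since the linear resupply closure is then outside its
validity. By linearity the bias amplitude α = (C_i,0 − C_i,eff)/(C_i,0 − C_p)
is independent of the concentration pair; `alpha()` uses one solve with an
arbitrary pair.

## Transient model and tracer

The time-dependent form adds the time derivative to the steady operator,

    ∂C_i/∂t = D_i V_i ∇²_r C_i − (C_i − C_i,0)/A,

integrated by method of lines (conservative finite volumes, stiff BDF with
the exact sparse Jacobian, geometric output times). The storage term has
unit capacity by default: this is the form whose characteristic
(1 − 1/e) times — 125, 282 and 23 s at β, β/4 and 4β — match the
independently known 120/270/24 s family; scaling the storage by V_i
(`vi_capacity=True`) relaxes exactly 1/V_i-fold faster and is kept for
sensitivity analysis. The relaxation is not single-exponential: the wall
trace completes most of its drop within a few τ, while strict 99%
completion waits on the far field adjusting over A ≈ 2.2e3 s, so
"time to steady state" quotes of ~5τ correspond to an exponential-tail
convention rather than a strict completion fraction;
`steady_state_time()` implements the strict 99% definition.

The tracer problem (internal-reference calibration) is the exact mirror:
zero far field, Robin flux driven by the perfusate tracer content, plus an
optional metabolic sink M·C_i*/C_i(r) evaluated on the native steady
field; that term shifts the steady wall ratio by <1%, so
C_i*(r_1, t)/C_p* tracks α̃(t) closely, and both calibration techniques are
biased by the same factor 1 − α̃(t).

## Calibration bias and correction

Dialysate concentration C_d = (1−R_0) C_p + R_0 C_i,eff stays exactly
linear in C_p under removal (the removal rescales the slope), so
no-net-flux regression returns R_m = (1 − α̃) R_0 with perfectly collinear
points; α̃ at a finite wait time comes from one transient solve
(pair-independence makes it grid-independent, which the code verifies
rather than assumes). Propagating both biases,
C_i,m = [(1−α) C_i,0 + (α−α̃) C_p]/(1−α̃), which interpolates between
C_i,eff (unbiased calibration) and C_i,0 (fully equilibrated calibration,
biases cancel); `correct_igc` is its exact algebraic inverse. The tracer
expression for R_m assumes the tracer is a trace species (C_p* much
smaller than glucose concentrations); behaviour outside that regime is
not modelled.

## PS product

PS = −F ln[(C_v−C_i)/(C_a−C_i)] is strictly increasing in C_i on (0, C_v),
so underestimated IGC yields underestimated PS. `ps_measured` composes the
steady bias map with this expression. When C_i ≥ C_v (elevated extraction)
the expression has no finite value and the code raises rather than
returning a number. Values are reported in s⁻¹ with a convenience
conversion to ×10⁻⁴ mL/mL/s.

## Known limitations

- Constant D_w per run: no metabolism- or shear-dependent endothelial
  permeability (users can change D_w between runs).
- No convective interstitial transport, probe insertion trauma, capillary
  network topology or recruitment, or saturable transport.
- The scenario sweep generator (`generate_fixtures`) spans the
  physiological ranges of the bias-model illustrations (C_i,0 2–8 mM,
  C_p 0–4 mM, β ×0.25–4, F 1–40 mL/100 mL/min, M ×1–15) via a seeded
  Latin hypercube; it produces parameter sets, not synthetic measurement
  noise, so passing tests demonstrate internal consistency of the models,
  not agreement with any particular experiment.
- Problem sizes used by the test suite and the acceptance script (400
  radial nodes steady, 300 nodes × ~800 time points transient, 90-cell
  equilibration grid) were chosen so refinement changes headline outputs
  by <2‰ (steady) and <2% (transient characteristic times).
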