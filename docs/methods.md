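# Methods

`vasapf` simulates two pathologies of a muscular artery cross-section that
share a single root cause — dysfunction of the vasa vasorum (VV), the
microvessels that nourish the outer wall: inflammatory wall thickening
(atherosclerosis) and intramural-hematoma-driven delamination (dissection).
Four fields are solved monolithically on the same mesh: the displacement
**u** (finite-strain mechanics), the dimensionless nutrient concentration
c, an Allen–Cahn phase field φ marking inflamed / hematoma tissue, and a
phase field d regularizing the rupture surface.

## Governing model

**Mechanics.** Quasistatic balance ∇·σ = 0 with the multiplicative growth
split F = F_e F_g, F_g = (1+α)I. The elastic response is nearly
incompressible neo-Hookean,

    Ψ = (μ/2)(Î₁ₑ − 3) + κ(J_e − 1)² + μ(J_e − 1 − log J_e),
    κ = νμ/(1 − 2ν),

with μ = 30 kPa, ν = 0.49. The volumetric part uses the compensated log
form: it vanishes to second order at J_e = 1 (stress-free reference), is
non-negative for every J_e > 0, and keeps the logarithmic compression
barrier. Its small-strain bulk modulus, 2κ + μ, sits 0.7 % above the
linear-elastic value — inside the package's 1 % small-strain verification
band. The Cauchy stress is σ = J_e⁻¹ (∂Ψ/∂F_e) F_eᵀ, evaluated
analytically.

**Damage coupling.** The stored energy is degraded by
g(d) = (1−d)² + d·d_min (d_min = 10⁻⁴): the isochoric part always, the
volumetric part only in tension (J_e > 1). A compressed, fully damaged
region therefore supports hydrostatic pressure but essentially no shear —
this is how the blood-pressurized aperture of a hematoma is represented
without an explicit fluid phase. The crack driver is the *undegraded*
tensile energy Ψ_drive = Ψ_iso + [J_e > 1] Ψ_vol; degrading the driver
itself would stall crack growth. Irreversibility enters through the
history variable Ψ_max (running maximum of Ψ_drive per Gauss point) and,
as a numerical belt-and-braces, a post-step clamp d ← max(d, d_prev):
Allen–Cahn relaxation alone can locally decrease d, which would amount to
healing.

**Nutrient.** Steady diffusion–reaction ∇·(D∇c) = R_c s(c), with
D = φ D_min + (1−φ) D_max (10³ → 1 µm²/T as tissue inflames) and
R_c = 10⁻². The sink carries a smooth saturation s(c) = 1 − e^(−c/0.1):
consumption is proportional to availability when nutrient is scarce and
uniform where it is plentiful. This keeps c non-negative; a hard one-sided
cutoff at c = 0 creates an under-resolved reaction layer (≈1 µm at
D_min = 1) that destabilizes the coarse-mesh Newton iteration.

**Phase fields.** Both φ and d follow Allen–Cahn dynamics with the
quartic double well f(φ) = 16Mφ²(1−φ)² (M = 1, barrier and mobility not
distinguished) and interface parameters ε = 25 µm (read as a length so
ε²∇²φ is dimensionally consistent on the µm mesh) and l = 2 h_fine. The
sources:

* hematoma (dissection): S_φ = R_s c d, R_s = 100 — blood availability
  times rupture openness;
* inflammation (atherosclerosis): S_φ = R_s max(c_th − c, 0)/c_th — a
  linear ramp below the nutrient threshold c_th, saturating at R_s. The
  threshold is a free model parameter; the default c_th = 0.25 places the
  inflamed zone in the genuinely starved outer wall (the baseline
  concentration bottoms out near 0.17 with the occluded VV) without
  recruiting more than roughly the outer third of the wall. Larger
  thresholds inflame so much tissue that the confined swelling buckles
  the stiff inner ring (see *Stability limits*).
* damage: S_d = −g′(d) Ψ_max / G_f with the fracture resistance
  G_f = Ψ_cri/l = 100 kPa.

**Growth.** α̇/(1+α) = k_g φ̇ with k_g = 10 (dimensionless). The implicit
update is the closed-form root α₊ = (α_n + k)/(1 − k), k = k_g Δφ,
requiring k < 1 per step (guarded; violations trigger a time-step cut).
Integrated exactly, 1 + α = e^{k_g φ}: full inflammation implies a 22000×
volumetric overgrowth, which is why the simulations study the early phase
(below).

## Discretization and solver

Bilinear quad4 elements (trilinear hex8 in 3D) with 2×2(×2) Gauss
quadrature; 5 DOF per node in 2D plane strain (u_x, u_y, c, φ, d), 6 in
3D. Plane strain embeds states in 3×3 tensors with unit total out-of-plane
stretch, so the out-of-plane elastic stretch is 1/(1+α). All integrals are
pulled back exactly to the reference configuration (dv = J dV, spatial
gradients via F⁻ᵀ); the damage block is formulated entirely in the
reference configuration. The follower lumen pressure acts on the deformed
facet geometry with an analytic tangent. Sources use current-iterate
values (fully implicit). No stabilized or mixed formulation is used for
the near-incompressibility; ν = 0.49 with the penalty-style volumetric
term is taken as given, so some volumetric locking of Q4 elements is
accepted.

Element tangents are consistent central finite differences of the element
residual (step 10⁻⁶ relative per column); the growth sensitivity ∂α/∂φ is
thereby included automatically. Global solution is a monolithic
Newton–Raphson with a sparse direct factorization, backward Euler in
pseudo-time, and:

* a backtracking line search on the composite residual norm (trial
  iterates that invert an element halve the update);
* a per-field RMS-scaled convergence norm, relative to the peak residual
  seen per field over the whole march (`newton_tol = 10⁻⁸`). A stagnated
  iterate below `newton_stall_tol = 10⁻⁵` is accepted: the residual is
  non-smooth (tension/compression switch, history kink, clamps) and the
  perturbation tangent has a noise floor in regions of extreme volumetric
  stiffness (J_e ≈ 0.05 in the compressed hematoma);
* time-step cuts (factor 0.5, up to 8) on Newton failure, with a
  three-step cooldown before the step grows again (factor 1.25);
* the lumen pressure ramped adaptively to its full value before any phase
  evolution, with φ and d frozen during the ramp;
* after each accepted step, d clamped non-decreasing and both phase
  fields projected to [0, 1] — the sources are not gradient flows of a
  bounded functional, so overshoot is otherwise unbounded.

The nutrient block is steady (no rate term); the initial state solves it
alone on the undeformed, uninflamed wall.

## Geometry, VV network, boundary conditions

The domain is a half annulus (inner radius 600 µm, wall 400 µm) meshed by
a structured polar grid: radial spacing at the fine target size, angular
spacing graded from h_fine inside the sector containing the VV tree to
h_coarse outside (geometric transition, ratio 1.3). The VV network is a
binary tree fractal rooted on the outer wall at θ = 0: trunk L₀ = 80 µm
pointing inward, three branching levels with unit length ratios and
sibling branch angles 2π/3, each branching angle jittered uniformly by
±0.1 rad from a seeded generator (only angles are stochastic). Segments
are clipped at mid-wall depth. The occlusion splits the trunk 30 µm from
its root; everything distal is occluded. Nutrient c = 1 is prescribed on
the lumen and on nodes within h_fine of non-occluded segments (the VV is
a Dirichlet source, the simplest 1D-to-continuum coupling).

Cut faces lie on the y-axis, so the tangential-displacement symmetry
condition is u_x = 0. The outer wall is clamped (`tether_outer`):
physically the adventitia is tethered by perivascular tissue, and
mechanically a *free* neo-Hookean annulus of this geometry has a finite
inflation limit pressure μ ln(r_out/r_in) ≈ 15.3 kPa — *below* the
120 mmHg ≈ 16 kPa systolic load, so no static equilibrium would exist.

Scenario switches: atherosclerosis pins d ≡ 0 (infinite-strength limit;
the fracture override G_f = 10⁹ kPa is applied as well) and activates the
inflammation source; dissection keeps G_f = 100 kPa, activates the
hematoma source, and pins d = 1 in a disc of radius r₀ = 2 h_fine at the
occlusion point — the ruptured VV micro-injury that seeds the hematoma.

## Study windows and problem sizes

Reference desk-scale runs (`scenario_preset`) use the full artery
geometry with coarsened meshes: `tiny` ≈ 270 elements (h = 100/50 µm) and
`small` ≈ 1300 elements (h = 60/20 µm); the full-resolution defaults
(h = 20/2 µm, ≈1.5×10⁵ DOF) are configured but not exercised by the test
suite. Evolution windows cover the early phase of each pathology:
dissection to t = 1.5×10⁻³ (hematoma φ ≈ 0.15, overgrowth 1+α ≈ 4, the
rupture front visibly propagating), atherosclerosis to t = 4×10⁻⁴
(lesion φ ≈ 0.025, α ≈ 0.28). The "lesion core" used in assertions is the
region where φ exceeds half its current maximum — a relative threshold,
since the exponential growth law makes saturated inflammation (φ → 1)
mechanically unreachable (see below) and the reference field plots carry
no numeric scale.

## Stability limits

Two genuine instabilities bound the simulated windows; they are properties
of the model at these parameters, not solver artifacts:

1. **Growth blow-up.** With k_g = 10, tissue at φ ≳ 0.5 demands e⁵ ≈ 150×
   linear overgrowth. Confined by the tether, the elastic Jacobian would
   collapse (J_e → 10⁻¹¹) and the volumetric stiffness μ/J_e² exceeds any
   workable conditioning. Desk-scale runs therefore study the
   early-lesion phase.
2. **Inner-ring buckling (atherosclerosis).** The swelling band compresses
   the un-inflamed inner ring circumferentially; past a critical swelling
   the symmetric equilibrium path reaches a fold (Newton stalls at the
   same pseudo-time for every Δt). With c_th = 0.25 the fold sits near
   t ≈ 6×10⁻⁴; the study window ends at 4×10⁻⁴. Tracking the buckled
   branch would require arc-length continuation, which is out of scope.

## What the synthetic conditions do and do not show

All inputs are generated (annulus mesh, seeded VV tree); no empirical
data enters. Passing tests therefore demonstrate the *mechanisms* —
nutrient starvation → inflammation → confined overgrowth → compressive
lesion with tensile shell; micro-rupture → blood-fed hematoma → pressurized
aperture with near-zero von Mises stress, crack-tip concentration and a
radial displacement jump — on an idealized single-layer isotropic wall.
They do not validate against histology or imaging, do not capture layered
anisotropy (no fiber families), residual stresses, lumen blood flow, or
3D axial propagation (a coarse hex8 extrusion exists but only the element
architecture is exercised).

## Numerical parameters at a glance

| Parameter | Default | Notes |
|---|---|---|
| μ, ν | 30 kPa, 0.49 | neo-Hookean wall |
| k_g | 10 | growth per unit φ (dimensionless) |
| R_c, D_max, D_min | 10⁻², 10³, 1 | nutrient sink / diffusivities |
| R_s | 100 | hematoma/inflammation rate |
| M, ε | 1, 25 µm | double-well barrier, interface width |
| l, η_d, d_min | 2 h_fine, 0.01, 10⁻⁴ | damage length, viscosity, residual |
| G_f = Ψ_cri/l | 100 kPa | inter-layer fracture resistance |
| p_max | 120 mmHg = 16.0 kPa | follower lumen pressure |
| c_th | 0.25 | inflammation threshold (invented) |
| K_c, K_φ, K_d | 1 | field scalings in the weak form |
| newton_tol / stall | 10⁻⁸ / 10⁻⁵ | scaled residual norms |
| Δt (dissection / athero) | 5·10⁻⁵ / 2·10⁻⁵ | with cuts ×0.5, growth ×1.25 |
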