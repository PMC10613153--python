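# vasapf

Phase-field multiphysics finite-element model of vasa-vasorum-driven
arterial disease: inflammatory wall thickening (atherosclerosis) and
intramural-hematoma-driven dissection, in one coupled framework.

The vasa vasorum (VV) are the microvessels that nourish the outer wall of
large and medium arteries. The model follows the hypothesis that their
dysfunction is the common root of both pathologies: an *occluded* VV
starves the wall of nutrient and triggers inflammatory overgrowth; a
*ruptured* VV bleeds into the wall, and the pressurized hematoma wedges
the layers apart like a hydraulic fracture.

`vasapf` is aimed at computational-biomechanics researchers who want an
open, tested, desk-scale implementation of that coupled model: four nodal
fields — displacement **u**, dimensionless nutrient c, inflammation /
hematoma phase φ and damage phase d — solved monolithically with
Newton–Raphson and backward Euler on a quad4/hex8 mesh.

## Model core

* Finite-strain mechanics with multiplicative volumetric growth
  F = F_e F_g, F_g = (1+α)I, and the growth law α̇/(1+α) = k_g φ̇
  (so 1+α = e^{k_g φ}); nearly incompressible neo-Hookean energy
  Ψ = (μ/2)(Î₁ₑ−3) + κ(J_e−1)² + μ(J_e−1−log J_e), σ = J_e⁻¹ ∂Ψ/∂F_e F_eᵀ.
* Steady nutrient diffusion–reaction ∇·(D(φ)∇c) = R_c s(c) with
  D = φD_min + (1−φ)D_max; c = 1 on every blood-contact surface (lumen
  and unoccluded VV segments).
* Allen–Cahn phase dynamics φ̇ = −f′(φ) + ε²∇²φ + S_φ with the double
  well f = 16Mφ²(1−φ)², where S_φ = R_s·c·d (hematoma) or a threshold
  ramp R_s max(c_th−c,0)/c_th (inflammation).
* Phase-field damage η_d ḋ = −d + l²∇²d − g′(d)Ψ_max/G_f with
  g(d) = (1−d)² + d·d_min, the tension/compression split H_J = [J_e ≤ 1]
  (compressed volumetric energy is never degraded — that is the
  pressurized aperture), and the history variable
  Ψ_max = max over time of the undegraded tensile energy.
* Follower systolic pressure (120 mmHg ≈ 16 kPa) on the deformed lumen;
  stochastic tree-fractal VV geometry (trunk 80 µm, three binary levels,
  sibling angles 2π/3, seeded angular jitter) with a trunk occlusion.

See `docs/methods.md` for assumptions, parameter table, numerical
choices and known limitations.

## Worked example

Run the desk-scale atherosclerosis scenario (≈270-element mesh, seeded
VV tree, 20 time steps — about half a minute):

```
$ vasapf run --mode atherosclerosis --preset tiny --seed 3 --out out/
atherosclerosis: 20 steps to t=4.0000e-04
  phi_max=0.0245 d_max=0.0000 c_min=0.0267 alpha_max=0.2737
  wrote out/atherosclerosis_0000.vtk
  ...
  wrote out/atherosclerosis_path.csv
```

Reading the numbers: the occluded VV leaves the outer wall starved
(`c_min` ≈ 0.03 against 1.0 at the lumen), inflammation has reached
φ ≈ 0.025 there, which by the growth law means a 27 % stress-free
growth stretch (`alpha_max` ≈ 0.27, roughly doubling the local unloaded
volume) — and the damage field stays identically zero: the wall thickens
without rupturing. The VTK series
holds u, c, φ, d plus cell stresses and von Mises for ParaView; the CSV
is the radial profile through the lesion (σ_rr, σ_θθ, von Mises, u_r, c,
φ, d). Switching `--mode dissection` activates the finite fracture
resistance and the damaged nucleus at the VV occlusion: the hematoma
pressurizes (mean aperture pressure of order 10² kPa, near-zero von
Mises inside, stress concentration at the front) and the rupture area
grows monotonically, with a radial-displacement jump across the
delamination tens of times larger than in the atherosclerotic wall.

Library use mirrors the CLI:

```python
from vasapf import run_scenario, scenario_preset
result = run_scenario(scenario_preset("dissection", "small", seed=1))
print(result.rupture_area[-1] / result.rupture_area[0])  # front growth
```

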