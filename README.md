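# arterymech

Residual stress, pressurized inflation and tear-initiation analysis for a
two-layer (media + adventitia) arterial wall, modelled as an incompressible
plane-strain Holzapfel–Gasser–Ogden (HGO) fibre-reinforced hyperelastic
cylinder. The package is aimed at soft-tissue biomechanics researchers who
need a fast, fully analytical counterpart to finite-element dissection
models: it solves the opening-angle boundary-value problem exactly (to
quadrature/root-finding precision), so FE results can be verified against
it, parameter sweeps run in milliseconds, and residual-stress effects can be
explored without meshing anything.

## The model

An unloaded artery ring Ω_r is not stress-free: cut radially, it springs
open into a sector Ω₀ with *opening angle* α. For an incompressible
plane-strain material (axial stretch λ_z = 1) the closing map is purely
kinematic,

```
r(R) = sqrt((R² − R_i²)/k + r_i²),   θ = kΘ,   k = 2π/(2π − α),
λ_r = R/(rk),   λ_θ = kr/R,
```

and the single unknown — the closed inner radius r_i (or, inversely, the
open inner radius R_i) — is fixed by radial equilibrium with traction-free
surfaces:

```
∫ (σ_θθ − σ_rr) dr/r = 0   over the wall.
```

Each layer is an HGO solid, `W = c(I₁ − 3) + Σₙ k₁/(2k₂){exp[k₂(Iₙ−1)²] − 1}`,
with two mirrored collagen-fibre families at ±β from the circumferential
direction that bear load only in extension. In the plane-strain
idealization the axial component of the fibre direction is ignored, so
I₄ = λ_θ²cos²β and fibres engage only where λ_θ > 1/cosβ. The nonlinear
integral equation is solved by safeguarded bracketing on per-layer
Gauss–Legendre quadrature (panels split at the fibre-engagement radius),
and the transmural Cauchy stress follows by cumulative quadrature plus the
constitutive law. The same boundary-value problem with an inner pressure
gives the inflated configuration, and a linear cohesive law
(G_c = ½ T_c Δu_c) supplies a maximum-principal-stress tear-initiation
criterion — an axisymmetric, tear-free surrogate for crack-resolved
critical pressures, useful for trends only.

## Worked example

Close the packaged rabbit carotid stress-free sector (R_i = 1.430 mm,
media 0.260 mm, adventitia 0.130 mm, α = 160°) into its unloaded,
residually-stressed ring:

```python
import arterymech as am

fx = am.fixture("rabbit_omega0")
annulus, state = am.solve_unloaded(fx.sector, fx.materials)
print(f"r_i = {annulus.r_i:.4f} mm, t_m = {annulus.t_m:.4f} mm, "
      f"t_a = {annulus.t_a:.4f} mm")
print(f"hoop stress: {state.s_tt[0]:.3f} kPa at the inner surface, "
      f"{state.s_tt[-1]:.3f} kPa at the outer surface")
```

prints

```
r_i = 0.7377 mm, t_m = 0.2597 mm, t_a = 0.1199 mm
hoop stress: -0.892 kPa at the inner surface, 0.121 kPa at the outer surface
```

The closed ring is markedly smaller than the open sector, its inner media
rim sits in circumferential compression and the adventitia's outer rim in
tension — the classic residual-stress pattern that flattens the transmural
stress gradient once the vessel is pressurized. The same solve from the
command line:

```
arterymech close --config run.yaml --out profile.csv
```

with `run.yaml` containing `geometry: rabbit_omega0` and
`materials: rabbit`. Subcommands `open`, `inflate`, `sweep`, `initiation`,
`cohesive-check` and `fixtures` cover the inverse solve, pressurization,
parameter sweeps and the cohesive-law utilities.

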