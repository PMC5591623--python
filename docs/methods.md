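# Methods

## Problem and assumptions

The artery is an infinitely long, two-layer, incompressible thick-walled
cylinder in plane strain (λ_z = 1 throughout). Three configurations play a
role: the stress-free open sector Ω₀ (inner radius R_i, media–adventitia
interface R_m, outer radius R_o, opening angle α), the unloaded but
residually-stressed closed annulus Ω_r (r_i, r_m, r_o, zero surface
tractions), and pressurized states with lumen pressure p. A single opening
angle applies to the composite ring — both layers open and close as one
continuous sector — and all maps preserve volume exactly:

    r(R) = sqrt((R² − R_i²)/k + r_i²),  θ = kΘ,  k = 2π/(2π − α),
    λ_r = R/(rk),  λ_θ = kr/R,  λ_z = 1.

## Constitutive law

Each layer is Holzapfel–Gasser–Ogden:
W = c(I₁−3) + Σ_{n=4,6} w(I_n), with
w(I) = k₁/(2k₂){exp[k₂(I−1)²] − 1} for I > 1 and 0 otherwise. The switch is
a hard branch at I = 1 (w is C¹ there; no smoothing). The two fibre
families lie at ±β from the circumferential direction; under the
plane-strain idealization their axial component is ignored, so both
families share the in-plane structure tensor diag(0, cos²β, 0) and

    I₄ = I₆ = λ_θ² cos²β.

Consequences worth knowing:

- fibres engage only where λ_θ > 1/cosβ, so β only scales the
  circumferential fibre contribution;
- for β ≥ 30° engagement needs λ_θ > 1.155, which the residual-stress
  states of the packaged fixtures never reach — those computations coincide
  exactly with the fibre-free (k₁ = 0) matrix, and the test suite asserts
  this;
- the fibres contribute to σ_θθ only; σ_rr and σ_zz are matrix + pressure
  terms. With the Lagrange multiplier 𝔭 = −σ_rr + 2cλ_r², the stress
  difference that drives equilibrium is
  σ_θθ − σ_rr = 2c(λ_θ² − λ_r²) + 4w′(I₄)λ_θ²cos²β.

Units are fixed package-wide: lengths mm, stresses and energy densities
kPa, angles degrees at every public interface (radians internally).
Cohesive separation energy is quoted in N/mm; since traction is kPa and
separation mm, G_c = ½·T_c·Δu_c·10⁻³. The packaged rabbit values
(T_c = 3 kPa, Δu_c = 0.667 mm → G_c ≈ 0.001 N/mm; adventitia one tenth of
that) are consistent under exactly this convention.

## Solving the boundary-value problem

Radial equilibrium dσ_rr/dr = (σ_θθ − σ_rr)/r with traction-free surfaces
reduces to one scalar integral condition, ∫(σ_θθ−σ_rr)dr/r = 0, a nonlinear
equation in the closed inner radius r_i (forward problem) or the open inner
radius R_i (inverse problem). Numerical choices:

- **Quadrature.** Per-layer Gauss–Legendre of order 40 (an order-80
  refinement agrees to 10⁻¹⁰ relative and is asserted in the tests). The
  layer interface is always a panel boundary, and panels are additionally
  split at the closed-form fibre-engagement radius (where λ_θcosβ = 1),
  because the energy switch makes the integrand C¹ but not C² and an
  unsplit panel would cost five orders of accuracy.
- **Coordinate.** Both the forward and the inverse condition are integrated
  in the deformed coordinate r. Integrating the forward condition in the
  reference coordinate R looks natural but is numerically treacherous: when
  a trial radius closes the ring almost to a point, the λ_r² term develops
  a boundary layer that in R-coordinates collapses into an interval of
  width ~r_i² and is silently missed by fixed-order quadrature, producing a
  spurious root.
- **Root finding.** Safeguarded bracketing (Brent) instead of raw Newton;
  brackets [0.01·R_i, R_o] forward and [r_i, 10·r_i] inverse, the latter
  auto-expanded ×10 (up to 10⁴·r_i) for strongly fibre-reinforced walls
  whose sectors open very wide. Convergence to machine precision
  (xtol 10⁻¹³).
- **Stress profile.** σ_rr by cumulative per-interval Gauss quadrature
  (order 6, with the same engagement split and geometric panel grading so
  no panel is wider than half its distance from the axis); σ_θθ and σ_zz
  pointwise from the constitutive law. The default output grid has 401
  nodes with the interface node duplicated and layer-tagged, so the
  physical jump of σ_θθ across the interface is representable while σ_rr
  stays continuous. Profile accuracy is independent of grid density; a
  consistency check rejects sector/annulus pairs whose outer surface comes
  out non-traction-free beyond 10⁻⁶·c_media.

Inflation is the same boundary-value problem with σ_rr(r_i) = −p; the
deformation is composed directly from Ω₀ with the same k, so
incompressibility is exact at every pressure.

## Tear initiation estimator

The cohesive law is linear (triangular): traction T_c at zero separation,
zero at Δu_c, area G_c; damage is irreversible with secant
unloading/reloading to the origin (the unloading rule is a standard
cohesive-zone convention; it is not prescribed by the underlying
experimental law). Initiation uses the maximum-principal-stress criterion
σ_mp ≥ T_c (inclusive); in the shear-free axisymmetric states σ_mp is
simply the largest diagonal component. Propagation direction is
perpendicular to the largest tensile principal stress — radial when the
hoop stress dominates.

`initiation_pressure` bisects for the smallest lumen pressure at which
σ_mp reaches T_c. Two monitoring modes:

- **wall-wide maximum** (default): conservative, but at large opening
  angles the worst point migrates to the media's outer half where the
  *residual* hoop tension itself grows with α, so the estimate is not
  monotone in α (for the rabbit fixture it peaks near α ≈ 80° and falls
  after);
- **defect-local** (`at_radius=`): monitors one material point, given by
  its radius in Ω_r and tracked through the deformation — e.g. the inner
  surface, where an intimal defect sits. This is the mode that mirrors
  crack-resolved critical-pressure trends: for the rabbit fixture the
  estimate rises strictly with α (p/c = 0.32 → 0.70 over α = 0…200°),
  and the inner-surface hoop stress at fixed p = 0.3·c falls strictly
  (2.73 → 0.55 kPa) — residual stress protects the inner wall.

Both modes ignore the tear geometry (arc length, faces, contact) and
inner-wall buckling entirely; the estimator is a lower-fidelity surrogate
whose absolute values should not be compared against crack-resolved
simulations.

## Synthetic parameter generator

`draw_parameter_set(seed)` draws admissible two-layer problems for property
testing: geometry around carotid scale (R_i uniform in [0.4, 3] mm, each
layer 5–30 % of R_i thick), opening angle uniform in [0°, 220°], stiffness
parameters log-uniform (c in [0.1, 50] kPa, k₁ in [0.01, 120] kPa, k₂ in
[0.1, 30]), fibre angle uniform in [0°, 90°], cohesive strength tied to the
matrix (T_c = 2c). The ranges deliberately bracket both packaged material
sets and extend far beyond them, which is what exposed the quadrature and
bracketing pathologies above. The generator is pinned to numpy's PCG64 bit
generator so seeds are portable. What the draws do *not* emulate: axial
prestretch, fibre dispersion, layer-specific opening angles, smooth-muscle
tone, or measurement noise in geometry — passing the round-trip and
solver-robustness tests says nothing about those effects in real vessels.
`noisy_profile` adds seeded multiplicative Gaussian noise to stress
profiles (boundary nodes kept exact) for the opening-angle recovery
experiments; 1 % noise yields mean recovery errors well under 2°.

## Known limitations

- Plane strain with λ_z = 1: no axial prestretch, although in vivo arteries
  carry substantial axial stretch that engages fibres axially.
- The published reference geometry table that the fixtures store carries
  internal numerical slop of a few 10⁻³ mm between its rows; the solvers
  here are mutually consistent (forward∘inverse round trips to 10⁻¹⁴ mm)
  and match the highest-precision rows of that table essentially exactly,
  but reproduce other rows only to ~2·10⁻³ mm.
- The initiation estimator has no tear, no contact and no buckling; only
  trends across opening angle are meaningful.
- The cohesive law is scalar and isotropic; radial–circumferential strength
  anisotropy of real aortic tissue is not represented.
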