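# Methods

## Governing model

The vessel wall is an axisymmetric, linearly elastic thick-walled cylinder
with radially varying properties E(r), ν(r), ρ(r). Displacements
u = (u_r(r,z,t), u_z(r,z,t)) obey the elastodynamic momentum balance

```
∂σ_rr/∂r + ∂σ_rz/∂z + (σ_rr − σ_θθ)/r = ρ ü_r
∂σ_rz/∂r + ∂σ_zz/∂z +  σ_rz/r        = ρ ü_z + ρ g
```

with Hooke's law in cylindrical coordinates (λ(r), G(r) from E, ν; ν is
capped at 0.4995 to keep the near-incompressible limit well posed). The
inner surface carries the lumen pressure (σ_rr = −P(z,t), σ_rz = 0), the
outer surface is traction free, and the ends are built in (u = 0) by
default; a `sliding` end option (u_z = 0, σ_rz = 0) is provided for
closed-form benchmarking, because under sliding ends the plane-strain Lamé
solution is the exact continuum solution. With built-in ends the true
solution differs from Lamé by several percent at mid-length even for
length-to-thickness ratio 10 (a long-range Saint-Venant end effect), so the
closed-form agreement property is meaningful only under sliding ends.

### Wall models

- Homogeneous, power-law property fields (E = a·r^b + c per property),
  FGM grading p(ξ) = p_in + (p_out − p_in)·ξⁿ over the normalized thickness
  ξ, and a three-layer natural wall (intima:media:adventitia = 1:6:3 by
  default, optional tanh smoothing of the interfaces).
- The FGM endpoints are returned exactly (no floating-point drift at
  ξ = 0, 1) for every heterogeneous index n.

### Reduced-order lumen model

The inlet waveform (half-sine pulse P0·sin(πt) or tabulated periodic data)
is marched along the axis with the Poiseuille gradient
dP/dx = −8 μ Q/(π r⁴) using a classical fourth-order integrator. The local
radius is either the quasi-static thin-wall equilibrium radius
r = E t r_in / (E t − P r_in) or, in two-way coupling, the structural wall
radius. Zero flow or zero viscosity reproduces the inlet waveform exactly
along the whole length.

## Discretizations

Two structurally independent spatial discretizations solve the same
continuum problem; their agreement is the package's primary correctness
evidence.

Both assemble the momentum operator in **divergence form** — the moduli are
never differentiated. This matters for graded walls: a heterogeneous index
n < 1 makes the property slope unbounded at the inner surface
(dE/dξ ∝ ξ^{n−1}), so any scheme that differentiates the coefficients (the
"expanded" form with λ′, G′ terms) loses consistency exactly where the load
enters. The stresses appearing in the divergence stay smooth there, because
the momentum balance itself bounds their derivatives.

### Differential quadrature (DQM)

Chebyshev–Gauss–Lobatto nodes on each axis; first-order weighting matrices
from the Lagrange product formula and second-order ones from the standard
recurrence. The momentum rows are the nodal divergence of the collocated
stresses (D_r·S_rr + D_z·S_rz + (S_rr − S_tt)/r, etc.). Surface tractions
and end constraints replace the boundary rows. Polynomial exactness to
degree n−1 is verified by tests. On graded walls the global polynomial
approximates a displacement field whose radial derivative has a ξⁿ-type
cusp, so convergence is algebraic and high degrees (n_r ≳ 30) begin to
oscillate; the DQM grids are therefore kept small (13–21 radial nodes),
which is also where the method is cheapest.

### Finite differences (FD)

Uniform grid, second-order central interior stencils. The radial
derivative terms use a **staggered flux-conservative** form,

```
∂/∂r (c g)|_i ≈ [c_{i+1/2} g_{i+1/2} − c_{i−1/2} g_{i−1/2}] / h,
```

with midpoint moduli sampled exactly from the material law. Surface
boundary conditions are **half-cell (finite-volume) momentum balances**: the
prescribed traction enters as the boundary flux, and the radial
displacement gradient at the surface — the quantity with the grading cusp —
is eliminated exactly through the traction condition instead of being
one-sided-differenced. (A one-sided σ_rr collocation row misestimates the
inner traction by ~70 % on the exact n = 0.2 solution; the half-cell form
restores clean second-order convergence, verified against a high-accuracy
1D radial boundary-value solution.) The end planes keep strong constraint
rows. Because the enforced surface condition is the integrated balance, the
*recovered* pointwise surface stress of the FD solver is a one-sided
post-processing estimate that converges with the grid rather than being
exact to round-off; the DQM solver's recovered surface traction is exact.

### Row equilibration and time integration

Momentum rows scale like E/h² while constraint rows are O(E/h) or O(1);
each row of (M, K, F) is scaled by its max-|K| entry before factorization,
which preserves the solution and keeps the LU accurate on fine grids.
Time integration is Newmark-β (average acceleration, β = 0.25, γ = 0.5).
Constraint rows carry no mass, so tractions and end conditions hold exactly
at every time level. The linear solves reuse a single factorization
(dense LAPACK below 4000 unknowns, sparse LU above).

## Two-way coupling

Per time step, the lumen pressure march (with the wall radius from the
current interface displacement) alternates with a structural Newmark trial
step; the interface displacement is under-relaxed (factor 0.7) and the step
is accepted when the relative change of the interface-displacement norm and
of the mean lumen pressure both fall below the coupling tolerance (1e-3).
Every iteration is logged (step, time, iteration, both residuals);
non-convergence raises with the tail of the log.

## Validation experiment and its norm

The benchmark scenario is a graded cylinder (radii 0.8/1.0 m, ν = 0.3,
power-law E and ρ, half-sine 16 kPa pressure) solved by both
discretizations over one loading period. Discrepancies are reported as
100·max|a−b|/max|ref| on the **mid-thickness report line** (all axial
positions, all times). A full-grid pointwise norm is *not* used
deliberately: at the clamped-end corners the continuum stress field is
singular, so a max norm evaluated at nodes approaching the corners grows
under refinement regardless of solver quality (measured: hoop-stress
discrepancy 3.8 % → 29 % as the FD grid refines), whereas the mid-thickness
norm converges (0.15 % → 0.05 %). Mid-thickness is also where the model's
outputs are conventionally reported.

The benchmark cylinder length (2.0 m, length-to-thickness 10) is a package
choice: the benchmark tables prescribe only radii and material laws.

## Grid defaults

- Validation scenario: DQM 13×21, FD 41×161 (slender geometry; errors
  u_r 0.057 %, σ_θθ 0.056 %, σ_zz 0.77 %).
- Aorta scenario: DQM 13×21, FD 121×81. The steep n = 0.2 grading and the
  short clamped segment need a finer FD radial grid and enough axial nodes
  to resolve the end boundary layers; the choices are convergence-tested
  (static mid-thickness values change by < 0.3 % under further refinement,
  and neighboring grid pairs give cross-method discrepancies of 1.7–2.4 %
  for hoop stress vs time and 3.0–4.8 % for displacement vs length).

## Nondimensionalization

T = t/t_e, Z = z/L, R = r/r_i, U_r = u_r·K/(P0·h) with the fixed stress
scale K = 10 GPa, and S_i = σ_i/P0. `nondim`/`redim` round-trip to
round-off.

## Limitations

- Small-strain, linear kinematics; no wall viscoelasticity or anisotropy.
- The lumen model is quasi-one-dimensional (Poiseuille gradient + thin-wall
  or structural radius); no axial fluid momentum or wave propagation.
- The layered natural wall's constituent moduli shipped as CLI defaults are
  explicitly flagged placeholders and must be supplied by the user for
  quantitative work.
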