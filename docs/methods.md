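# Methods

## Model

Cancellous (spongy) bone is treated as a two-phase periodic composite.
Cortical bone forms a lattice of struts, idealized in the representative
volume element (RVE) as three orthogonal square rods of cross-section
`b × b` crossing at the center of a cube of edge `2a + b`; the pore space is
bone marrow.  The lengths parameters `(a, b)` control the cortical volume
fraction

    rho_b = (6 a b^2 + b^3) / (2a + b)^3 ,

which the package sweeps from 29.5 % (healthy, a = 0.32 mm, b = 0.36 mm)
down to 5.3 % (late-stage osteoporosis, a = 0.43 mm, b = 0.14 mm), always at
a total RVE volume of 1 mm³.

Each material point carries seven unknowns: the displacement `u`, the
electric scalar potential `φ` and the magnetic vector potential `A`, with
state variables

    ε = sym ∇u ,   E = −∇φ − Ȧ ,   B = ∇×A ,

so Faraday's law and the magnetic Gauss law hold identically.  The phase
behavior is:

* **Cortical bone** — linear elastic (E = 22 GPa, ν = 0.32), piezoelectric
  with the shear-mode pattern `e15 = 3·10⁻³ As/m²` (collagen fibers along
  z), electrically insulating:
  `σ = C ε − eᵀ E`, `D = e ε + ξ E`, `H = μ⁻¹ B`, `J = 0`.
* **Bone marrow** — viscoelastic (E = 2 GPa, ν = 0.3) with a
  volume-preserving inelastic strain `ε_i` obeying `ε̇_i = μ_v dev σ`,
  conducting with `κ₁ = 10⁴ S/m`: `σ = C (ε − ε_i)`, `D = ξ E`,
  `H = μ⁻¹ B`, `J = κ E`.

Both phases share vacuum permittivity and permeability.  A divergence
penalty `γ/2 (∇·A)²` with `γ = 1` fixes the gauge of `A`.

## Discretization

Trilinear 8-node hexahedra interpolate all seven fields (equal order); all
element blocks use 2×2×2 Gauss quadrature, exact for the trilinear bilinear
forms on parallelepipeds.  The semi-discrete system is

    M d̈ + C ḋ + K d = F

where M holds only the A–A permittivity mass, C the conduction and
piezo/permittivity rate couplings, and K the stiffness, piezoelectric,
permittivity (negative-definite), curl–curl and gauge blocks.  Constraints
(Dirichlet sets and periodic ties) are eliminated through a sparse
prolongation `d = T d_free + g(t)`; the inhomogeneity `g` carries the affine
macro fields or prescribed boundary motion and is advanced with the same
time-integration recurrences as the unknowns, so prescribed values and their
rates are scheme-consistent.

The inelastic strain lives at quadrature points, advances once per accepted
step by explicit Euler using the end-of-step trial stress, and enters the
residual through the frozen internal force; the mechanical block of K uses
the matching consistent tangent `C − C (Δt μ_v D_dev C)`.  Because `μ_v` is
tied to `0.5·Δt` (in s/GPa, converted to a rate coefficient in 1/(Pa·s)),
the viscous correction is of relative order 10⁻⁶ here.  Stationary solves
(effective tangents, Hill–Mandel checks) drop the viscous correction — they
are instantaneous elastic responses — so stiffness and flux evaluation stay
mutually consistent.

## Time integration

A generalized-alpha scheme for the first/second-order coupled system with a
single spectral-radius parameter `ρ∞ = 0.5`:

    α_m = (3 − ρ∞) / (2 (1 + ρ∞)) ,  α_f = 1/(1 + ρ∞) ,
    γ_a = 1/2 + α_m − α_f ,

residual evaluated at `(d_{n+α_f}, v_{n+α_f}, v̇_{n+α_m})` and iteration
matrix `S = α_m²/(α_f γ_a² Δt²) M + α_m/(γ_a Δt) C + α_f K`.  The problem is
linear in `d` for frozen internal state, so Newton converges in one
iteration per step; `S` is factorized once per run (SuperLU after symmetric
diagonal equilibration, plus one refinement pass — the operator blocks span
roughly twenty decades between stiffness and permittivity entries, which
otherwise limits the attainable accuracy).

Newton convergence is judged block-wise: the residual norms of the u, φ and
A rows are measured separately, each against the largest first-iteration
residual of that block seen in the run, with an additional roundoff floor
computed from absolute-value operator products (a residual below ~10³ times
machine epsilon of the magnitudes that compose it is numerically zero).  A
single mixed-unit norm would let the mechanical rows mask the electric ones
entirely.

## Scale transition

Periodic boundary conditions: micro states split additively into affine
macro parts and periodic fluctuations,

    u = ε̄·y + ũ ,  φ = −Ē·y + φ̃ ,  A = ½(B̄×y) + Ã ,

with all degrees of freedom fixed at the eight corner nodes and opposite
faces linked (edge chains resolved to a single ultimate master).  The
symmetric-gauge affine vector potential reproduces `B̄` exactly under
trilinear interpolation and is divergence-free, so it does not load the
gauge penalty.  Averaged fluxes `(σ̄, D̄, Ḋ̄, H̄, J̄)` are volume-weighted
quadrature sums; `Ḋ̄` comes from the scheme's rate fields, not from
differencing across steps.  The five effective tangents follow from forward
differences of the averaged fluxes under unit-entry perturbations
(increment 10⁻⁸) about the zero state, computed once and cached — all
twelve stationary solves share one factorization.  The effective Young's
modulus is recovered isotropically,
`E_eff = C̄₄₄ (3 C̄₁₂ + 2 C̄₄₄)/(C̄₁₂ + C̄₄₄)`.

The Hill–Mandel (macrohomogeneity) check compares the macro products
`σ̄·ε̄`, `D̄·Ē`, `B̄·H̄` with the volume averages of the corresponding
micro products of a converged stationary solve, using the actual fields as
the admissible variation and normalizing by the cancellation-free magnitude
of the micro products; each work line is probed under its canonical load.

## Macroscale driver and the conduction closure

The benchmark body is a 30 cm × 3 cm cylinder meshed with an all-hexahedral
butterfly (O-grid) pattern, both end faces mechanically fixed, an inner disc
(r < 0.75 cm) of the left face grounded (φ = 0, A = 0), and a central axial
band (10 % of the length, configurable) driven by
`u_x = u_max a(t)`, `u_max = 2 µm`.  The amplitude is the smoothstep
`a = 3s² − 2s³` (s = step/n_steps): monotone 0→1, maximal rate at mid-run,
zero rate at both ends.  The default run mode uses the cached effective
tangents as a linear constitutive law at every integration point; a nested
mode that solves one transient RVE per macro integration point is retained
for verification (end-of-step macro states are sent down and the returned
fluxes blended to the generalized midpoint with weight α_f).

**Conduction closure.**  The scalar-potential equation of this model is a
pure Gauss law; it contains no charge-relaxation term.  Taken literally at
the macroscale, the sustained piezoelectric field Ē ∝ a(t) (order 10² V/m
here) would drive a persistent conduction current κ̄Ē that exceeds the
displacement current by about eleven orders of magnitude, producing a
magnetic field that grows with the loading amplitude and saturates at the
end of the run.  Physically, free charge in a conductor with
ξ/κ ≈ 10⁻¹⁵ s relaxes instantaneously: no static field can persist in the
conducting marrow, and at these parameters the conduction contribution to
the macroscopic magnetic field is negligible — which is also the behavior
the effective model is meant to reproduce (the magnetic field peaks when
the loading *rate* peaks and nearly vanishes once loading stops, and
the electric current only becomes visible when κ₁ is raised a hundredfold).
The macroscale driver therefore evaluates the conduction term with the
induced part of the electric field only, `J = κ(−Ȧ)`: the K_Aφ conduction
block is dropped from the macro operator while the C_AA damping block is
kept.  The microscale problem is untouched: its conduction acts on the full
E, its effective conductivity tangent κ̄ is well-defined and nonzero, and
all microscale results use the unmodified equations.

Because of this closure, cached-tangent and nested modes coincide exactly
only for non-conducting material sets; their agreement is verified in that
regime (κ₁ = 0, μ_v = 0), where the nested computation on a homogeneous RVE
is a single-scale solution in disguise.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| a, b | 0.32, 0.36 | mm | RVE lengths parameters (healthy bone) |
| elements_per_segment | 2 | – | 2 → 6³ coarse mesh, 4 → 12³ fine mesh |
| E (bone, marrow) | 22, 2 | GPa | Young's moduli |
| ν (bone, marrow) | 0.32, 0.30 | – | Poisson ratios |
| ξ₁ | 8.85·10⁻¹² | F/m | permittivity (both phases) |
| μ_c | 1.257·10⁻⁶ | H/m | permeability (both phases) |
| e15 | 3·10⁻³ | As/m² | bone piezoelectric coefficient |
| κ₁ | 10⁴ | S/m | marrow conductivity |
| μ_v | 0.5·Δt | s/GPa | marrow viscosity (tied to the time step) |
| ρ∞ | 0.5 | – | spectral radius of the time integrator |
| Δt | 10⁻³ / 10⁻² | s | micro / macro time increment |
| tol_N | 10⁻⁸ | – | Newton tolerance (block-relative) |
| γ | 1.0 | s²A²/(kg·m) | gauge penalty |
| u_max | 2·10⁻⁶ | m | peak macro displacement |
| Δ_tol | 10⁻⁸ | – | tangent perturbation increment |

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the coarse 6³ RVE (216
elements, 343 nodes, 2401 DOFs) for homogenization and 100-step transients;
mesh-independence comparisons use the fine 12³ RVE (1728 elements, 15 379
DOFs) over 5 steps; macroscale trend runs use a reduced O-grid cylinder of
120 hexahedra over 20 steps with cached tangents.  These sizes are the
package's reference configurations; all are configurable.

## Known limitations

* The idealized three-rod RVE has sharp phase corners; averaged
  piezo-driven quantities (D̄, H̄) converge slowly under refinement
  (the coarse/fine gap in |D̄| is ≈ 7 %, while σ̄ agrees to ≈ 3.5 %), and
  pointwise magnetic fields grow with refinement near corners.  The coarse
  6³ mesh is the reference configuration.
* The anisotropic (elongated cuboid) RVE variant and tetrahedral RVE meshes
  are not implemented; image-derived microstructures are out of scope.
* The macroscale conduction closure above is a deliberate modeling choice;
  runs that need the literal Gauss-law coupling at the macroscale can
  construct the macro system with `conduction="full"`.
* No structural inertia term: mechanics is quasi-static; the only mass is
  the permittivity A–A block.
* User-supplied macro meshes are read in legacy ASCII VTK only, and the
  user must supply boundary node sets programmatically.
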