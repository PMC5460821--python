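# Methods

`ifpi` implements time-harmonic poroelastic magnetic resonance elastography
(MRE) with interstitial fluid pressure imaging: a coupled Biot
displacement–pressure finite-element forward solver, a reduced pressure
solve driven by displacement data, estimation of the unknown Neumann
pressure boundary data from full-volume displacements, and a subzone
nonlinear inversion for the material parameter maps.  This note records the
model, the numerical choices, and what the synthetic experiments do and do
not demonstrate.

## Governing model

The solid displacement **u** and pore pressure *p* at angular frequency ω
satisfy, on the domain Ω,

    ∇·(μ∇u) + ∇((λ+μ)∇·u) − (1−β)∇p = −ω²(ρ − βρ_f) u
    iω ∇·u = ∇·q,      q = iωβ u + (iβ/(ρ_f ω)) ∇p

with μ the shear modulus, λ Lamé's first parameter, ρ and ρ_f the bulk and
pore-fluid densities, and the complex coupling coefficient

    β = ω φ² ρ_f κ / (iφ² + ωκ(ρ_a + φρ_f)),

where κ is the hydraulic conductivity (m³·s/kg), φ the porosity and ρ_a the
apparent mass density.  The flux definition and the compact mass-balance
form are kept exactly consistent (the sign pairing is verified by a
discrete global flux-balance identity that holds to roundoff on every
converged solution); published statements of this system differ among
themselves by an overall sign on the displacement source of the pressure
equation, and we fix the convention by that internal-consistency test.
Boundary conditions are type I (Dirichlet) or type II (Neumann) for each
field: prescribed displacement u₀ / traction f₀, and prescribed pressure
p₀ / normal flux r₀ = n·q.

At 1 Hz with κ ≈ 1e−7 m³s/kg the medium is effectively undrained: the
mass-balance equation suppresses ∇·u by roughly two orders of magnitude
below the unconstrained elastic estimate, the phantom responds nearly
incompressibly (lateral bulging), and the pore pressure acts as the
associated constraint field with boundary layers of width
δ = √(|β|(λ+2μ)/(ρ_f ω²)) ≈ 1.3 cm.  These scales drive every numerical
difficulty discussed below.

## Discretization

Structured meshes of 8-node trilinear hexahedra on the cube, 2×2×2 Gauss
quadrature (exact for trilinear coefficient products), with material
parameters carried nodally and interpolated with the same basis.  The
coupled solve has 4 complex unknowns per node; type-I values are imposed by
row/column elimination so prescribed entries are exact.  Because
displacement rows (∼μh) and pressure rows (∼|β|h/(ρ_f ω)) differ by ~11
orders of magnitude, systems are diagonally equilibrated before the sparse
LU; large structured systems additionally use a recursive-bisection
(nested-dissection) node ordering, which cuts the 21³ coupled factorization
from minutes to seconds within ~1 GB.

Default mesh: 21 nodes per axis (3 mm spacing) for forward/derivative
studies; the mesh is a configuration parameter.

## Synthetic phantom

6 cm cube; 3×2×2 cm inclusion centred at (3, 3, 4.8) cm, assigned by
node-center containment.  Matrix (μ, λ, κ) = (3000 Pa, 4500 Pa, 1e−7);
inclusion (6000, 9000, 1e−7) in the two-parameter configuration and
(6000, 9000, 1e−5) in the three-parameter one.  Top face clamped, bottom
face driven axially by 1e−4 m, side faces traction-free; p = 0 on the whole
boundary for data generation, and a single corner anchor p(0,0,0) = 0 for
the reconstruction mode.  Unstated constants: ρ = ρ_f = 1000 kg/m³,
ρ_a = 150 kg/m³, φ = 0.2 (soft-tissue extracellular-fluid fraction), and
the 1 Hz drive is read as cyclic frequency (ω = 2π rad/s; a literal
rad/s switch exists but produces pressure magnitudes inconsistent with the
reference description).  Computed displacements (±2.7e−5 m in-plane,
pressures of a few Pa) match the documented scales, and the coupled solver
is validated to ≤1–2 % against an independent fine-grid 1-D finite
difference solution of the laterally constrained column.

Noise: independent zero-mean Gaussian samples added to each of the six real
scalar components at every node, with σ = (percent/100) × RMS over nodes of
the displacement-vector magnitude.  Note the RMS is dominated by the large
axial drive component, so a given percentage is relatively harsher on the
smaller transverse components than a per-component definition would be.
The optional 3×3×3 boxcar (`spatial_average`) implements the
spatially-averaged data variant.

## Pressure from displacement data

Given displacement data and a property estimate, the reduced (one unknown
per node) pressure system is K_p p = b with
K_p(k,j) = (i/(ρ_f ω))⟨∇φ_k, β∇φ_j⟩.  The unknown boundary-flux loads
∮ r₀φ_k dΓ_q are estimated by substituting the momentum equation into the
flux definition, which requires second spatial derivatives of the data;
these come from global least-squares polynomials of total degree 10 (one
model per real scalar component, coordinates scaled to [−1,1]³, columns
norm-scaled; the design matrix condition number is ~5e3, well within double
precision).  Derivatives are analytic in coefficient space.

Three numerical choices matter here and are deliberate:

1. **Endpoint pull.**  Least-squares polynomial second derivatives are
   unreliable on the hull of the fitted domain (endpoint oscillation,
   aggravated by the weak edge singularities of the clamped/traction-free
   cube).  Evaluation points within one element of the hull are pulled
   one element inward.
2. **Substituted right-hand side.**  The estimated loads are substituted
   into the load vector, making every term a volume integral against
   test-function gradients.  This form is exactly compatible for the
   point-anchored Neumann-like solve (Σ_k ∇φ_k = 0) — otherwise the global
   defect of estimated loads acts as a spurious point source at the anchor
   — and involves only the smoothed polynomial fields, never raw nodal
   noise.
3. **Data-anchored scale calibration.**  The substituted right-hand side
   scales linearly with the current μ, λ estimate, which would couple any
   overall property bias into the pressure and feed back through the
   inversion.  A single complex factor is therefore fitted against the
   data-driven mass-balance rows (whose coefficients contain only the
   known β), tested on the low sine modes of the box.  This removes the
   property-scale feedback; at a deliberately biased property estimate the
   factor comes out at the inverse of the bias, as designed.

Accuracy: the load formula itself is verified to <1 % against the exact
discrete flux loads of a manufactured smooth solution, and the full
pipeline reproduces the coupled pressure to machine precision when fed
exact discrete loads.  On the actual phantom, however, the polynomial's
boundary-region second derivatives carry O(1) errors (the real,
elastically-dominated components are worst), and the reconstructed
pressure field retains a normalized RMS error of roughly 0.7–1.9 at the
meshes studied (21³ and below) rather than the ~0.2 of the reference
experiments.  We did not find a configuration of the stated machinery
(degrees 4–12, global or windowed fits, facet- or volume-assembled loads,
either sign convention, either ω reading) that closes that gap; the
limitation and its evidence are recorded in the repository notes.

## Subzone inversion

The domain is tiled by overlapping box subzones (default edge 2 cm,
overlap 20 %; the scaled-down runs use 3 cm zones with 1/3 overlap on
coarse meshes so each zone stays overdetermined).  Each zone solves the
coupled system with full type-I data on its surface — measured
displacements and pressures transferred from the global reduced solve —
and minimizes the zone displacement misfit Π_z = ½∫|u_c−u_m|² over nodal
μ, λ (and log₁₀κ in three-parameter mode, with bounds μ, λ ∈ [10², 10⁶] Pa
and log₁₀κ ∈ [−10, −3] enforced by projection).

The per-zone optimizer is damped Gauss-Newton: the LM-damped normal
equations are solved by matrix-free conjugate gradient in which every
Hessian-vector product reuses the factorized zone operator (the assembled
operator is affine in the nodal coefficient fields, so directional
derivatives are exact and cheap), and steps are accepted only if the zone
misfit decreases.  Plain nodal nonlinear CG was tried first and found to
be non-convergent for this problem — it monotonically decreases the misfit
while pumping energy into near-null oscillatory (checkerboard) property
modes, a behaviour reproducible even with noiseless data and oracle
pressure boundary values.  The LM damping suppresses those modes within a
zone; a 3×3×3 boxcar applied to the assembled property maps between global
passes re-damps what still accumulates (this is also why reconstructed
interfaces are smoothed over about one mesh spacing).  Two further
stabilizers matter in practice: the damping is applied per parameter
block (μ, λ, log₁₀κ each damped relative to its own curvature scale, so
the stiff μ block does not freeze out the weakly-sensed κ directions),
and the total change per zone visit is trust-capped (±30 % on μ, λ and
half a decade on log₁₀κ), which bounds what noisy data or a biased
pressure field can do in any single pass.  Zone updates are averaged over
overlapping zones; processing order is shuffled with a fixed seed but
results are order-independent by construction.

Outer loop per global pass: estimate the boundary loads from the
polynomial model and current properties → solve the global reduced
pressure problem → transfer boundary values to the zones → update
properties.  Convergence is declared when the relative RMS change of μ per
pass falls below 1e−3; a divergence guard stops the loop if the summed
zone objective grows by more than 50 %.  Initial estimate: homogeneous
μ = 4000 Pa, λ = 6000 Pa (middle of the tissue-like range) and, in
three-parameter mode, κ = 1e−6 m³s/kg.

A consequence of the imperfect estimated pressure is worth stating
plainly: the property updates co-adapt to the biased pressure boundary
data, so the μ error typically reaches its minimum within the first few
global passes and then degrades slowly.  The reproduction protocol
therefore runs a small fixed number of passes (three at 13³) rather than
iterating to the χ-change tolerance; with oracle pressure boundary values
the same loop converges monotonically (μ error 0.33 → 0.15 noiseless),
which isolates the pressure estimate as the accuracy bottleneck.

## Error metrics and reproduction scales

Reported errors are normalized RMS over nodes,
Δf = ‖f_true − f_est‖/‖f_true‖, with complex magnitude for the pressure
and linear (not log) κ.  The reproduction runs are scaled down to fit the
available compute: forward/derivative studies at 21³ (the resolution
implied by the reference's 3 mm interface smoothing), inversion cells at
13³ with degree-8 polynomials (keeping roughly the same nodes-per-
coefficient ratio as degree 10 at 21³), three global passes, two
Gauss-Newton steps per zone visit.  Problem sizes are recorded with every
reported number.

What the synthetic experiments show: the forward model is correct to
discretization accuracy (oracle-verified assembly, flux balance, 1-D
column agreement, patch and convergence tests); the reduced pressure solve
is exactly consistent with the coupled one given exact loads; the
derivative estimation reproduces the documented interior second-derivative
scale (peak |∇·∇u| ≈ 0.19 on the y = 4.2 cm slice, against the ~0.1
order-of-magnitude estimate); and the inversion machinery descends
correctly (finite-difference-verified adjoint gradients, monotone accepted
steps).  What they do not show: recovery of the reference's absolute error
levels for the reconstructed fields, which our implementation of the
boundary-load estimation does not reach (see above); accordingly the
reconstruction-error tables produced here are systematically worse than
the reference ones, with the same qualitative ordering (errors grow with
noise; κ degrades faster than μ).  None of the synthetic data includes
MRI acquisition physics, and the Gaussian noise model is a simplification
of measurement error.
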