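# Methods

`axonrve` models the tensile micromechanics of central-nervous-system (CNS)
white matter as a fiber composite: undulated axons embedded in an
extracellular matrix (ECM), with a strain-dependent rule for how much of
each axon is kinematically coupled to the matrix. This note records the
model, its numerical realization, the defaults and why they were chosen,
and what the synthetic benchmarks do and do not demonstrate.

## Geometry: the pseudo-3D RVE

The representative volume element is a thin cuboid, by default
0.4 × 10 × 5.68 µm — one axon diameter thick in x, so the microstructure is
effectively planar while the mechanics remain 3D. Each axon is generated
from random waypoints at uniform z spacing, smoothed by a cubic spline
parameterized by z, re-sampled to uniform arc length, and clipped to the
box by projecting out-of-bounds coordinates onto the faces (projection onto
a convex box is 1-Lipschitz, so clipping can only reduce tortuosity when
the endpoints are interior). The transverse waypoint amplitude is scaled by
bisection until the realized tortuosity — arc length over end-to-end chord —
matches a target drawn from a truncated normal distribution
(mean 1.13, sd 0.06, support [1.02, 1.30]). Those distribution parameters
are a modeling choice: the experimental undulation histogram the study
conditions refer to is not published numerically, and this choice puts the
population mean inside the reported 1.05–1.25 range.

Axons (nominal diameter 0.4 µm) are appended until the summed swept-circle
volume π r² L reaches the 53% target fraction. Overlap between fibers is
ignored, consistent with the embedded-element premise that fiber volume is
not removed from the matrix. Because a single whole axon changes the
fraction by ~3.5 percentage points, sequential stopping alone cannot land
within the ±1-point tolerance; the generator therefore trims the radius of
the one closing axon so the achieved fraction equals the target exactly.
All preceding axons keep the nominal diameter. The axon count is emergent
(≈ 16 at default settings), not forced: the published figure of 33 axons is
not reconcilable with the printed box, diameter and fraction by swept-volume
arithmetic, so the generator targets the fraction.

Randomness is hierarchical: axon *i* draws from
`SeedSequence(seed, spawn_key=(i,))`, so a given axon is identical no matter
how many follow it, and a fixed seed reproduces the RVE bitwise.

## Transitional kinematic model (TKM)

Experiments on optic nerve and embryonic spinal cord show axons deform
non-affinely at low stretch and progressively couple to the glial matrix as
they straighten. The rule implemented: an axon whose **current** undulation
is ≥ 1.08 does not interact with the matrix (its two end nodes are always
tied at the RVE surfaces); an axon strictly below the threshold has 8%,
20%, or 44% of its 50 equal-arc sub-segments coupled when the applied
stretch is at most 1.06, 1.12, or 1.25. The rule is re-evaluated before
each loading stage from the deformed fiber geometry, and coupled sets only
grow — a segment never uncouples. Which segments couple first is not
specified by the rule; the default policy couples the locally straightest
sub-segments first (straight portions reach affine kinematics first),
with `random` and `from-ends` policies available.

## Constitutive model

Both phases are one-term Ogden solids,
W = (2µ/α²)(λ₁^α + λ₂^α + λ₃^α − 3), with a shared exponent α = 8.22 and
the axon modulus three times the ECM's. The FE solver uses the decoupled
nearly incompressible form — isochoric stretches in W plus a volumetric
penalty (κ/2)(J−1)² with κ = 100 µ (≈ Poisson 0.495). The closed-form
uniaxial nominal stress S(λ) = (2µ/α)(λ^{α−1} − λ^{−α/2−1}) assumes exact
incompressibility; at κ = 100 µ the finite-element uniaxial response sits
about 0.4% (λ = 1.06) to 1.4% (λ = 1.25) below it, which is the dominant
term in the 2% patch-consistency budget.

Stress is evaluated spectrally from the right Cauchy–Green tensor; the
material tangent dS/dC is computed by central finite differences along the
six symmetric modes of C with a tr(C)-scaled step, giving ~10⁻⁹ relative
accuracy — exact enough for quadratic Newton behavior while avoiding the
repeated-eigenvalue case analysis of the analytic Ogden tangent.

## Finite-element realization

- **Matrix**: structured 8-node hexahedra (2×2×2 Gauss), total-Lagrangian,
  assembled vectorized over elements. Default element size 0.4 µm; the
  identification studies use 0.5 µm (see problem sizes below).
- **Axons**: each is a chain of 50 two-node nonlinear truss segments over
  its sub-segment boundaries. A segment at stretch λ_f carries axial force
  S(λ_f)·π r² referenced to its rest length — the fiber is slack-capable
  (S < 0 in compression is retained; chains wrinkle instead of supporting
  transverse load).
- **Coupling**: penalty springs between a fiber node and the matrix
  displacement interpolated trilinearly at the node's anchor point;
  k_high = 10³ µ_ecm·h for coupled and end nodes, k_low = 10⁻³ µ_ecm·h as
  regularization for otherwise transversely floating nodes (h = element
  size). Halving k_low changes the homogenized stress by far less than
  0.5%.
- **Anchoring** (a genuinely open design point): nodes coupled from the
  start are anchored at their reference locations. A node that couples
  *mid-protocol* is re-anchored at the matrix material point currently
  coincident with it, found by fixed-point iteration of X = x_f − u_m(X).
  The alternative — keeping the reference anchor — drags a fiber that has
  already straightened non-affinely back toward the affinely convected
  image of its undulated reference shape; tortuosity then *increases* at
  stage switches, contradicting the observed monotone straightening, and
  the stress response overshoots. The reference variant remains available
  (`RVEModel(anchor_mode="reference")`) for comparison.
- **Loading**: U_z = 0 on the Z = 0 face, prescribed U_z on the opposite
  face (stages 1.06 / 1.12 / 1.25, 6 equal substeps each), lateral faces
  traction-free, in-plane rigid modes pinned at two corner nodes of the
  bottom face.
- **Solver**: full Newton with a consistent tangent (sparse LU,
  minimum-degree ordering), residual tolerance 10⁻⁸ relative / 10⁻¹⁰
  absolute, 25 iterations max, an inversion-guarded backtracking line
  search, and a per-step displacement cap of half the smallest element
  edge. Failed increments are bisected (up to 4 levels). Two measures keep
  the floppy fiber chains from destabilizing Newton: (1) before and after
  every global step, each chain's *soft* nodes are equilibrated by a small
  dense damped-Newton solve with the matrix field frozen; (2) when a
  coupling update stiffens ties mid-protocol, the switch is applied as a
  continuation in the tie stiffness at constant stretch. Neither changes
  the converged equilibria.
- **Outputs**: homogenized nominal stress S33 = Σ(top-face z-reactions) /
  (reference cross-section, 4 µm²), cross-checked against the volume
  average of the first Piola–Kirchhoff P₃₃ including the fiber term; the
  von Mises invariant of element-averaged Cauchy stress; per-axon
  tortuosity at λ ∈ {1.0, 1.06, 1.12, 1.25}.

Because every stiffness in the model (ECM and axon moduli, bulk penalty,
tie stiffnesses) scales linearly with the axon modulus at the fixed 3:1
ratio, the displacement solution is independent of µ and the homogenized
curve is exactly linear in µ. This is a property of the model family, not
an approximation; the inverse loop still runs one full forward simulation
per objective evaluation.

## Inverse identification

The objective E(µ) = Σᵢ (S_target(λᵢ) − S_sim(λᵢ; µ))² is evaluated at
m = 20 equidistant stretch points on (1, 1.25] (the right endpoints of the
sampled intervals; λ = 1 is excluded since both curves vanish there), with
linear interpolation between curve samples. Minimization is textbook
golden-section on the (20, 50) kPa bracket: interior points at
a + (1−1/φ)(b−a) and a + (1/φ)(b−a), the lower evaluated first, one new
evaluation per iteration, termination when the bracket width drops below
1.0 kPa — which fixes the first evaluated point at 31.46 kPa and the
evaluation count at nine, independent of the objective. Evaluations are
memoized on µ (10⁻⁶ kPa granularity). The RVE, mesh, coupling rule and
load program are frozen across all evaluations of one identification.

Because the experimental tension curve is not available as a table, the
benchmark target is synthesized from the incompressible uniaxial Ogden law
at the published tissue curve fit (µ = 32.8 kPa, α = 8.22) and tagged
`synthetic`; any user-supplied two-column CSV curve is accepted in its
place.

## Problem sizes

Default analyses use a 0.5 µm element mesh (220 hexahedra, ≈ 500 matrix
nodes) with ≈ 16 axons × 51 fiber nodes, ≈ 4 000 degrees of freedom; one
staged simulation takes tens of seconds on a single CPU and a full
nine-evaluation identification a few minutes. The homogeneous-matrix
consistency check uses a 0.25 µm mesh (1 840 elements). Self-consistency
recovery studies use a 0.7 µm mesh; recovery is exact-by-construction with
respect to the mesh, since target and forward model share it.

## What the synthetic benchmarks show — and a known headline gap

Self-consistent recovery (target generated by the forward model itself)
validates the inverse loop: the modulus is recovered within the 1.0 kPa
search tolerance for every seed tried. The golden-section anchors and the
coupling-rule table are exact.

The headline benchmark — identifying µ against the *synthetic* Ogden
(32.8 kPa, 8.22) curve — does **not** reproduce the published 33.28 kPa;
the search saturates near the upper bracket end (≈ 50 kPa). This is an
arithmetic property of the printed study conditions, not a solver artifact:
with a 53% fiber fraction at a 3:1 stiffness ratio, even *perfect* affine
coupling of every fiber yields an effective modulus of
µ_eff = µ_ax(1/3 + 0.53) = 0.863 µ_ax, so matching a target of amplitude
32.8 kPa requires µ_ax ≈ 38 kPa at minimum; with the transitional rule
capping coupling at 44% of each axon's length the model is necessarily
softer still (µ_ax ≈ 55–65 unconstrained, clipped by the bracket). The
original study optimized against the raw experimental curve, which its own
simulated curves matched with sub-kPa residuals; that raw curve is
evidently softer at high stretch than its one-term Ogden fit, and the fit
is the only form available for synthesis. The self-consistency tests and
all structural anchors are unaffected. Related published inconsistencies
(33 axons at 53% volume fraction in this box are geometrically impossible)
point to the same accounting gap.

## Known limitations

- Full-integration trilinear hexahedra with κ = 100 µ can lock volumetrically
  in strongly heterogeneous fields; the homogeneous patch test is exact, but
  local von Mises fields near fibers are stiffness-biased at coarse meshes.
- Fibers are 1D truss chains, not swept solids: bending stiffness and
  fiber–fiber contact are absent, and the fiber "area" acting on a
  cross-section is Σπr² (≈ 47% here) rather than the 53% solid-volume
  fraction.
- Coupling updates are discrete (per stage), matching the staged protocol;
  continuous evolution of the coupled fraction within a stage is out of
  scope.
- The truncated-normal undulation distribution emulates only the reported
  population range, not the shape of the unpublished experimental
  histogram, so population-level conclusions transfer to real tissue only
  at the level of means and trends.
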