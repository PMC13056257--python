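# Methods

`semcell` simulates a single adherent cell as an ensemble of coarse-grained
particles of four kinds: cytoplasm (type 1), nucleus (type 2), a planar
lattice of static adhesive ECM particles (type 3) and inert glass particles
(type 4).  This note records the model, the parameter derivations, the
numerical choices, and the design decisions taken where the problem was
genuinely open — in enough detail that every number the package produces
can be traced to a formula or an explicit choice.

## Model and units

All quantities live in a µm / s / zJ unit system (1 N/m = 1e9 zJ/µm²,
1 N·s/m = 1e9 zJ·s/µm²); cell-level inputs in SI units are converted on
entry.  Each mobile particle obeys the overdamped Langevin equation

    η ẏᵢ = F(yᵢ) + ξᵢ ,

integrated with Euler–Maruyama,

    y ← y + (Δt/η) F + √(2 kT_eff Δt / η) 𝒩(0,1)   per coordinate.

There is no inertia; the per-particle mass is bookkeeping only.

### Pair potentials

Cytoplasm and nucleus particles interact through a Morse-like potential in
the squared-distance exponent form

    V(d) = u₀ exp(2ρ(1 − d²/d_eq²)) − α u₀ exp(ρ(1 − d²/d_eq²)) ,

with ρ = α = 2, truncated at 2.5 d_eq.  With α = 2 the minimum sits at
d = d_eq with depth −u₀.  By default the energy is shifted so V(cutoff) = 0
(the force is untouched; the discontinuity it leaves in the force at
2.5 d_eq is ~1e-4 of the well curvature and irrelevant to the dynamics — a
flag disables the shift).

Cytoplasm–ECM adhesion is a Lennard-Jones 12–6 potential
V(d) = 4ε[(σ/d)¹² − (σ/d)⁶] truncated at d_c (σ = 5 µm, ε = 6e4 zJ,
d_c = 15 µm by default); cytoplasm–glass uses the same form truncated at
its zero crossing (pure volume exclusion).  Nucleus–ECM is absent by
default; an optional generalized m–n (Mie) coupling
V(d) = C ε[(σ/d)ᵐ − (σ/d)ⁿ] with C = (m/(m−n))(m/n)^(n/(m−n)) — normalized
so the well depth is exactly −ε — provides the weak soft-core 3–2 variant.

Rigid indenters (the spherical tip and the constriction pillars) exert a
quadratic penalty: particles at distance r < R from the center (sphere) or
axis (cylinder) are pushed radially outward with magnitude K (r − R)²,
zero for r ≥ R, no adhesion.  The default K = 1e3 u₀/d_eq³ is effectively
rigid (sub-0.01 d_eq interpenetration at the loads that occur); a particle
exactly at the center is pushed along +z (sphere) or in-plane +x
(cylinder).

### Parameters from cell-level rheology

Treating the cell as N_p close-packed particles connected by springs:

    d_eq  = 2 R_cell (p_d / N_p)^{1/3}
    κ_eff = κ₀ N_p^{-1/3} (1 − λ N_p^{-1/3})
    u₀    = κ_eff d_eq² / (8 ρ²)
    η_p   = η₀ / N_p

Reference values (R_cell = 10 µm, N_p = 1000, p_d = 0.74, κ₀ = 1.2e-2 N/m,
η₀ = 5e-2 N·s/m, λ = 0.75) give d_eq ≈ 1.809 µm, κ_eff ≈ 1.11e-3 N/m,
u₀ ≈ 1.135e5 zJ.  Three derivation choices were open and are resolved as
follows:

- **Per-particle drag is η₀/N_p** (not η₀·N_p): dividing is the only
  reading under which the summed drag of the ensemble equals the
  cell-level viscosity, matching the derivation's intent.  A
  `drag_scaling` switch exposes the alternative.
- **The nuclear stiffness κ_nuc (4.5e-2 N/m by default) passes through the
  same N_p-softening chain** before the well-depth relation, so
  u₀(2,2)/u₀(1,1) = κ_nuc/κ₀ (3.75 at the defaults).  Applying the
  well-depth formula to the raw κ_nuc would make the ratio ~40, which
  contradicts the expectation that doubling the nuclear stiffness doubles
  the nuclear well depth.
- **Nuclear per-particle drag is η_nuc/N_p** ("np", default): the drag
  derivation fixes the divisor at the cell's total particle count for
  every member of the ensemble; nuclear and cytoplasmic particles are
  equal-sized members of the same ensemble and differ only in the
  viscosity prefactor.  Distributing η_nuc over the nuclear particles
  alone ("nn" switch) would make nuclear particles ~40× draggier than
  their equal-sized cytoplasmic neighbors.

The cytoplasm–nucleus cross interaction uses u₀(1,2) = k₁₂ u₀(1,1) with
k₁₂ = 1.51 by default and d_eq(1,2) = d_eq(1,1) (equal-sized particles).

### Effective temperature

The noise amplitude is the fluctuation–dissipation form with an effective
thermal energy kT_eff, defaulting to u₀/50.  No physical temperature is
intended: kT_eff is an annealing control, small enough that bound pairs
stay bound (the escape barrier is ≫ kT_eff) and large enough to unjam the
packing during equilibration.  The anneal schedule scales it per stage.

### Timestep

The default Δt is set so the largest drift displacement is 0.02 d_eq at
initialization; a step moving any particle farther than 0.5 d_eq raises a
stability error.  Protocols that traverse stiff transients (the anneal,
indentation contact, constriction passage) use an adaptive variant that
retries with a smaller Δt when the drift overshoots the 0.02 d_eq target
and grows Δt by 5% per quiet step.  Deterministic (kT_eff = 0) integration
converges at first order in Δt, as expected for explicit Euler.

## Protocols

### Nucleus preparation (phase separation)

A cell starts as N_p particles placed uniformly in a cylinder (minimum
spacing 0.5 d_eq; rejection sampling), 10% tagged nuclear at random.  The
Morse attraction is far too short-ranged (Gaussian-like in d) to gather
nuclear particles dispersed across the cell, so the anneal combines three
ingredients:

1. a temporarily strengthened and extended nuclear self-interaction
   (u₀ × 3, cutoff × 1.5 in the gathering stages, relaxed stepwise back to
   nominal),
2. elevated noise early (kT_eff × 3) to unjam the mixed packing,
3. a centering spring on the nucleus.  During gathering this spring acts
   **per particle** toward the cytoplasmic centroid (each nuclear particle
   is pulled individually, which contracts and merges dispersed clusters);
   once the nucleus exists, the spring becomes the **rigid** form used
   during migration — every nuclear particle receives the same force
   k·(c_cell − c_nuc) — which re-centers without deforming.

The default schedule is four stages (two gathering, two relaxing,
5000/3000/1500/1500 steps); if the purity target (8% cytoplasmic particles
inside the 3-D convex hull of the nuclear particles) is missed, up to
three extra gather/relax cycles are appended, and the run ends with a
short relax at the nominal potential.  A short overlap quench precedes the
anneal.  Stage lengths were chosen so the full-resolution (N_p = 1000)
anneal completes in about a minute of wall time while leaving the purity
comfortably inside the target across seeds; the acceptance bound is the
purity, never the schedule.

### Spreading on ECM micropatterns

ECM particles sit on a square lattice (spacing configurable; σ/2 for
patterned substrates, d_eq for the full-plane indentation substrate)
clipped to a circle, square, triangle, rectangle or full plane, with an
optional margin of inert glass sites outside the shape.  The cell is
released just above the substrate and run under Brownian dynamics; CSI,
NSI, whole-cell projected area, **basal** projected area (particles within
1.5 d_eq of the lowest cell particle — the contact footprint), ellipticity
and purity are recorded per output interval.

Scaled-down runs preserve the dimensionless adhesion ratio ε/u₀ rather
than the absolute ε: u₀ grows ≈4.7× when N_p drops 1000→200, so holding
ε fixed would collapse the weak/strong spreading contrast that exists at
the reference resolution (where ε/u₀ ≈ 0.53).  Test-scale "strong"
adhesion uses that same ratio and "weak" uses 0.15.

### Indentation

The synthetic spread-cell generator places cytoplasm in a volume-conserving
pancake (radius 1.4 R_cell) with the nucleus in an oblate spheroid near the
top surface — the configuration a spreading simulation produces, built
geometrically so that calibration and testing do not pay for a long
spreading run — and relaxes it on a full-plane substrate.  Peripheral
basal particles (below one d_eq, beyond 85% of the spread radius) are
immobilized, mimicking focal adhesions.  A rigid spherical tip approaches
at 1 µm/s from one d_eq above the top particle, indents to the set depth
(default 2 µm) below the contact plane, holds, and retracts at 1 µm/s; the
vertical reaction force is sampled on a fixed time interval with the phase
label.  The resulting curve shows the three-phase response: force rising
through loading, relaxing during the hold as the packing rearranges, and
returning to baseline on unloading.

### Constricted migration

Two rigid vertical pillars (quadratic-penalty cylinders) flank a gap in
the middle of a rectangular ECM strip bordered by glass.  Migration is
driven by particle turnover: every `period` steps one cytoplasmic particle
is inserted on the substrate at the basal leading edge (a uniformly random
bulk surface site within a 60° in-plane cone about the migration
direction — anchoring on bulk particles with ≥4 neighbors prevents a
detached filament from growing out of previous insertions) and the
trailing-most cytoplasmic particle is removed, conserving the count.  The
rigid centering spring (restricted to the migration plane) drags the
nucleus with the advancing cell body.

Geometry defaults, chosen because the sources print none: pillar radius
R_cell, so the channel is longer than the nucleus (a short channel merely
pinches a waist without elongating the projected outline); gap = 0.4× the
nuclear hull-volume-equivalent diameter (+1 d_eq for particle size),
because the penalty admits ~0.4 µm of pillar penetration per side, so a
0.5× gap is not effectively sub-nuclear; and a device ceiling (quadratic
slab penalty; the floor acts on nuclear particles, which have no substrate
interaction of their own) mirroring the finite channel height of
microfluidic constriction devices — without vertical confinement the
nucleus evades the squeeze by expanding in z and the projected NSI never
drops.  With these defaults the NSI traces the characteristic sequence:
rounded before entry, minimum during passage, partial recovery after exit.
Scaled migration runs use the 20%-nucleus variant (40 nuclear particles at
N_p = 200) so the projected-hull NSI is resolved above its discreteness
noise (~±0.04 for a 20-point hull).

## Analysis

- **Shape index** 4πA/P² of the projected outline, from the 2-D convex
  hull (default) or an alpha shape for strongly tapering outlines.  The
  alpha shape keeps Delaunay triangles with circumradius ≤ α; with no α
  given, the smallest threshold yielding a single connected polygon is
  found by bisection over the sorted circumradii.
- **Ellipticity** f = (a − (b+c)/2)/a from an algebraic least-squares
  quadric fit constrained to ellipsoids, applied to the convex-hull
  vertices of the cloud so surface samples and solid blobs are treated
  alike; radii come from the eigen-decomposition of the centered quadric.
- **Purity**: percentage of cytoplasmic particles strictly inside the 3-D
  convex hull of the nuclear particles (the hull stands in for a rendered
  nuclear surface: deterministic and mesh-free).  The denominator is all
  cytoplasmic particles (literal reading); a switch provides
  inside/(inside+nuclear).
- **Per-particle virial stress** σ_ab(i) = −½ Σ_j r_ij,a F_ij,b over
  interacting pairs, in stress×volume (energy) units; the kinetic term is
  omitted (overdamped).  Compression is negative; trace/3 is the mean
  volumetric stress.  Division by the particle sphere volume (radius
  d_eq/2) converts to true stress on request.  Normalized displays clip to
  the 5th–95th percentile band mapped to [−1, 1].
- **Binned profiles**: equal-width bins over the occupied range of one
  axis; empty bins are NaN, never zero.
- **Local shear strain**: per-particle least-squares deformation gradient
  from reference→current neighbor vectors, then the von Mises shear
  invariant of the Green–Lagrangian strain (exactly zero under rigid
  rotation); particles with <3 reference neighbors are NaN.

## Calibration

The UQ surrogate is a 4th-order polynomial chaos expansion over six
independent Normal priors (σ = 0.1 µ) on κ₀, η₀, κ_nuc, η_nuc, k₁₂ and λ,
built by least-squares point collocation: the basis is the tensor
probabilists' Hermite family, orthonormalized per variable, restricted to
total degree ≤ 4 (C(10,4) = 210 terms), and the default design is 2×
oversampled (420 prior draws) — collocation rather than tensor quadrature
because a level-5 tensor grid would need 5⁶ runs.  Means, standard
deviations and first-order Sobol indices per time point follow directly
from the coefficients; outputs with (numerically) zero variance report
undefined indices rather than 0/0.

Fitting minimizes the RMSE between a simulated and a target force curve
(simulation linearly interpolated onto the target's timestamps) with
Nelder–Mead at xatol = fatol = 1e-4, the search variables normalized by
the initial guess so the tolerances act on relative changes; a runner
failure at a simplex vertex is penalized with +∞ and logged.  λ is
included in the UQ but excluded from optimization.

The calibration runner prepares one spread cell on a full-plane substrate,
relaxes it ~3000 steps to a deep minimum under the nominal parameters, and
reuses that state for every evaluation with kT_eff = 0, so equal inputs
give bit-equal outputs and the force curve varies smoothly with the
mechanical parameters instead of through rearrangement cascades.  Two
further smoothing measures matter in practice: a softer tip penalty
(50 u₀/d_eq³ instead of the rigid 1e3) spreads the contact over several
particles, and the recorded curve is lightly smoothed (3-sample rolling
mean).  Without them the force response is dominated by discrete contact
events and the RMSE landscape is too rugged for a simplex search.
Synthetic targets for closed-loop tests are generated by this same runner
at known parameters; a two-column CSV reader accepts external digitized
force curves when available, but nothing depends on one.

## What the synthetic data do and do not show

Every input is generated internally: random mixed cells, lattice
substrates, geometrically constructed spread cells, simulator-generated
force-curve targets.  These emulate the *structure* of the corresponding
experiments (a mixed cytoplasm demixing into a nucleus, an adherent
pancake with an apical nucleus, a three-phase indentation record) but none
of the biological variability: no cytoskeleton, no active forces beyond
the turnover and centering rules, no cell-to-cell parameter scatter, no
measurement noise.  Passing tests therefore demonstrate the internal
consistency and qualitative phenotypes of the mechanical model — not
agreement with any particular cell type beyond what the reference
parameter set encodes.

## Problem sizes

The default test scale is N_p = 200 (180/20, or 160/40 for migration);
the phase-separation acceptance runs the reference N_p = 1000 over three
seeds.  These sizes keep the full suite and the acceptance script in the
minutes range on one core while preserving the dimensionless ratios
(p_d, ρ, α, λ, k₁₂, ε/u₀) of the reference parameter set.

## Known limitations

- No membrane, cortex or cytoskeletal filaments: extreme nuclear
  elongations driven by actin-mediated compression are out of reach, and
  strongly flattened cells can locally expose the nucleus.
- The nucleus interacts with the substrate only through the cytoplasm
  (plus the optional weak 3–2 coupling and the migration floor penalty).
- Single cell only; no division, no cell–cell interactions.
- Euler–Maruyama is first-order; statistics requiring weak second-order
  accuracy would need a finer timestep than the defaults.
- The alpha-shape auto-α (tightest single component) can be conservative
  for very sparse outlines; pass an explicit α when comparing against
  externally digitized outlines.
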