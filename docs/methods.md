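# Methods

`frillsim` models ridge formation in the neck frill of the frilled dragon
(*Chlamydosaurus kingii*) as a frustrated-growth elastic instability, and
estimates the skin-to-substrate stiffness ratio that controls the pattern
from depth-dependent nanoindentation moduli.  This note records the model,
its assumptions, the numerical choices, and what the desk-scale defaults
do and do not establish.

## Morphoelastic model

The frill lobe is a thin skin sheet (thickness T = 47 µm, inner neck
boundary of length L with T/L = 0.014) either alone or bonded to a much
softer connective-tissue substrate.  Each tetrahedral element carries a
growth tensor

    G = Gs · Gc,
    Gs = g_s I + (1 − g_s) N Nᵀ,     Gc = I + (g_c − 1) C Cᵀ,

where N is the reference surface normal and C the crease direction:
`Gs` expands the element isotropically in the plane perpendicular to N
by g_s, and `Gc` stretches it along C by g_c.  The local factors
attenuate with depth through a generalised logistic,

    g_i = 1 + (g(i) − 1) / (1 + 0.25 · e^(−k (T − x_i))),

with x_i the distance of the element centroid to the anterior surface
(for g_s) or to the crease plane (for g_c).  The sharpness k is taken as
100 mm⁻¹ with all lengths in mm, making the growth transition at the
skin–substrate boundary ≈ 10 µm wide; the constants carry no units in the
published measurements, so this reading is a package convention (exposed as
`SolverConfig.sharpness`).

Elasticity is compressible neo-Hookean.  With the elastic deformation
gradient F = A_def (G Â)⁻¹ and J = det F,

    W = (µ/2)[tr(F Fᵀ) J^(−2/3) − 3] + (K/2)(J − 1)²,
    σ = (1/J) ∂W/∂F Fᵀ = µ J^(−5/3) dev(F Fᵀ) + K (J − 1) I,

with K = α µ and α = (2 + 2ν)/(3 − 6ν); all runs use ν = 0.45 (nearly
incompressible soft tissue) for both regions, so the skin-to-substrate
stiffness ratio E_skin/E_substrate equals µ_skin/µ_substrate.  Stresses
are normalised internally by µ_skin; only moduli ratios affect the
equilibrium shapes.

Nodal forces follow the traction formulation: the traction −σ n of each
deformed face (n = outward normal scaled by area) is shared equally by
its three vertices, which for constant-stress linear tetrahedra is
identical to the negative gradient of the total elastic energy (verified
against finite differences in the test suite).

**Volumetric averaging (mean dilatation).**  Displacement-based linear
tetrahedra lock volumetrically at ν = 0.45: with the pointwise pressure
K(J − 1) the flat-strip benchmark wrinkles at ≈ 1.7× the analytic
wavelength, i.e. an effective bending stiffness ~5× too large, and ridge
counts bias low.  The solver therefore evaluates the volumetric term at
the cluster-averaged dilatation J̄ (reference-volume-weighted mean of J
over the six tetrahedra of each lattice hex), the standard
mean-dilatation treatment; the pressure becomes K(J̄ − 1) and the
assembled forces remain the exact negative energy gradient (tested by
finite differences).  The deviatoric term stays pointwise.  With
averaging the wavelength bias drops to ~1.1× and becomes independent of
ν, confirming the pointwise bias was locking, not physics.  The
pointwise form remains available (`SolverConfig.volumetric_averaging =
False`, the default outside the fast profile).

### Growth modes

* **Single-sheet runs** (semicylindrical sheet, curved lobe, the PDMS
  analog): growth is homogeneous — every element receives the full
  tangential expansion g and there is no separate crease tensor, so the
  crease edge lengthens at the same rate as the surface.  This is the
  `GrowthTargets.uniform` mode.
* **Multi-layer runs** (bilayer frill): both factors attenuate with depth
  as above; the skin grows by g(s) ≈ 1.3, the crease region by
  g(c) ≈ 2.2, and the substrate stays near 1.
* The developmental schedule maps normalised time τ ∈ [0, 1] (smooth
  stage → three-ridge stage) to targets through a linear surface ramp
  g_s(τ) = 1 + 0.3τ and a quadratic crease ramp
  g_c(τ) = 1 + 1.65τ − 0.45τ², fixed by the three measured anchors
  (1.0, 1.0) at τ = 0, (1.1, 1.5) at τ = 1/3, (1.3, 2.2) at τ = 1.

### Boundary conditions

The inner (neck) boundary is fully fixed.  Crease nodes move only along
C in single-sheet runs; in multi-layer runs they lose the component
normal to the crease plane (mirror symmetry of the two lobes).  A seeded
surface-normal perturbation of amplitude 10⁻³ T breaks the symmetry of
the discretised problem once, before stepping; without it the flat branch
can persist beyond the instability threshold.

## Dynamic relaxation

Equilibria are found with damped second-order pseudo-dynamics

    v ← v + ((f − γ v)/m) Δt,    x ← x + v Δt,

with node mass m = a³ (a = mean node spacing).  The printed time-step
rule Δt = 0.01 a/K is dimensionally inconsistent; the package uses
Δt = dt_factor · l_min / √(K + 4µ/3), where l_min is the smallest mesh
edge (the through-thickness spacing on thin-sheet meshes), which is the
explicit-stability scaling.  The default configuration keeps the printed
dt_factor = 0.01; the `SolverConfig.fast()` profile used by the shipped
presets runs at dt_factor = 0.8 (just under the stability limit) with an
automatic restart-and-halve guard on numerical blow-up.

Damping starts at γ = γ₀ m and is halved whenever the relative energy
decrease over the convergence window stalls, floored at γ_min m.  The
fast profile uses γ₀ = 3, γ_min = 1 (per unit pseudo-time): these values
keep the slowest bending mode near critical damping at desk scale.  The
damping path matters physically: the post-buckling landscape has
near-degenerate minima with different ridge counts (energy differences
~0.2%), and very light damping lets ridges coarsen (merge) during the
long tail of relaxation, while quasi-static stepping with near-critical
damping tracks the branch selected at the instability onset — which is
what the developmental sequence being modelled does.  For this reason the
ridge-count experiments drive growth quasi-statically (typically 4–10
increments with full re-relaxation, the lobe ramp pausing at the measured
stages g = 1.05, 1.10, 1.15, 1.20, 1.28), including the "full growth"
study conditions.

Convergence requires the relative energy change over `energy_window`
iterations to drop below 0.1% *and* the largest per-step node
displacement below `disp_tol · a`.  The window (10⁵ iterations in the
original GPU-scale conditions) is scaled with the iteration budget at desk scale
(3000 iterations in the fast profile, with Δt ≈ 10× larger, so the
pseudo-time window is comparable).

A "stiffness" mass-scaling option (per-node mass proportional to incident
element stiffness) is implemented for experimentation but is **not** used
by any preset: although equilibria are mass-independent, the altered
relaxation path changes which post-buckling branch is reached, and the
uniform-mass path is the one consistent with the reference dynamics.

## Morphometrics

Ridges are counted on five sampling bands at fractions 0.2–0.8 of the
in-plane distance from the fixed boundary to the free edge.  On each band
the surface-normal displacement is sampled along the arc, smoothed over
3 node spacings, and local maxima with prominence ≥ 10% of the band's
displacement range count as ridges; a band whose displacement range is
below 0.02 T — 20× the peak-to-peak of the seeded perturbation — is
reported flat, so flat states read zero while the low-amplitude early
ridge stages (band ranges of a few hundredths of T) are still detected.  The per-lobe count is the mode over bands, ties
resolved toward the mid band.  Amplitudes are peak-to-adjacent-trough
(read from the unsmoothed profile at the smoothed-profile extrema) —
"amplitude" is not defined in the published measurements; peak-to-trough
is how a fold on a section is naturally read.  Wavelengths are successive
peak-to-peak arc distances; the SD pools the individual peak spacings
across bands.  Realized linear
surface growth is √(deformed/reference anterior-surface area), which
equals the boundary-relative linear measure because the boundary is
fixed.  The analytic film-on-substrate comparison is
λ = 2πT(µ_k/(3µ_s))^(1/3).

## Two-layer indentation model

The apparent Young's modulus under an indenter probing skin of thickness
T on a softer substrate is modelled as

    E(d) = E_substrate (E_skin/E_substrate)^M,   M = 1/(1 + A (d/T)^B),

with positive mixing coefficients A, B.  E(0) = E_skin and
E(d≫T) → E_substrate exactly.  Fits minimise least squares on log E
(the moduli span ~2 decades), multi-started over (A, B) ∈ {0.5, 1, 2}²,
with positivity enforced by log-parameterisation.  Because T and A trade
off, the model is fitted independently at each of 10 thicknesses across
27–72 µm; reported parameters are means across that grid and the quoted
uncertainty is the spread (SD) across it — a convention of this package,
not a claim about how the published uncertainties were derived.  The
conventional exponent symbol collides with the boundary length L and is
renamed `mixing_exponent`.

Synthetic indentation profiles apply multiplicative lognormal noise of
unit mean and CV 5% (moduli are positive and scale-spanning); profiles
and fits are exercised in round-trip tests (noiseless: all four
parameters within 1%; 5% noise, 100 seeds: moduli within 10%).

## Geometries and problem sizes

All meshes are structured curvilinear hex lattices split into six
positively oriented tetrahedra per cell (reproducible connectivity, exact
skin–substrate interface conformity).  The single-lobe stand-in for the
reconstructed embryonic geometry is parametric: a 120° inner arc of
length L, lobe extent 1.0 L outward, crease along the sagittal edge;
sensitivity to the arc angle is part of the test suite.  The substrate
block is 10 T deep (geometrically graded layers, finer at the interface);
the real substrate depth is not quantified in the available measurements.

Desk-scale reference resolutions (chosen so each experiment relaxes in
minutes on one CPU core; all runs single-threaded and bit-reproducible
per seed):

| experiment | lattice | tets |
|---|---|---|
| curved-lobe ramp | 28 × 56 × 2 | ~18.8k |
| PDMS semicylinder | 16 × 40 × 2 | ~7.7k |
| bilayer frill | 16 × 32 × (2+3) | ~15.4k |
| wavelength strip | (8–10/T) × 2 × (3+5) | ~10–12k |
| semicylinder sweeps | 12 × 30 × 2 | ~4.3k |

At these resolutions the in-plane node spacing is 2–3 T rather than the
≤ T of the original GPU-scale meshes, and the quantitative fidelity is
mixed, deliberately reported rather than hidden:

* The lobe reproduces the published ridge sequence at the measured
  stages — two low-amplitude ridges at g = 1.10 and three by g = 1.20 —
  but late in the ramp (g ≳ 1.24) two ridges merge, so the g = 1.28
  state carries two ridges where fully resolved runs keep three.  The
  post-buckling minima differ in energy by only ~0.2% at this scale, and
  both the selected branch and the merging are step-size sensitive near
  onset.
* The bilayer frill wrinkles and its realized linear surface growth
  (≈ 1.277 for applied 1.3 at stiffness ratio 100) matches the published
  elastic-compression measurement, but modal ridge counts read 1–2
  rather than 3: the film-substrate wavelength at ratio 100 (≈ 0.28 L)
  is marginally resolved, and at ratio 20 (≈ 0.17 L) unresolved, so the
  count-vs-ratio trend is not recovered at this scale (counts rise with
  resolution: 1 at 15k tets, 2 at 35k in refinement runs).
* The semicylinder growth sweep shows buckling and the expected
  thickness trend, but count-vs-g monotonicity fails at the smallest
  meshes (a low-amplitude two-wrinkle state at g = 1.1 merges into one
  deep fold by g = 1.2).
* The PDMS analog (three pleats, wavelength increasing toward the free
  edge) and the film-on-substrate wavelength law (measured within 2 SD
  of λ for ratios 10 and 50) are reproduced.

Refinement experiments show onset and counts moving toward the reference
values as the in-plane spacing approaches T; the residual ~1.1× bending
overstiffness of the mean-dilatation linear tets is the dominant
remaining bias.

## What the synthetic data do and do not emulate

The generators reproduce the geometry and mechanics regime of the study
system (thin stiff sheet on a ~100× softer substrate, fixed curved inner
boundary, sagittal crease, two-decade modulus transition with
multiplicative measurement noise).  They do not emulate imaging noise,
fixation shrinkage (the published fixed-tissue amplitudes are
themselves flagged as shrinkage-biased), spatial thickness variation of the skin, or
anisotropic/viscoplastic tissue behaviour.  Passing tests therefore
establish correctness of the implementation under the stated model, not
fidelity of the model to every feature of embryonic tissue.

## Known limitations

* Strictly elastic, quasi-static; no contact, so deep post-buckling
  folds that would self-contact are not modelled.
* Displacement-based linear tetrahedra at ν = 0.45 lock volumetrically;
  at desk-scale aspect ratios this biases ridge counts low (see above).
* The crease-growth region is only ~T wide; at desk-scale in-plane
  spacings ≫ T the crease tensor's influence is under-resolved.
* The parametric lobe replaces the (undeposited) reconstructed embryo
  mesh; absolute amplitudes are not comparable, only their scale.
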