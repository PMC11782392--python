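# Methods

This note documents the model behind `aaaprobe`: what is simulated, the
constitutive and structural choices, the numerical methods, and the known
limits of the reduction.  It is written for a reader who wants to judge what
the computed numbers do and do not mean.

## Problem

Clinical surveillance of abdominal aortic aneurysms (AAA) measures the
antero-posterior (AP) diameter with ultrasound, and increasingly the cyclic
diameter change ΔD = D_sys − D_dias over the cardiac cycle, from which a
stiffness index

    β_diam = ln(P_sys/P_dias) / (ΔD/D_dias)

is formed (β_circ analogously from the circumference C).  The sonographer's
probe, however, presses on the abdomen with anywhere from ~2 kPa (light
contact, LPP) to ~30 kPa (firm compression, FPP).  That pressure transmits
through the abdominal soft tissue, partially unloads the aneurysm wall, and
— because the arterial stress–strain curve is J-shaped — moves the wall's
operating point toward its compliant "toe" region.  The measured β therefore
depends on how hard the probe is pressed.  The Elasticity Loss Index

    ELI = β_LPP / β_FPP = (Δx_FPP/Δx_LPP) · (x_dias,LPP/x_dias,FPP)

(x = D or C; the second, ultrasound-only form follows because the pressure
ratio cancels) quantifies that dependence: ELI_circ > 1 flags a nonlinear,
J-shaped wall, while a linear-elastic wall leaves β_circ essentially
unchanged (ELI_circ ≲ 1).  The package reproduces this mechanism in silico
with a nonlinear finite-element model of the scanning-plane cross section
and a 54-run factorial study: 3 patient-like geometries × 3 probe levels
(2/15/30 kPa) × 3 surrounding-tissue shear moduli (5/10/20 kPa) × 2 wall
models (nonlinear HGO vs. linearized orthotropic).

## Geometry: a synthetic scanning plane

Real cohorts start from CT segmentations that are not publicly available.
The geometry module instead generates the maximum-diameter cross section
parametrically: an elliptical abdomen outline (default semi-axes
160 × 110 mm), an elliptical aneurysm lumen mid-surface (AP diameter
d_max, the clinical measurement), a circular "spine cut" posterior to the
aneurysm whose boundary is clamped, and a 70 mm probe footprint centered on
the anterior surface.  Three archetypes emulate the cohort-like variation
reported for small surveillance series — sac roundness, spine proximity,
aorta depth:

| archetype | d_max (mm) | lumen ellipticity | aorta depth (mm) | spine gap (mm) | wall elements |
|---|---|---|---|---|---|
| P1 | 50 | 1.08 | 45 | 8  | 82 |
| P2 | 55 | 1.00 | 40 | 10 | 86 |
| P3 | 46 | 1.16 | 50 | 4  | 78 |

These parameter values are **synthetic**: they are our invention, chosen
once to span the clinically surveilled 45–55 mm AP-diameter band with one
near-spherical sac (P2) and two laterally elongated, spine-constrained sacs
(P1, P3 — P3 the most constrained).  Brachial blood pressures
(76/138, 90/153, 88/144 mmHg) are paired with the archetypes and converted
to abdominal aortic pressures by the standard amplification adjustment
(diastolic −12 %, systolic +5 %), then mmHg → kPa.

The wall mid-surface is discretized into ~82 membrane elements per cross
section (82/86/78 across archetypes), matching the element count at which
per-element field statistics are reported.

Meshing is a distmesh-style force equilibration: boundary vertices are
fixed, interior points seeded on a graded triangular lattice (edge target
2 mm at the wall → 14 mm at the abdomen outline, locally refined under the
probe) and relaxed under edge-spring forces with Delaunay retriangulation,
using shapely signed distances to the domain (abdomen minus lumen minus
spine).  Typical meshes: ~1100 triangles, minimum angle ≥ 27°.  Meshing is
deterministic for a fixed seed.

## Materials

**Wall (HGO).**  The aneurysm wall is an incompressible fiber-reinforced
membrane with the Gasser dispersion form

    Ψ = C10 (I1 − 3) + (k1 / 2k2) Σ_{i=4,6} [exp(k2 E_i²) − 1],
    E_i = κ (I1 − 3) + (1 − 3κ)(I4i − 1),

two symmetric fiber families at ±θ from the circumferential direction,
fibers active only in tension (E_i > 0).  Parameters (elderly healthy
aorta): C10 = 100.9 kPa, k1 = 4.07 MPa, k2 = 165.55, κ = 0.16, θ = 48.4°.
The membrane reduction fixes λ_z = 1 (the cross section is a symmetry
plane), eliminates the thickness stretch by incompressibility
(λ_t = 1/λ_circ) and imposes zero through-thickness stress, yielding a
closed-form σ_circ(λ) and analytic tangent.  The exact dispersion variant
(dispersion inside vs. outside the exponential; volumetric split) is not
uniquely fixed by the parameter table it comes from; we fix the
generalized-structure-tensor form above and validate it by tangent
self-consistency.

**Wall (linearized).**  An orthotropic linear elastic membrane with
E_θ = 1.11 MPa, E_z = 3.58 MPa, G = 4.0 MPa, ν = 0.44.  The single ν is
interpreted as ν_θz and ν_zθ = ν E_z/E_θ follows from the symmetry
relation.  Under ε_z = 0 and zero through-thickness stress the hoop
response is σ = C_eff ε with C_eff = E_θ/(1 − ν_θz ν_zθ) ≈ 2.96 MPa,
constant by construction.  G does not enter the in-plane cross-sectional
response of this reduction; it is stored for completeness.

**Wall in compression (tension field).**  A 2 mm membrane cannot support
circumferential compression — it wrinkles; numerically, a compressed
membrane ring with no bending stiffness is unstable at the shortest
resolved wavelength.  Both wall models therefore default to a tension-field
treatment: the carried tension is scaled smoothly (cubic Hermite over
λ ∈ [0.98, 1]) down to a 5 % residual in compression.  This mirrors the
behavior of thin shells shedding compressive load, and is why lateral wall
stresses "tend toward zero" rather than going strongly negative under firm
probe pressure.  `compression="elastic"` restores the full elastic law.

**Surrounding tissue.**  Homogeneous, nearly incompressible neo-Hookean in
plane strain: W = (μ/2)(Ī1 − 3) + (K/2)(J − 1)², with μ ∈ {5, 10, 20} kPa
(soft/medium/stiff) and volumetric penalty K = max(1000 μ, 6·10⁴ kPa).  The
floor on K keeps |J − 1| < 10⁻³ under the firmest probe load (tissue
pressures reach ~30–45 kPa, so K = 1000 μ alone would not) without
ill-conditioning the direct solver.

## Discretization and solver

Tissue: 6-node quadratic triangles (3-point Gauss), generated by inserting
midside nodes on the linear triangulation.  Quadratic displacement was
chosen over linear because constant-strain triangles lock volumetrically
near the incompressible limit.  Wall: 2-node geometrically nonlinear
membrane segments carrying N(λ) = σ(λ)·t_ref/λ, sharing corner nodes with
the tissue — the tie constraint holds identically.  Loads are follower
pressures (blood on the deformed wall polyline, probe on the deformed
abdomen footprint) with their exact, configuration-linear consistent load
vectors and load-stiffness blocks; on 3-node quadratic edges the consistent
nodal weights are (1/6, 2/3, 1/6) and the load stiffness is constant.

Equilibrium: total Lagrangian Newton–Raphson with linear load stepping
(default 10 increments per stage), automatic step halving (max 4) on
divergence, and per-iteration backtracking when a trial step inverts an
element or overflows the fiber exponential.  Convergence at relative
residual 10⁻⁸ of the external force norm or absolute 10⁻¹⁰ N/mm.  The
sparse tangent (nonsymmetric due to follower loads) is factorized directly;
everything is deterministic.

**Probe rim taper.**  A uniform pressure step on a soft half-space induces
a crease-like strain singularity at the footprint rim (surface folding at
shear strains ~O(1)).  The physical transducer face is a curved array and
does not end in a pressure step; the applied probe pressure therefore rolls
off as cos² over the outer 30 % of the half-footprint.  The taper is
geometric regularization, not a fitted quantity.

## The out-of-plane (2.5D) correction

All reported measurements (AP diameter, circumference, σ_circ, ε_circ)
live in the maximum-diameter plane, which motivates reducing the 3D problem
to that plane.  Pure plane strain, however, misrepresents one thing
badly: the probe footprint is 20 mm *out of plane*, so in 3D the
probe-induced stress decays strongly with depth, whereas a plane-strain
strip load does not decay enough.  Taken literally, plane strain drives the
transmural pressure negative and collapses the lumen to a slit near ~12 kPa
probe pressure — the model becomes unsolvable and unphysical well below the
firm-probe condition.

The package therefore applies a shear-lag correction: an elastic foundation
with modulus k = μ·(π/2ℓ_z)², ℓ_z = 20 mm (the probe's out-of-plane
footprint), the modal stiffness of a half-cosine decay profile over ℓ_z.
Crucially the foundation acts only on the *probe-induced* part of the
deformation: it is anchored at the no-probe diastolic state, and before the
systolic stage its force is frozen (dead load), because both the diastolic
inflation and the cyclic distension are z-uniform over the sac length in 3D
and must not be artificially stiffened.  ℓ_z is fixed at the physical
footprint dimension; setting `out_of_plane_length=None` recovers pure plane
strain.  This correction is the central modeling departure of the package
and the main reason computed magnitudes should be read as 2.5D surrogates,
not patient-specific 3D predictions; the study reproduces directions and
orderings of effects.

## Zero-pressure configuration

The imaged (generated) geometry corresponds to diastole.  The load-free
reference is recovered by the backward-displacement fixed point: inflate
the candidate reference to diastolic pressure (full assembly, tissue
included, homogeneous lumen pressure, no probe), set
X_{k+1} = X_imaged − U_k, repeat until the re-inflated candidate matches
the imaged geometry within 0.05 mm (max nodal error), at most 15
iterations.  The plain iteration contracts slowly for soft tissue
(ratio ≈ 0.7), so the update is Aitken-relaxed by default; this changes
the rate, not the fixed point, and the closure property (re-inflation
reproduces the target within tolerance) is checked for every study
configuration.

## Examination protocol

Per run: (1) ramp lumen pressure to diastolic with no probe; (2) anchor the
out-of-plane foundation and ramp the probe pressure to its level at
constant diastolic pressure; (3) freeze the foundation force and raise the
lumen pressure to systolic at constant probe pressure.  Blood pressure is
applied before the probe because the probe-first order squeezes an
unpressurized ring, which buckles immediately (and no sonographer scans an
unpressurized patient).  D is measured as the span of the intersections of
the deformed wall mid-surface with the AP line (lab-frame +y, the fixed
probe axis) through the deformed lumen centroid; C as the mid-surface
polyline length.  Mid-surface rather than inner-surface measurement is a
convention; the relative indexes are insensitive to the constant offset at
first order.

β is computed with the applied aortic (adjusted) pressures, since those are
the loads in the simulation.  The ELI implementation evaluates the
ultrasound-only form and verifies the β-ratio identity to machine
precision on every output.

## Study sizes and runtime

The default factorial study (54 runs, 18 zero-pressure recoveries, meshes
of ~1100 quadratic triangles, ~82 wall elements) runs in roughly a quarter
of an hour on one CPU.  Field summaries (median/quartiles of σ_circ at
diastole+probe and of cyclic ε_circ) are taken over the wall membrane
elements of the single modeled cross section.  Welch two-sided t-tests
compare per-element fields between probe conditions.

## What the synthetic study does and does not show

The generator emulates: cohort-scale geometric variation of the scanning
plane, patient-specific blood pressures, the probe/tissue/wall load path,
and realistic parameter magnitudes.  It does not emulate: true 3D sac
shape and its axial tethering, intraluminal thrombus or calcification
(absent in the emulated cohort), heterogeneous abdominal anatomy (organs,
muscle sheets), image formation or operator variability, axial prestretch
and residual stress.  Passing tests therefore demonstrate that the
*mechanism* — probe pressure shifting a J-shaped wall toward its toe and
lowering measured stiffness, modulated by surrounding-tissue stiffness and
geometry — is reproduced with clinically plausible magnitudes; they do not
validate patient-specific values of β or ELI.

## Numerical choices (summary)

- Units: kPa, mm; forces per unit out-of-plane depth (kPa·mm).
- Newton tolerances: rtol 10⁻⁸ (external-force scale), atol 10⁻⁷ kPa·mm
  (= 10⁻¹⁰ N/mm); max 30 iterations, 10 load steps per stage, 4 halvings.
- Zero pressure: tol 0.05 mm, max 15 iterations, Aitken ω ∈ [0.5, 8].
- HGO exponential guarded at k2·E² ≤ 60 (signals "stretch out of
  admissible range").
- Tie constraint by shared nodes; spine clamp includes midside nodes.
- Degenerate inputs (zero-length pressure edges, inverted reference
  triangles, non-simple contours) raise typed exceptions rather than
  propagating NaNs.

## Known limitations

Two directional findings of full 3D models are *not* reproduced by the 2.5D
reduction, and are worth knowing before interpreting stress fields:

- Under firm probe pressure the whole wall-stress distribution shifts
  *down* here (minimum toward zero *and* maximum decreasing), because the
  transmitted pressure unloads the cross section as a whole.  In 3D the
  anterior/posterior wall tension can rise while the lateral walls unload
  (ovalization dominating a more attenuated transmitted pressure).  The
  heterogeneity (IQR) orderings and all β/ELI orderings are unaffected.
- The linear wall's β_circ rises with probe pressure by ~8–9 % with soft
  surrounding tissue (tissue compression-stiffening), a stronger version
  of the same effect that makes ELI_circ < 1 for linear walls in 3D
  studies, where β_circ is closer to constant.

Other limitations:

- The 2.5D foundation is a single-mode surrogate for 3D spreading; its
  scale ℓ_z is physically motivated but not calibrated against 3D runs.
- The tension-field wall has no bending stiffness, so post-wrinkling wall
  shapes are not resolved, only the shedding of compressive load.
- Probe–skin contact is idealized as (tapered) pressure; no friction, no
  rigid-probe kinematics.
- Archetype geometries are analytic ellipses; real sacs are lobed and
  asymmetric.  Magnitude-level agreement with any specific patient is out
  of scope.
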