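# Methods

## Model

The tissue is represented as a labelled voxel grid with five classes:
air/paraffin (0), interstitium (1), blood lumen (2), lymphatic lumen (3)
and pleural-surface voxels (4). Axis order is (z, y, x) with z the
sectioning/depth axis; the voxel pitch is isotropic and given in μm.

Flow is steady, incompressible and inertia-free. The interstitium
(alveolar walls, matrix and capillary beds lumped together) is a Darcy
porous medium, u = −(k/μ)∇p with ∇·u = 0. Vessel lumens carry Stokes
flow, 0 = μ∇²uⁱ − ∇pⁱ, ∇·uⁱ = 0 for i ∈ {L, B} (lymph, blood). Every
lumen–interstitium voxel face is a permeable membrane whose normal
seepage obeys uⁱ·n = Kⁱ(pⁱ − p) with n the outward lumen normal; the
tangential velocity at membrane faces is zero (the wall keeps its
no-slip character for the tangential component — the model itself does
not specify it, and the seepage velocities are ~6 orders below lumen
velocities, so the choice is inconsequential). Boundary conditions:
Dirichlet pressure p_int on external interstitial faces; uniform
prescribed normal velocity on inlet opening patches (the lumen patches
on the three cube faces farthest from the pleura); Dirichlet pressure on
the remaining opening patches, with backflow suppression (below);
no-flux/no-slip at air interfaces and at blood–lymph contact faces;
gravity neglected. Osmotic (Starling) terms and cyclic breathing strain
are outside scope.

The porosity φ does not enter the steady equations; it is carried only
to report the pore velocity u/φ as a diagnostic.

### Parameters

| symbol | default | units | meaning |
|---|---|---|---|
| μ | 1.2e-3 | Pa·s | interstitial-fluid dynamic viscosity |
| ρ | 1030 | kg·m⁻³ | fluid density (not used at steady state) |
| k | 4.4e-18 | m² | interstitial Darcy permeability |
| φ | 0.13 | — | interstitial porosity (diagnostic only) |
| p_int | −1064 | Pa | external interstitial pressure |
| u_L | 3e-4 | m·s⁻¹ | lymphatic inlet normal velocity |
| p_L | −1200 | Pa | lymphatic outlet pressure |
| K_L | 1.9e-12 | m·s⁻¹·Pa⁻¹ | lymphatic wall hydraulic conductivity |
| u_B | 3e-3 | m·s⁻¹ | blood inlet normal velocity |
| p_B | +2000 | Pa | blood outlet pressure |
| K_B | 2.71e-12 | m·s⁻¹·Pa⁻¹ | blood wall hydraulic conductivity |

All are literature values for peripheral human lung at rest. Internally
everything is SI; μm pitches are converted at ingestion. Lengths given
in μm are converted to voxels by rounding to nearest (830/13.2 → 63).

## Discretization and solver

Marker-and-cell staggering on the uniform voxel grid: one pressure
unknown per fluid cell, one normal-velocity unknown per lumen–lumen
interior face and per pressure-outlet boundary face. Membrane-face
velocities are eliminated through the wall relation, so membranes appear
as symmetric conductances K·A between the adjacent cell pressures.
Darcy faces carry conductance kA/(μh); external Dirichlet faces use the
half-cell gradient (making the 1D column solution exact). The viscous
operator uses the standard 7-point stencil with ghost no-slip walls at
half-cell tangential distance; wall-normal seepage is treated as zero in
the viscous stencil (it is negligible against lumen velocities). Outlet
pressures act on ghost cells one cell beyond the boundary, so the
effective pressure-drop length of a tube of n cells is (n+1)h; the
Poiseuille validation compares against the closed form at that length.

With the velocity block A (SPD), discrete gradient B and pressure
conductances C, the eliminated system (C + BᵀA⁻¹B) p = rhs is symmetric
positive definite whenever any Dirichlet pressure exists (otherwise a
singularity error is raised before solving; fluid components not
connected to any pressure anchor are dropped and counted). The solver
factorizes A sparsely (the lumen networks are thin, so the factor is
cheap), runs Jacobi-scaled conjugate gradients on the Schur complement,
then refines: a coarse Galerkin correction over the strongly-coupled
components (each lumen network and each Darcy-connected interstitial
region) removes the pressure-datum drift that membrane-only coupling
leaves nearly unconstrained, alternated with short CG passes until the
physical continuity defect ‖r‖/‖gross flux‖ falls below the requested
tolerance. Velocities are recovered as u = A⁻¹(b_u − Bp) with a
per-component pressure datum (chosen exactly equal to an outlet pressure
of the component) subtracted first: the ambient pressure (~10³ Pa) and
the intra-lumen variation (~10⁻⁵ Pa) otherwise cancel catastrophically
and floor the membrane-flux accuracy near 1e-6 relative. With the datum
shift, mass-balance defects on the analytic oracles reach ~1e-11
relative. A direct sparse solve was rejected after measurement: on this
class of grids SuperLU needs 125 s / 3.3 GB at 48³ and exceeds 8 GB at
64³, while the Schur-CG path solves 96³ in ~3 minutes.

Backflow suppression: after each solve, outlet faces with inward normal
velocity are converted to no-slip walls and the system re-solved, up to
20 iterations (flagged if the cap is hit). Since faces are only ever
added to the wall set, the loop cannot oscillate. Suppression can be
disabled for pressure-driven validation problems and linearity checks.

## Image processing for modelling

`prepare_model_volume` mirrors the standard preparation chain: extract a
cubic VOI; upsample each class mask by integer replication (volume
fractions preserved exactly; the reference factor is 3 per axis, i.e. 27
children per voxel); smooth each class with a 3×3×3 median filter;
remove lumen components not 26-connected to any domain face (counted in
provenance); resolve overlaps with precedence lymph > blood > tissue
(equivalent to subtracting the lymph image from the blood image and both
from the tissue image); divide the pitch by the upsampling factor and
multiply by an optional shrinkage scale (×2 emulates the fixation
shrinkage correction; voxel counts are unchanged, only the pitch).
On unscaled grids (upsample 1), the 3³ median erases vessels thinner
than ~2 voxels, so desk-scale runs use `median_window=1`.

Inlet faces are the lumen patches on the three distal cube faces: the
face opposite the pleural face plus the two perpendicular faces with the
larger mean pleural distance, ties broken in fixed face order. A vessel
class with no inlet patch is an error (the model would be unforced); a
class with inlets but no outlet is only a warning, since membrane
leakage still admits a steady state.

## Morphometry

- Pleural distance: Euclidean distance transform to the pleural-voxel
  set (or to the declared pleural face when no pleural voxels exist),
  scaled by the pitch.
- ROI sampling: rejection placement of axis-aligned squares on the
  tissue extent of one z-plane; overlapping candidates are rejected and
  attempts are capped (default 500), with a shortfall flag when fewer
  than requested fit. `seed=None` is entropy-seeded; tests and the
  pipeline always pass seeds.
- Classification: median of the pleural distances over the ROI's tissue
  voxels, strictly below 830 μm → subpleural. ("Median" was chosen over
  "mean" as the robust reading of the source tooling's wording.)
- Volume/surface: voxel counts × pitch³; surface area from a marching
  cubes triangulation of the lymph mask. The field is lightly smoothed
  (Gaussian σ = 0.8 voxels) before contouring at 0.5 — a binary
  isosurface overestimates a sphere's area by ~9%, the smoothed one is
  within ~1% — and floored at 0.6 on original mask voxels so that
  1-voxel collapsed sheets cannot drop below the contour level and
  vanish. Thin structures (radius ≲ 2 voxels) are still measured a few
  percent low.
- Fractal dimension: corner-aligned box counting with box sizes 2, 4,
  8, … ≤ min(dims)/4; D = −slope of log N vs log s. Fewer than three
  usable sizes or non-varying counts → excluded flag (mirrors the
  failure mode on small partial volumes). Corner-aligned grids were
  chosen over translation-optimized ones for determinism.
- Skeleton: 3D topology-preserving thinning (scikit-image); skeleton
  voxels with >2 of 26 neighbours are junction voxels, adjacent junction
  voxels merge into one junction node; branches are maximal paths
  between end/junction nodes; tortuosity = polyline path length /
  Euclidean end-to-end length, averaged unweighted over branches
  (the aggregation is not specified by the source method; unweighted
  mean chosen). Zero-Euclidean branches (closed loops) are excluded
  from the mean and counted. Note: the thinning implementation
  annihilates even-width tubes whose axis lies exactly between voxel
  columns, so validation geometries use integer-centred axes.

## Synthetic phantoms

The generator emulates segmented peripheral lung tissue: a 2-voxel
pleural slab on the −z face; air blobs (default 15% volume fraction,
spheres of 2–4.5 voxel radius) standing in for alveolar spaces; a blood
tree built from jittered centreline polylines joined through a central
hub, rasterized with spherical brushes (root radius 30 μm, taper 0.8,
two extra branching levels); and a lymphatic network grown from a
depth-spanning spine anchored at the first lymphatic opening. Side
segments (radius 10–25 μm, the micro-lymphatic calibre range; the true
radius distribution is unknown, so defaults sit inside that range) are
added per depth bin until the realized lymph/tissue volume fraction
matches the linear gradient model target_vf + gradient·depth within
−8%/+12%, with a hard ±20% check per bin. A configurable fraction of
segments is drawn as 1-voxel-thick ribbons (partially collapsed
lymphatics) and a fraction runs parallel to nearby blood vessels
(perivascular); optionally a lymphatic annulus fully encircling a
z-running blood segment is painted and connected to the spine. Opening
counts per cube face are realized exactly and verified by 2D connected
component counting on each face; interior geometry is clipped two
voxels away from all faces so no accidental openings occur. Everything
is deterministic given the spec seed; cohort volumes derive per-volume
seeds from (seed, index).

Default study conditions: pitch 13.2 μm, pleural volume fraction 0.04,
gradient −1e-5 per μm — volume fractions of a few percent falling with
pleural distance, matching the reported range for control tissue. The
intralobular configuration places 1 lymphatic + 4 blood inlet openings
on the distal faces (plus one outlet per class elsewhere); the
subpleural configuration places 6 lymphatic + 3 blood.

Cohorts for the correlation-recovery study assign each VOI a true
volume fraction intercept + gradient·distance + N(0, σ), truncated to
[0.008, 1]: the floor is the generator's structural minimum (the
connective spine and opening stubs occupy ~0.6% of a 48³ volume and
cannot be removed without disconnecting the network). Defaults
σ = 0.006 and distances 0–2500 μm were calibrated once so that the
expected |r| = βσ_d/√(β²σ_d² + σ²) ≈ 0.77 at n = 25, the effect size
reported for control tissue; measured recovery gives |mean r| ≈ 0.77.

What the phantoms do not emulate: scanner physics (noise, beam
hardening), registration artefacts, real alveolar micro-architecture
(air is spherical blobs, not septa), anatomically realistic tree
topology, or stain variability. Passing tests therefore demonstrate
correctness of the measurement and modelling chain on known geometry,
not performance on real segmentations.

## Statistics

Mann–Whitney U uses the count-distribution recurrence for an exact
two-sided p when both groups have ≤12 observations and no ties, and the
normal approximation with tie and continuity corrections otherwise; the
method used is recorded. Distance regressions report signed Pearson r
with p from t = r√((n−2)/(1−r²)) (identical to the slope test of the
simple regression), dropping and counting excluded records such as
failed fractal fits. Group comparisons run the six per-measure tests
with raw p-values by default; Bonferroni adjustment is optional.

The sensitivity protocol multiplies and divides K_L, K_B and u_L by 100
(one base + six perturbed solves) and reports the change in Q_L_in, the
net membrane flux into the lymphatic domain. The "below the error
limits" flag compares each |ΔQ| against a discretization-error estimate
taken as |ΔQ_L_in| between the base grid and one ×2 refinement — a
portable substitute for solver-internal error estimates. Note that with
the default parameter set the membrane resistance 1/K (~4–5e11) exceeds
the interstitial access resistance μℓ/k (~1e10 at ℓ ≈ 50 μm vessel
spacing) by a factor ~40, so transmural flux scales almost linearly
with K and the conductivity perturbations land far above the
discretization error; only the inlet-velocity perturbations show the
asymmetric small-change structure (×100 collapses drainage by raising
lymph pressure; ÷100 raises drainage only slightly).

## Problem sizes and tolerances

Validation and study runs use desk-scale sizes chosen so the whole
suite completes in minutes on one CPU: oracles at 20³–40² cross
sections, the phantom flow at 64³ (≈ 845 μm cube at native pitch), the
sensitivity base case at 48³ with a 96³ refinement, cohorts of 25 × 48³
phantoms × 20 replicates. Solver tolerance defaults to 1e-10 (1e-8 for
the larger study runs); analytic-oracle tests run at 1e-12. Degenerate
inputs are handled explicitly: empty masks give zero/None measures, an
unforced flow system raises before solving, infeasible phantom specs
raise errors naming the violated constraint.

## Known limitations

- Staircase lumen walls bias tube flow low (−7% at radius 8 voxels,
  converging under refinement); vessel radii below ~2 voxels are not
  resolved by the Stokes discretization.
- Skeleton path lengths overestimate smooth curve lengths by up to ~5%
  (digital chain-code bias), which propagates into tortuosity.
- The membrane condition uses cell-centre pressures at half-voxel
  distance from the wall, shortening the effective Darcy path by one
  voxel per crossing (sub-percent at the default parameters).
- Collapsed lymphatics are rendered as flat ribbons, not as deflated
  tubes with residual lumen.
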