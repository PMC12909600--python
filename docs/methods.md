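# Methods

## Coordinate and grid conventions

All geometry lives on axis-aligned regular grids in world millimetres,
0-based indices, voxel-center convention: voxel `(i, j, k)` has its center
at `origin + index * spacing`. Occupancy is decided by voxel-center
inclusion (no partial-volume weighting) — deliberately simple, because it
makes every geometric operation verifiable by exhaustive enumeration on
small grids, which is how the test suite checks it. Non-axis-aligned
direction matrices are rejected at import; DICOM-RT is out of scope.
Synthetic cases default to 2 mm isotropic spacing (CBCT-like); geometry
unit tests use 1 mm. Volumes reported in cc are `count × voxel volume /
1000`.

## Lattice model

The high-dose lattice is a simple-cubic grid of sphere centers, step equal
to the center-to-center spacing (default 20 mm), symmetric about a center
point (default: the GTV centroid, since a center point must be chosen and
no clinical rule is given). Per axis the smallest symmetric set of planes
covering the requested matrix extent is used: offsets `−k…k` with
`k = ceil(extent / 2·spacing)`, so a 200 mm extent at 20 mm spacing gives
11 planes (1331 spheres) and the matrix extent defaults to the smaller of
200/300 mm that exceeds the GTV bounding box by one spacing. Sphere
diameter defaults to 10 mm. Alternative (offset-plane) topologies exist in
the literature; the topology here is the plain cubic grid, kept as a single
code path rather than a config enum until a second topology is needed.

**Cropping.** The GTV is retracted by 10 mm (exact EDT); each sphere is
kept only if at least 95 % of its voxels survive intersection with the
retracted GTV, automating the manual deletion of partially cropped spheres.
The 95 % tolerance corresponds to allowing a spherical-cap protrusion of
≈1.3 mm for a 5 mm sphere — below one voxel at 2 mm spacing — so the kept
set matches the analytic criterion `‖c − c_GTV‖ ≤ r_GTV − 10 − r_sphere`
for spherical GTVs to within one voxel (a property the tests assert).
PTV_High is the union of the *full* kept spheres, not their cropped
remnants, so the boost target is geometrically clean; all its voxels still
lie well inside the GTV because survivors sit ≥ ~8.7 mm inside it.

## Margins

Uniform expansion/retraction use the exact Euclidean distance transform
with physical sampling (`scipy.ndimage.distance_transform_edt`), not
structuring elements, so margins are isotropic in mm even on anisotropic
grids. Expansion: occupied iff distance to the nearest occupied voxel
center ≤ margin. Retraction: occupied iff occupied and distance to the
nearest unoccupied voxel center > margin. Both are identity at margin 0;
expansion clipping at the grid edge and empty retraction results warn
rather than fail. PTV_Low is the 5 mm GTV expansion (the upper end of the
clinical 3–5 mm range, configurable) clipped to Body; the normal-tissue
ring is `(PTV_Low + 30 mm) − PTV_Low`, also clipped to Body — on narrow
extremity bodies the ring is heavily body-clipped by design.

## Stand-in dose painter

The clinical optimizer is a commercial black box, so the package paints
dose geometrically and claims only *objective satisfaction*, not physical
realism:

* **bath**: uniform `phase1_gtv_dose` (4 Gy) inside PTV_Low, Gaussian
  falloff `4·exp(−d²/2σ_p²)` of the EDT distance `d` outside
  (σ_p = 4 mm), hard-capped at the 4 Gy ring objective outside PTV_Low;
* **boost**: per kept sphere, flat `phase1_sphere_dose` (12 Gy) inside the
  sphere with a Gaussian tail `12·exp(−(r−R)²/2σ_b²)` beyond its surface,
  truncated at 5σ_b; spheres combine by voxelwise maximum;
* **combination**: `max(bath, boost)` inside the GTV, bath alone outside —
  maximum, not sum, so overlapping kernels cannot breach the 15 Gy hotspot
  cap, and boost can never spill outside the GTV at all.

σ_b defaults to 2.5 mm. This is a budget choice: the PTV_Low mean-dose
objective allows at most 1 Gy of boost-penumbra contribution on top of the
4 Gy bath, and a shell integral of the tail over a densely packed lattice
(≈1 sphere per 8 cc of retracted GTV) gives ≈0.6–0.7 Gy at σ_b = 2.5 mm
versus ≈1.1 Gy at 4 mm, which would breach the 5.0 Gy bound for the
largest targets. Phase 2 paints a uniform 4 Gy fraction in PTV_Low with
the same capped falloff; phases accumulate by voxelwise addition on an
identical grid. Geometrically unsatisfiable requests (a sphere within one
σ_b of the PTV_Low boundary, or a breached hotspot cap) raise
`PlanConstructionError` listing the violated constraint instead of
silently degrading coverage. The painter is fully deterministic.

## DVH evaluation

`D(v)` sorts in-mask doses descending (stable sort as the tie-break) and
interpolates linearly between cumulative-volume knots `k × voxel volume`,
clamping to the hottest voxel below one voxel volume — at 2 mm spacing a
voxel is 0.008 cc, so D0.03cc interpolates inside the fourth-hottest voxel.
`V(d)` is a plain count (≥ threshold). The RTOG conformity index is the
Body volume at the prescription isodose over the target volume, with the
12 Gy prescription for PTV_High and 4 Gy for PTV_Low. The default
objective set encodes the clinical template; the PTV_Low Dmean upper bound
is 5.5 Gy by default with the stricter 5.0 Gy variant selectable (the
workflow uses the strict variant for its accept/reject gate, and the
painted plans satisfy both). Galois-style consistency between `D(v)` and
`V(d)` holds up to interpolation inside the cut voxel, which is what the
property tests assert.

## Gamma verification

Global-normalisation gamma: for each reference voxel above the 10 %
threshold, the minimum over evaluated positions of
`sqrt((Δr/dta)² + (ΔD/(δ·D_max_ref))²)`, with the evaluated dose
trilinearly interpolated on a search lattice of step `min(spacing)/2`
(configurable) out to 3×dta. The search enumerates offsets in increasing
distance and retires a voxel as soon as the spatial term alone exceeds its
current best γ, so the radius cap only affects voxels whose γ would exceed
3 anyway. Presets: 3 %/2 mm (plan acceptance) and 5 %/3 mm (secondary
verification, the default, matching how results are reported); pass gate
90 %. Local normalisation is available via a flag. The workflow's QA stage
compares the painted dose against a deliberately perturbed recomputation
(2 % global rescale + 1 mm shift by default) — an identical recomputation
would make the gate vacuous.

## Contour similarity

Dice is the standard `2|A∩B|/(|A|+|B|)` with the both-empty case defined
as 1 (identity convention). Mean surface distance is the symmetric average
of the two directed mean nearest-neighbour distances between boundary
voxel-center sets (boundary = occupied voxels 6-adjacent to background or
the grid edge), computed with KD-trees and verified against an O(n²)
all-pairs oracle.

## Synthetic cohort

The generator emulates the *geometric* character of a 10-patient cohort
(five thoracic, five extremity): elliptic-cylinder thorax bodies
(95 × 75 mm half-axes), tapered narrow extremity cylinders (radius capped
at 55 mm so the 3 cm ring is clipped by Body), GTVs as ellipsoids or
smoothed 2–3-lobe ellipsoid unions with per-axis extents drawn from
60–120 mm (thorax) or 40–80 mm (extremity) — ranges chosen so every
default case hosts at least one lattice sphere after the 10 mm retraction
(min half-extent 20 mm ≥ retraction + sphere radius + one voxel). OARs are
small offset solids. Everything derives from `numpy` seeded generators;
cohort seeds spawn from one master seed, so cases are independent and
bit-reproducible.

`perturb_contour` emulates inter-observer recontouring: the mask's signed
distance field (voxel-center EDT corrected by half a voxel so
boundary-adjacent centers sit at ≈±spacing/2) is offset by a smooth
Gaussian random field (correlation length 12 mm) normalised to the
requested RMS and re-thresholded; since |∇(signed distance)| ≈ 1 near the
surface, the boundary displaces locally by about the field value.

What the generator does **not** emulate: image intensities and artefacts,
deformable day-to-day anatomy, realistic organ shapes, heterogeneous
densities. Passing tests therefore demonstrate the correctness of the
geometry/evaluation stack and the internal consistency of the workflow,
not clinical plan quality on real patients.

## Workflow

`run_phase1` executes lattice generation → structure derivation →
recontouring surrogate with Dice/MSD gates (> 0.95, < 2 mm) → dose
painting → objective check → gamma QA, in an adaptive-or-nothing fashion:
any failed gate stops the case with no dose output and the failing stage
recorded. Only compute wall-times are logged, under fixed step names;
human steps (physician review, consults) are intentionally not simulated.
`run_phase2` paints and accumulates the four Phase 2 fractions (order
irrelevant; bath voxels reach exactly 20 Gy). `run_cohort` summarises
per-case metrics, pass flags and timings as a DataFrame/CSV.

## Problem sizes and determinism

Default cases are ≈0.8–1.2 M voxels at 2 mm spacing; a full Phase 1 run
takes on the order of a second on one core, the 10-case cohort a few
seconds. Oracle cross-checks run on ≤ 32³ grids where exhaustive
enumeration is exact. All randomness flows through explicit seeds; every
pipeline stage is deterministic given its inputs.

## Known limitations

* The painter's dose fields are idealised (flat sphere tops, Gaussian
  penumbra); peak-to-valley ratios, beam penumbra asymmetry and MU/
  deliverability are not modelled.
* Gamma search is lattice-sampled; γ values carry an O(step) upward bias
  relative to the continuous optimum (never affecting a voxel whose
  continuous γ is far from 1 on smooth fields).
* Only axis-aligned grids; no resampling between mismatched grids except
  the interpolation inside gamma.
* The both-empty Dice = 1 convention and the empty-retraction warning are
  deliberate and documented rather than errors.
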