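# Methods

This note documents the modelling choices behind `femoneck`: what each
stage assumes, which parameters matter, what the synthetic subject does and
does not emulate, and the numerical decisions a user should know before
trusting or extending results.

## Synthetic subject

The generator replaces a CT scan, an MRI muscle segmentation and a gait
trial with constructive stand-ins whose ground truth is exact.

**Femur geometry.** The femur is a union of analytic primitives in an
anatomical frame (x anterior, y medial, z superior): a tapered circular
shaft along z, a neck frustum leaving the shaft axis at the prescribed
neck-shaft angle (FNA) with the anteversion angle (ATA) built into its
transverse direction, a head sphere of the prescribed diameter (FHD), two
condylar lobes whose centre line defines the ATA reference, and
greater/lesser trochanteric bumps placed so the greater-trochanter apex
height (GTH, signed about the head centre) and the head-to-lesser-trochanter
vertical offset (OSV) are exact. Total length L fixes the head apex at
z = L with the medial-condyle base at z = 0; the absolute offset OSA fixes
the neck length. Every morphology parameter is therefore known by
construction and stored with the mesh, which is what makes the measurement
stage testable to sub-millimetre tolerances. Because OSA and ATA are
prescribed, the horizontal offset ground truth is the derived
OSH = OSA·cos(ATA).

Meshing uses a conforming six-tet (Kuhn) subdivision of a cubic lattice
(pitch = element size / 1.26, so the mean tet edge matches the requested
element size), keeping tetrahedra whose four corners fall inside the solid.
Corner slivers whose four nodes all lie on the boundary are deleted (they
flatten under snapping), then every boundary node is Newton-projected onto
the implicit surface; the few nodes whose projection would invert an
element (≈1 % of surface nodes, near primitive-intersection creases) are
backed off toward the lattice, leaving shallow local dents that the
measurement stage absorbs with trimmed least-squares fits. Default element
size is 4 mm (≈12 k nodes, 57 k linear tets, ≈37 k DOF — a desk-scale
setting; the same generator produces finer meshes and 10-node quadratic
elements on request).

**Density image.** A voxel grid (default 1.5 mm isotropic) with
cortical-level density (default 1800 mg/cm³) in a 4-mm surface shell,
trabecular level (300 mg/cm³) in the interior, a 2-mm linear transition and
zero background, emitted in calibrated units; a raw-unit mode applies a
known affine distortion and ships synthetic phantom samples so the
calibration fit is exercised end to end.

**Linkage and muscles.** Seven segments, six ideal joints; segment masses
and centres from standard anthropometric fractions of body mass and height,
with a lumped head-arms-trunk mass on the pelvis (body mass minus both
limbs) since the model has no upper body. Twenty-seven muscles are
straight origin→insertion lines with segment-fixed endpoints; femoral
attachments are anatomic anchor points on the constructive solid, snapped
to the nearest mesh surface node so FE point loads sit exactly on nodes.
The deep hip flexors (psoas, iliacus) carry a pelvic-brim via point:
straight lines would pass through the hip centre and lose their flexion
moment arm. Nineteen muscles are flagged for the organ-level load set; the
eighteen of them that attach to the femur transmit loads (the long biceps
head spans pelvis→tibia and carries none). Maximal isometric forces use
the PCSA route (k = 61 N/cm²) for the muscles with segmented volumes and
lower-limb-mass scaling of generic values for the rest; volumes, optimal
fibre lengths and pennation angles are plausible literature-scale values,
chosen once so that the default gait solves without muscle saturation.

**Gait trial.** Exactly 100 intervals. Vertical GRF is a smooth plateau
plus two bumps peaked at the double-support instants (defaults 15 % and
50 % of the cycle), scaled to body weight, identically zero in swing
(stance fraction 0.6); small anterior-posterior and mediolateral shear
components are included. Joint angles are smooth periodic curves with a
reduced range of motion consistent with the conservative gait of older
adults (hip flexion 8° ± 14°). The centre of pressure rolls heel to toe
and is placed on the line of progression 80 mm medial to the hip, a step
width typical of level walking; this makes the frontal-plane lever arm of
the GRF nearly constant through stance, so the hip abduction moment — and
with it the gluteus medius force and the neck strain — inherits the
double-bump GRF shape. With these defaults the solved gait gives peak
gluteus medius force ≈2 BW and peak hip JCF ≈4.6 BW, inside the ranges
reported by instrumented-prosthesis and modelling studies.

**What the generator does not emulate:** population shape statistics (no
statistical shape model), imaging noise and segmentation error, soft-tissue
artefact, muscle wrapping geometry beyond the single via points,
inter-trial gait variability, and upper-body dynamics. Passing tests on
this subject therefore demonstrate correctness of the computational
pipeline — not validity against in vivo strain, which requires real data.

## Morphology measurement

The protocol measures eleven parameters from the surface mesh alone.
The longitudinal direction is initialised as the first principal axis of
the surface cloud and refined by fixed-point iteration: transversal planes
at 50 % and 80 % of the current length, circle fits of the shaft sections
(excluding named trochanter/condyle/head/neck nodes), shaft axis through
the two section centres, length re-measured along it. The raw principal
axis alone is tilted a few degrees by the head mass, which would alias
into multi-millimetre length errors; the refinement removes that frame
dependence. The neck axis passes through the head-sphere centre and the
centre of the minimal-radius neck cross-section, found by sweeping
stations along the head→shaft direction and circle-fitting the inner
radial band of each station (the neck is the closest surface to its own
axis, which rejects trochanter contamination). Skew shaft/neck axes
intersect at the midpoint of their common perpendicular (OSN). All sphere
and circle fits are algebraic least squares with one 3-σ trim pass, which
absorbs the sparse snapping dents. Degenerate inputs (no spherical head,
e.g. a plain cylinder; empty shaft sections) raise explicit errors.
Recovery accuracy on 20 random subjects across the cohort band: worst
length error < 0.2 mm, worst angle error < 0.3°, against tolerances of
0.5 mm / 2°.

## Body-level solver

Quasi-static mode (the default, matching the per-interval FE coupling)
zeroes every inertial term, so inverse dynamics reduces to successive
static free bodies from the foot up; dynamic mode differentiates
zero-phase-Butterworth-filtered (4th order, 6 Hz) coordinates with periodic
central differences and applies full recursive Newton–Euler (verified
against a symbolic Lagrangian double-pendulum oracle to < 1 %). Hip
moments are balanced as full 3-vectors; knee and ankle moments are
projected on their hinge axes, the constraint torque carrying the rest.

Static optimisation is solved with the reserves eliminated:
min ‖a‖² + ‖M − A a‖² over 0 ≤ a ≤ 1, a bound-constrained linear
least-squares problem (`scipy.optimize.lsq_linear`, tolerance 1e-12,
deterministic). This is exactly the minimum-activation-squared programme
with per-DOF ideal torque reserves of unitary maximum force entering the
cost at weight one: reserves are then recruited only where muscles cannot
balance the moment. On the default gait the peak reserve is ≈0.03 % of the
peak joint moment. Pennation enters as a cos(φ) factor on the tendon-line
force (configurable off via a zero angle); the force–length–velocity
relationship is deliberately not modelled, so force = activation × F_max.

Joint reaction analysis sums, over the subtree distal to a joint, segment
weights (and inertial terms in dynamic mode), external GRF and the solved
muscle forces at every attachment inside the subtree; JCFs are reported in
the femur anatomical frame. JCF_net is the magnitude of the resultant of
the hip and knee contact forces acting on the femur.

## Material mapping and FE solver

Element density is the 4-point Gauss average of the trilinearly
interpolated image over each (straight-sided) tetrahedron; a centroid-only
mode exists for comparison. The density–modulus law defaults to a
Morgan-type power law E = 6850·(ρ/1000)^1.49 MPa with a 1 MPa floor and
global ν = 0.3 — both configurable, since published laws differ by site
and calibration chain. No modulus binning: each element keeps its own E.

Assembly shares one path for 4- and 10-node tets (per-element quadrature,
exact for the straight-sided quadratic element); the global matrix is
factorised once per constraint set (direct sparse LU) and reused across
the 100 right-hand sides of a sweep. Element strains are B·u at the
quadrature mean; nodal strains are volume-weighted element averages;
principal strains come from batched symmetric eigendecomposition. The
relaxed boundary scheme constrains exactly six DOFs — the most distal
medial-condyle node fully, the most distal lateral-condyle node
antero-posteriorly and vertically, one patella-groove node
antero-posteriorly — along the mesh's stored anatomical directions
(implemented through per-node frame rotations, so a CT frame that is not
axis-aligned is handled exactly). Six constraints make the system
statically determinate: reactions follow from equilibrium alone, which is
what lets the %δ check isolate body–organ force mismatch rather than FE
error. Verification: patch test exact to 1e-10, quadratic-tet cantilever
within 2 % of Euler–Bernoulli, global equilibrium to 1e-8 relative on
every solve.

## Coupling and the static-equivalence residual

The body (MRI/kinematic) and organ (CT) frames are deliberately misaligned
by 15° and 20 mm in synthetic mode and re-registered by point-to-point ICP
(k-d-tree correspondences, Kabsch update, PCA initialisation over the four
proper-rotation sign choices, tolerance 1e-6 mm, max 200 iterations); on
clean synthetic clouds the recovery is exact to ~1e-12 mm. Muscle forces
are applied at the closest surface node to each transformed attachment
(distances logged; warning above 2 mm, error above 10 mm); since
attachments are snapped to nodes upstream, placement distances are
numerically zero and the nodal load sum equals the transformed force sum
exactly.

The FE load set is every external force on the femur free body except the
joint contact forces: the 18 femur-attached coupling muscles plus the
femur segment weight applied at the node nearest its centre of mass
(weight ≈68 N against muscle loads of order 2 kN, so the placement
approximation is negligible). With this complete load set, %δ =
|JCF_net − R_FEM|/JCF_net measures exactly the body→organ transfer error
and is at numerical precision (≈1e-9 %) on the default sweep; omitting the
weight (`include_weight=False`) reproduces the muscle-only load scheme, in
which %δ carries the femur-weight imbalance and grows where muscle load is
small. An optional mode additionally applies the hip JCF at the femoral
head for sensitivity studies; it is off by default so the equivalence
check remains meaningful. Intervals with JCF_net ≈ 0 (deep swing) report
the absolute residual instead of a percentage.

## Post-processing

The neck region of interest lies between the subcapital plane (head-sphere
boundary) and an intertrochanteric bound, both perpendicular to the
measured neck axis. The "3-mm circle" average is implemented as the
Euclidean 3-mm ball intersected with surface nodes — at 3 mm on a ~35-mm
neck the difference from a geodesic disc is below mesh resolution.
Averaging first, then taking the extremum, suppresses point-load
singularities (the continuum hypothesis); averaged peaks are contractions
of the raw nodal extrema by construction. Peak timing uses local maxima
with a prominence floor of 5 % of the series range (suppressing numerical
ripple) on the cyclically padded series; elastic-limit comparisons are
strict inequalities against 0.73 % (tensile) and 1.04 % (compressive).
Regressions (peak e1 vs gluteus-medius force/BW and vs hip JCF/BW) use
ordinary least squares over all 100 intervals, swing included.

## Problem sizes and determinism

Default analyses use the 4-mm linear-tet femur (≈37 k DOF), 100 intervals,
and single-threaded direct solves; the full sweep is a few minutes of
desk-scale computation, and the convergence ladder uses quadratic tets at
coarser pitches. Every stage is deterministic for a fixed subject
specification — there is no stochastic solver anywhere — so repeated runs
reproduce results bitwise; random subjects are drawn only through the
seeded `sample_spec`.

## Known limitations

Straight-line muscle paths understate wrapping moment arms at extreme
postures; the pelvis is fixed in space (each interval is a static
snapshot); the synthetic cortical shell is uniform in thickness, unlike
real femora; the constructive femur has a vertical shaft (no anatomical
bow or oblique run), so absolute strain magnitudes should be read as
order-of-magnitude physiological rather than subject-predictive; and
two-way coupling (strain-adaptive remodelling feeding back into the body
model) is out of scope.
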