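# Methods

`ecgforge` simulates the body-surface ECG of the QRS complex on labeled voxel
torso phantoms and quantifies how robust a bipolar chest lead is to geometric
uncertainty — body habitus, heart size and orientation, and electrode
misalignment. This note documents the model, its assumptions, the tunable
parameters, and the numerical and design choices.

## Volume-conductor model (SPFD)

At ECG frequencies (~1 Hz) the displacement current is negligible and the
potential is an instantaneous function of the source, so the torso is a
quasi-static volume conductor:

    div(sigma grad phi) = -div J     inside the body,
    (sigma grad phi) . n = 0         on the body surface.

The scalar-potential finite-difference (SPFD) discretization places unknowns
on voxel vertices. The conductance of the edge joining two adjacent nodes is
the arithmetic mean of the conductivities of the (up to four) voxels sharing
that edge, times edge cross-section over edge length; voxels outside the grid
count as air. Kirchhoff's current law at every node yields a symmetric,
singular M-matrix whose rows are exactly zero on air-only nodes — the
insulating (pure-Neumann) boundary emerges from zero-conductance air edges
rather than from explicit boundary rows. A current dipole enters as an
equal-and-opposite nodal injection pair (+I/−I); the quasi-static reduction
makes the solve real-valued.

Solvers:

* **multigrid_preconditioned** (default): conjugate gradients preconditioned
  by one geometric V-cycle. The hierarchy is Galerkin-coarsened through
  trilinear prolongation on the full rectangular node grid (6 levels by
  default, capped by grid size), smoothed with damped Jacobi (omega 0.7, two
  pre/post sweeps), coarsest level factorized directly. CG was chosen as the
  outer iteration because it requires — and the symmetric V(2,2)-Jacobi cycle
  provides — a symmetric positive preconditioner; a stationary SOR outer
  iteration wrapped around a multigrid preconditioner has no such guarantee.
* **direct**: sparse LU, cached per system so one factorization serves every
  dipole of a sequence.
* **sor**: plain successive over-relaxation (default relaxation factor 1.8,
  configurable); provided for reference, practical down to relative residuals
  of roughly 1e-7.

Singularity handling: air nodes receive decoupled identity rows and one body
node a small diagonal penalty (1e-6 of the mean diagonal). This is equivalent
to removing the air rows and grounding the Neumann nullspace; the penalty is
small enough not to contaminate the physical residual, and the remaining slow
gauge mode is irrelevant because the gauge is re-fixed after the solve:
potentials get zero mean over body-surface nodes, and air nodes are pinned to
exactly zero. All bipolar (two-electrode) quantities are gauge-invariant.
Convergence is measured as the relative residual of the pure Neumann operator
(default tolerance 1e-6).

Accuracy: against the infinite-medium closed form p cos(theta)/(4 pi sigma
r^2), a unit dipole centred in a homogeneous 64^3 block agrees to a per-shell
median of under 5% for shell radii of 5–10 voxels. Beyond that the *closed
form itself* drifts from the true solution of the insulated box: Neumann
face images contribute roughly +2 (r/R)^3 per image pair, measured +6% at r =
12 voxels (R = 32) — while multigrid and direct solutions of the same
discrete system agree to 1e-11. The analytic comparison is therefore made at
mid-range radii where the oracle is valid to better than the tolerance.

## Synthetic torso phantom

The study phantom is synthetic: a stacked-superellipse torso (exponent 2.5,
half-axes 210 x 147 mm, 400 mm tall section) with concentric skin (4 mm), fat
(12 mm) and muscle shells, a generic-muscle interior, two lateral lung
ellipsoids, an optional ribcage, and a heart ellipsoid (axes 55/50/60 mm)
with a 12 mm myocardial shell around a blood pool, centred 30 mm left of the
midline and 35 mm anterior. Its realism target is topological — layer order,
heart-between-lungs mediastinum, tissue set — not anatomical; individual
organ shape and chamber anatomy are out of scope. The default voxel size is
4 mm; demo-scale runs use `coarse_geometry(8.0)`, which inflates layer
thicknesses to stay at least one voxel thick. Grid origins are snapped to the
voxel lattice so that all morphs of one study share a single world-space node
grid; without this, the conduction path would snap to different node chains
in different members and inject purely numerical waveform variability.

Conductivities are a static low-frequency table (S/m): skin 0.1, fat 0.04,
muscle 0.2, bone 0.02, lung 0.1, myocardium 0.1, blood 0.7, air 0. A single
table suffices at ~1 Hz; no dispersion model is evaluated.

Body-mass index: mass is the non-air voxel volume times a uniform density of
1.05 g/cm^3. Because the phantom is a torso section, whole-body mass is
defined as torso mass divided by a fixed torso-mass fraction of 0.5, and BMI
uses a fixed standing height of 1.752 m. These constants only serve to give
the physique morph a meaningful target scale.

### Morphs

* **Physique** (`morph_physique`): the torso cross-section semi-axes are
  scaled in x–y (height unchanged) and the fat-layer thickness with them
  (proportional to the squared scale, floored at one voxel), organs fixed in
  place, until the computed BMI matches the target within 2% (bracketing walk
  plus Brent root-finding on the generator parameters carried in the volume's
  metadata). Heart volume is conserved up to re-voxelization (well within the
  ±10% requirement). Targets: 17.2, 23.2, 28.5, 34.2 kg/m^2.
* **Heart size / orientation** (`morph_heart`): a uniform volumetric scaling
  (90–110% of the original volume; linear factor is the cube root) or a
  rotation about the vertical axis through the heart centre (−8 to +8
  degrees). For generator phantoms the analytically known heart surface is
  re-voxelized under the composed affine, which tracks sub-voxel boundary
  motion exactly while keeping crisp integer labels. (Nearest-neighbour label
  resampling cannot do this: a 110% volumetric scale moves the surface only
  ~1.7 mm, less than half a 4 mm voxel, and changes nothing.) Volumes without
  generator metadata fall back to signed-distance label resampling, with that
  half-voxel limitation documented. Voxels the heart vacates are refilled
  with lung tissue; total body voxel count is conserved exactly.

## Cardiac source model

Only ventricular depolarization (the QRS) is modelled. A single current
dipole marches along the conduction system in five segments — A–V node to
His bundle, His to bundle branches, the branches, then left and right
Purkinje trees activated in parallel from the trunk's end — in nominal 2 mm
steps snapped to voxel vertices (zero-length steps merged, so the realized
dipole length l_dn grows to about one voxel on coarse grids). Conduction
velocities: 1.25 m/s in the His/branch segments, 3.25 m/s in the Purkinje
fibers. Activation times accumulate step length over segment velocity;
parallel branches restart the clock at the trunk's completion time.

Because the injection current is fixed while l_dn varies, each dipole's
potential map is rescaled by l_mean / l_dn (l_mean is the mean realized
length of its segment), restoring a uniform effective moment. The default
moment is 2e-5 A·m (20 mA·mm), a realistic effective magnitude for the
ventricular activation wavefront that produces millivolt-scale surface ECG;
every robustness metric except the raw amplitude is invariant to it.

The default path descends along a frontal-plane cardiac axis tilted about 30
degrees from vertical toward the subject's left — the normal electrical axis.
This matters: the diagonal bipolar pairs are oriented along that axis by
design, and with a (non-physiological) vertical trunk the amplitude maximum
would sit off the closest-pair position. Heart-size and orientation scenarios
transform the path with the same affine as the heart, so dipoles stay inside
the morphed myocardium.

## Leads and waveform assembly

A 7 x 10 electrode lattice (row pitch 45 mm, column pitch 35 mm, rows top to
bottom, columns subject-right to left) is projected along −y onto the
anterior skin, centred on the heart height. Diagonal bipolar pairs — upper
electrode at row r, column c for r = 2–6, c = 3–9; lower at (r+1, c+1) —
give 35 pairs roughly 6 cm apart. Misalignment displaces exactly one
electrode of a pair by 10 or 20 mm along one of eight 45-degree directions in
the chest tangent plane and re-projects it to the skin: 2 targets x 8
directions = 16 variants per pair per displacement.

Each dipole is solved once per phantom (the field is electrode-independent);
the cached surface potentials serve all 35 pairs and all misalignment
variants. A lead's waveform is the sequence of corrected bipolar samples
b_i = phi'_i(upper) − phi'_i(lower) at activation times t_i, linearly
interpolated onto a uniform grid (1 ms default) spanning [0, t_n], with the
two Purkinje chains interpolated separately and summed where they overlap in
time. No action-potential kernel is convolved onto the samples; the dominant-
frequency argument enters only through the quasi-static premise. QRS width is
t_n − t_1.

## Robustness metrics

* **SA** = |V_max − V_min| of the waveform.
* **DTW**: classical unconstrained dynamic-time-warping dissimilarity with
  absolute-difference cost, steps {(1,0),(0,1),(1,1)}, full boundary
  alignment, unweighted sum over the warping path; backtracking ties prefer
  the diagonal, then the vertical step. No window or step weighting.
* **Normalized DTW**: DTW after min–max normalization
  V' = (V − V_min)/|V_max − V_min| of each signal; a shape-only
  dissimilarity, invariant to independent positive affine transforms.
* **Geometry**: d is the mean distance from an electrode to the conduction-
  path dipole positions; theta is the angle between the rays to the uppermost
  and lowermost myocardial points *as seen from the electrode*, computed as
  the span of elevation angles over myocardial voxel directions. For a sphere
  of radius R at distance D this is the visual extent 2 asin(R/D); rays to
  the literal top/bottom voxels would under-read it (2 atan(R/D)), because
  the silhouette extremes are tangent points. A true steradian solid angle
  (convex-hull triangle summation) is available as an optional metric.
  Pair-level d and theta are the mean over the two electrodes.

## Evaluation design

Factors and comparison counts: physique N=4 (6 unordered pairs), heart size
N=7 (21), heart orientation N=7 (21) — 48 individual-difference comparison
patterns; misalignment contributes 16 reference-vs-variant patterns per lead
pair per displacement. With 35 pairs the pooled individual-difference
evaluation spans 35 x 48 = 1680 DTW/normalized-DTW comparisons. Per pair and
factor the summary reports mean SA, mean DTW, mean normalized DTW and the
mean absolute differences |delta d| and |delta theta| over the same
comparisons.

**Regression**: each comparison pattern is one observation (48 rows —
misalignment factors are excluded from the pooled fit), with DTW and
normalized DTW regressed on standardized delta-d and delta-theta by ordinary
least squares. VIF = 1/(1 − R_j^2) screens collinearity (warning attached at
VIF ≥ 10, fit still returned). Contribution rates default to squared
standardized coefficients normalized to 100%; an LMG (average over entry
orderings) decomposition is available and results are labelled with the
method. A per-pair pooling mode (35 x 48 rows) exists as an option.

**Quality map**: per factor, mean SA and mean normalized DTW are divided by
their maxima over the 35 pairs; the waveform-quality factor of a pair is the
arithmetic mean over factors of (SA_norm − nDTW_norm), and the recommended
region is the set of pairs at or above the 80th percentile (ties included).
The cross-factor combination rule (arithmetic mean) is this package's choice.

## Problem sizes and verification scope

The demo scale used throughout the examples, tests and the acceptance script
is the 8 mm torso (~120k voxels, ~134k nodes; a dipole solve takes well under
a second with the multigrid-preconditioned solver) with the full five-factor
design, plus a 64^3 block for the analytic dipole oracle and a layered 30^3
volume for the solver-equivalence check. At 8 mm the heart-size and
orientation morphs produce small but resolvable waveform differences; finer
grids sharpen the per-factor contrasts but do not change the structural
counts or the qualitative mechanisms.

What the synthetic phantom does and does not show: passing tests demonstrate
the solver's correctness, the metric definitions, the design counts and the
geometric mechanisms (amplitude falls with heart–electrode distance; on a
homogeneous torso the amplitude-maximal pair is the distance-minimal pair —
with the heterogeneous table the low-conductivity lungs deflect the maximum
about two columns laterally). They do not certify anatomical accuracy,
absolute amplitudes for a given subject, or lead-specific clinical values:
organ shapes, chamber anatomy and tissue dispersion are deliberately not
modelled.

## Known limitations

* Anatomical realism is topological only; no age/sex/ethnicity chamber
  modelling.
* Nearest-node electrode sampling quantizes electrode positions to the voxel
  grid; sub-voxel misalignment displacement is partially absorbed at coarse
  resolutions.
* The SOR method stagnates near relative residuals of ~1e-7 (gauge-mode
  floor); use multigrid-CG or the direct solver for tighter tolerances.
* P and T waves, repolarization, ionic membrane dynamics and capacitive
  tissue effects are out of scope.
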