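# Methods

This note documents the models, algorithms, parameters, and numerical
choices behind `gridfit`, and what the synthetic validation protocol does
and does not establish.

## Problem setting

Intracranial EEG electrodes (subdural grids and strips, penetrating depth
arrays) are localized from the post-implantation CT, where each metal
contact produces a high-intensity artifact blob. Two obstacles stand
between the thresholded CT and usable coordinates:

1. **Localization.** Artifact clouds are noisy, contacts may merge at low
   SNR, and hardware from other arrays (overlapping contacts, cables) may
   contaminate the selection. We localize all contacts of an array
   *simultaneously* by fitting a flexible spring-mesh model of the array to
   the voxel cloud, rather than segmenting contacts one by one.
2. **Brain shift.** The brain deforms after implantation (routinely several
   mm, up to 10–20 mm), so CT-space coordinates of subdural arrays sit
   below the pre-implantation MRI cortex. We project them back to the
   smooth cortical envelope (SCE) under smoothness and deformation
   constraints, and translate co-implanted depth electrodes by the
   resulting displacement field.

## Array models

An array is modeled as structural points `m` (the contacts `e` are a
subset) joined by springs between first (orthogonally adjacent), second
(two steps apart), and diagonal neighbors:

* **Grids** — an `n_rows x n_cols` lattice at the inter-electrode distance
  D; every point is a contact; first + second + diagonal springs.
* **Strips** — a lattice at D/2 pitch whose narrow dimension is extended by
  D/2 on each side; contacts are the central points at D spacing. The
  extra points give the thin strip a bending structure that the contact
  chain alone lacks.
* **Depths** — the contact chain at spacing D with first and second
  springs (no diagonals; chains cannot shear).
* **3D slabs** — for the final grid/strip fit, a second structural layer is
  stacked at the array thickness T along the local surface normal, with
  first and diagonal springs within and across layers, and one rectangular
  cuboid per lattice cell whose volume is conserved during fitting
  (resisting collapse and twist).

Spring weights α per neighbor class default to 1.0 (first), 0.5 (second),
0.5 (diagonal): first neighbors carry the primary spacing constraint,
longer links contribute shear/bending stiffness at half weight. T defaults
to 0.5·D clamped to [0.5 mm, 2.5 mm] — small relative to D so the slab
controls bending without dominating the in-plane mesh. Both are
configurable; results are insensitive to factor-two changes in either.

Rest lengths `d0` of the 2D models are the *manufactured* geometry (the
canonical lattice at D or D/2 pitch), so the coarse fit measures
deformation against the array as built.  The 3D slab is *created from* the
coarse-fit solution, and its rest lengths and cuboid volumes are recorded
from that construction-time (curved) configuration: the refinement then
preserves the curvature the coarse fit found instead of fighting it (a
flat rest state would force curved slabs to flatten, because a curved
cell's volume exceeds its flat counterpart's by several percent).  The
translation reference `m0` is wherever the model was placed (the initial
estimate for step 1, the extruded coarse fit for step 2).

## The fitting cost

With voxels `v_n`, normalized intensities `w_n` (W = Σw), and Gaussian
width σ:

    E_Fit = kTrans·ETrans + kDef·EDef − kCorr·ECorr

    ETrans = (1/NMod) Σ_j ‖m0_j − m_j‖²                      [mm²]
    EDef   = (1/NConn) Σ_(j,k) α_jk ((d0_jk − d_jk)/d0_jk)²   [—]
    ECorr  = (1/(NMod·W·σ·√2π)) Σ_n Σ_j w_n·u_j·exp(−‖v_n−e_j‖²/2σ²)

`u_j` is each contact's share of spring connections normalized to the
maximum — it boosts the Gaussian attraction of interior contacts, which
the deformation term grips harder than border ones. ECorr is normalized by
W, so rescaling all intensities changes nothing.

### Two minimization steps

* **Step 1** (coarse): 2D model, σ = D, contacts constrained onto a smooth
  approximation of the cloud — a surface z = f_surf(x, y) for grids and
  strips, a cubic line y = f_lin(x) for depths — with tolerance ε = 1 mm.
  We enforce the constraint by *substitution* (the constrained coordinate
  is eliminated), which is always feasible and turns the problem into
  smooth unconstrained minimization (L-BFGS with analytic gradients).
  Termination: |ΔE_Fit| < D·10⁻².
* **Step 2** (fine): 3D slab (grids/strips) or 2D chain (depths), σ = D/4,
  free of the surface, under hard bounds: relative deformation of *every*
  point pair below 10% (springs/neighbors) or 25% (all other pairs),
  cuboid volumes conserved within ε = 0.01, and optional user-fixed
  contacts pinned exactly (by variable elimination, after checking the
  fixed coordinates respect the bounds themselves). Termination:
  |ΔE_Fit| < D·10⁻⁶.

Step 2 solves unconstrained first; if that optimum satisfies every bound —
the common case, because EDef already keeps strains far below 10% — it *is*
the constrained optimum. Otherwise quadratic penalties on all violating
pairs (margin 0.98·δ inside the true bound) are ramped over four orders of
magnitude, followed, if needed, by a pure feasibility-restoration pass.
Feasibility of the returned solution is asserted post hoc in every path
(with 10⁻⁶ slack for constraints active exactly on the bound), never
trusted from the optimizer.

### Supporting estimates

* **PCA alignment.** Axes are ordered by decreasing variance; each axis
  sign is fixed so its largest-magnitude loading is positive and the
  rotation is proper. This makes results bit-reproducible; clouds whose
  second singular value is < 10⁻⁴ of the first are flagged collinear
  (fatal for grids, expected for straight depths).
* **Surface smoother.** A LOESS-style locally weighted quadratic
  regression: at each node of a 24×24 grid over the cloud's footprint, the
  `span` fraction of nearest voxels (default max(0.25, 30/NVox)) is fit
  with tricube weights; the height field is then interpolated by a bicubic
  spline, giving fast smooth evaluation and exact derivatives inside the
  optimizer. Queries outside the footprint clamp to the box edge.
* **Initial grid estimate.** Voxels are projected to the PC1–PC2 plane and
  the convex hull is iteratively trimmed (removing the flattest vertex).
  Corner candidates are the angle-trimmed 4 vertices — exact on clean
  footprints — plus, because protruding hardware can masquerade as a
  corner, the cyclic 4-subsets of the 10 most corner-like vertices that
  best fit the nominal (NCols−1)D × (NRows−1)D rectangle (after fitting a
  shared foreshortening scale, since curvature shrinks the projection).
  The candidate whose interpolated lattice collects the most smoothed
  artifact intensity wins: contact blobs are bright and discrete, so a
  lattice on the true array outscores one dragged toward clutter.
  Interior contacts are bilinearly interpolated between the winning
  corners and lifted onto f_surf.
* **Initial depth/strip estimate.** The cubic line fit is made robust to
  off-curve clutter: when the residual scale exceeds what a single
  artifact chain can produce (0.6 mm MAD), a deterministic RANSAC
  consensus cubic replaces it and only its inlier voxels define the
  chain extent. Contacts are spread uniformly along the curve between
  those extremes; if the on-curve extent exceeds the chain length
  (collinear clutter, e.g. a cable running off a strip's end), a matched
  filter picks the offset whose NElec D-spaced positions collect the
  most artifact intensity — blobs are bright and discrete, cables dim
  and uniform.
* **Corrupted-footprint fallback for grids.** A rigid-pose matched filter
  (lattice orientation in 3-degree steps x centers on a 2 mm grid, scored
  on a Gaussian-smoothed intensity image of the projected cloud, locally
  refined) replaces the hull corners only when it collects at least 10%
  more intensity than the best hull candidate: on clean footprints the
  hull estimate follows the draped curvature and scores within ~5% of any
  rigid lattice, while corners grabbed by clutter leave 20-100% of the
  artifact mass uncovered.

### Calibration of kCorr

kTrans = 1 and kDef = 200 are fixed by calibration: kDef sets how much
the mesh resists deformation, and localization is flat across a broad
region of its value. kTrans controls a robustness trade-off: lowering it
improves nominal accuracy slightly (the translation term anchors the
solution to the initialization, bias included) but removes the anchor that
keeps the fit stable when the attraction weight is badly mis-set, which is
exactly the robustness the method advertises; kTrans = 1 keeps an
order-of-magnitude kCorr perturbation at a ~1-point accuracy cost. kCorr — the only scale-sensitive
weight, because ECorr's normalization depends on geometry and cloud size —
is calibrated per (array type, overlap) on simulated suites: candidates
{3·10², 10³, 3·10³, 10⁴} are evaluated by median normalized error and ties
break toward the smaller value (weaker attraction deforms less). Shipped
defaults from this procedure: 3·10³ (grids, strips), 10³ (depths). For
unseen geometries the calibrated table interpolates over (log NElec, D)
within the same array type and overlap state, falling back to the nearest
calibrated point.

## Synthetic validation protocol

The simulator emulates the observable the fitter consumes — thresholded
CT artifact clouds with ground truth:

* **Phantoms and placement.** Grids/strips are draped on spheres of radius
  50–80 mm (the range of cortical convexity curvatures), by an
  azimuthal-equidistant initial map plus an on-sphere spring relaxation
  that leaves first-neighbor strain < 0.5% (chains are placed exactly along
  great circles); depth arrays follow straight or curved trajectories
  (curvature 0.002–0.006 mm⁻¹, i.e. bending radii ~170–500 mm) with exact
  chord spacing D.
* **Artifacts.** Each contact becomes the ball of 0.5 mm lattice voxels
  within the contact radius — 1.0 mm for grid/strip discs, 0.8 mm for
  depth cylinders — with a Gaussian intensity profile (scale radius/2)
  mimicking the bright metal core and dimmer halo. At 3 mm pitch and high
  noise, neighboring depth artifacts begin to merge, reproducing the low-SNR
  difficulty of high-density arrays.
* **Noise.** Each voxel moves in a uniformly random direction by
  |N(0, σ)| mm, σ ∈ {0.1, 0.2, 0.4} for the low/medium/high levels (high ≈
  one voxel at CT resolution).
* **Clutter.** Overlap scenarios add a foreign contact pair hovering 2 mm
  above a random spot of the array (70% of cases) or a cable-like voxel
  tube crossing it (30%); ground truth never includes distractors.  The
  clutter is clipped at 1.5 D from the nearest contact, because the
  operational input is the *user-selected* voxel cloud and coarse brush
  selections exclude hardware running far off the array.  Depth scenarios
  vary trajectory curvature instead.

The validation grid spans grid 4×8 @ D = 10 mm, strip 1×6 @ 5 mm, depth
1×8 @ 3 mm — three array families, three IEDs, three noise levels, clutter
on/off — with 10 replicates per condition (20 for the noise-monotonicity
check, 5 for noise-free recovery). These sizes were chosen so the full
protocol, including the order-of-magnitude kCorr perturbations, runs on a
single CPU in minutes while every condition retains enough arrays for a
stable median.

**Noise-free recovery.** With noise off, the median contact error is
1-1.5% of D for grids and below 1% for strips and depths; the *worst*
contact of a 4x8 grid draped on the strongest-curvature phantoms reaches
4-5% of D (about 0.5 mm), against a generator floor of 0.4%.  The residual is
a curvature-dependent bias of the two-step design itself: the sigma = D
coarse step pulls edge contacts slightly toward the array's mass center
(asymmetric Gaussian tails), and the refinement's rest lengths, built
from that configuration, lock part of it in.  It shrinks with gentler
curvature and does not grow with noise.

**What passing does and does not show.** The protocol exercises exactly the
failure modes the fitter is designed for — noise, merging artifacts,
missing information, distractors, curvature — under a known ground truth,
and its accuracy definitions (below) are the standard ones. It does *not*
emulate CT↔MRI co-registration error, intensity inhomogeneity or beam
hardening, anatomically realistic envelopes, or skull/vasculature clutter;
accuracy numbers here bound the algorithmic error, not the end-to-end
clinical error.

## Evaluation metrics

Per array, with truth `eSim` and fit `eFit`: d_loc_med = median_j
‖eSim_j − eFit_j‖/D and d_loc_max the maximum. Batch accuracy = 1 −
median(d_loc_med) over arrays, after excluding (single pass) arrays whose
d_loc_med exceeds the batch median by 5 standard deviations. Accuracy
converts to millimetres as (1 − accuracy)·D.

An unlabeled voxel cloud cannot distinguish an array from its mirror image
or 180°-rotation, so evaluation resolves the array's orientation
symmetries (8 for square grids, 4 for rectangles, 2 for chains) by
relabeling — never moving — the fitted contacts before scoring.

Diagnostics: IED MAD (mean absolute deviation of first-neighbor
distances — spatial regularity), projection distance dProj = ‖e0−e‖ /
distance-to-brain-center (the brain center defaults to the SCE vertex
centroid; any reference point can be passed), local deformation s_j = mean
first-neighbor distance / D, estimated high-frequency-activity score
−ln(distance-to-pial + 0.5 mm) (used only for ranking, so log base and
floor are benign), and probabilistic anatomical labels as voxel-label
fractions within a 3 mm sphere.

## Brain-shift compensation

**Envelope.** The pial surface is rasterized at 2 mm, filled, and
morphologically closed with a 50 mm spherical element implemented by two
Euclidean distance transforms; the erosion isosurface is extracted by
marching cubes directly on the distance field at level 50 mm (sub-voxel
smooth), lightly Taubin-smoothed, and returned watertight. Closing bridges
sulci narrower than the element while preserving the convex outline.

**Projection cost.**

    EProj = kTrans·ETrans + kDef·EDef + (kAnch/NAnch) Σ_u EAnch_u + kRough·ERough
    s.t. dist(e_j, Σ) < ε = 0.1 mm for every contact

with kTrans = 1, kDef = kAnch = kRough = 100 (combined method) or
kTrans = 1, kDef = 1000, anchors/roughness off (Springs baseline). Here the
spring rest lengths are the *input* (CT-space) distances — the deformation
term measures expansion between the initial and final projection states,
not against the manufactured lattice. EAnch is the mean squared distance
to an anchor set: per-contact orthogonal projections along the local
grid-plane normal (plane fit to the contact + up to 4 lattice neighbors;
grids only) and along the averaged envelope vertex normal within 15 mm
(any array; radius doubled once if empty, nearest-vertex fallback,
flagged). Anchors are computed once from the input coordinates and treated
as fixed data. ERough is the mean squared discrete Laplacian (nine-point
stencil [[1,1,1],[1,−8,1],[1,1,1]], config-exposed) of the deformation
fields G = D0 − D built from the horizontal/vertical inter-electrode
distance matrices; strips and 2–3-row grids use the 1D stencil [1,−2,1]
along the long axis. Uniform expansion has zero Laplacian — only spatially
*inhomogeneous* deformation is penalized.

The on-surface constraint is handled by a quadratic penalty on the
distance to the envelope (exact gradient via closest points) ramped over
three magnitudes, then snapping the final iterate to the nearest surface
point when within 2ε (else an error); every projector's output is asserted
to be within ε of the envelope per contact. Mesh queries (closest point,
ray casting, containment) use a k-d tree over face centroids with exact
point–triangle tests and a vectorized Möller–Trumbore intersector.

**Depth correction.** Depth contacts inherit a weighted average of the
grid/strip translation field t_k with Gaussian weights in distance
(σ_R = 5 mm, normalization) and translation magnitude regularization
(σ_D = 30 mm); contacts with vanishing total weight stay put and are
flagged.

### Desk-scale behavior of the projection comparisons

Two qualitative patterns reported for these methods on patient data change
form on synthetic phantoms, for geometric reasons worth recording:

* With the stated weights, the combined method drives ERough to numerical
  zero (~10⁻⁵) on phantoms: synthetic anchor fields are smoothable at
  negligible anchor cost, while the Springs baseline retains small
  incidental roughness (~10⁻³) from envelope faceting. The robust ordering
  on phantoms is therefore *both spring-based methods an order of magnitude
  smoother than the orthogonal projections*, and the combined method never
  rougher than its roughest anchor source — which is what the test suite
  asserts. A strict Springs ≤ combined ordering is a real-data phenomenon
  (noisy, non-smoothable anchors) that synthetic anchors cannot reproduce.
* On a convex envelope *any* outward projection expands contact spacing,
  so even the Springs baseline shows a positive local-deformation vs
  projection-distance slope on phantoms — the smallest of the four
  methods, which is the relation the tests assert. A slope near zero for
  Springs requires the small-shift, irregular-envelope regime of real
  implantations.

## Determinism and degenerate inputs

All randomness flows through explicit seeds (scenario seeds derive from a
base seed via a SeedSequence spawn tree); fitting itself is deterministic,
so identical inputs give bit-identical outputs. Clouds sparser than the
contact count proceed with a warning (the model supplies the missing
structure); clouds collinear for a grid fit, degenerate footprints,
rank-deficient line fits, empty thresholds, and infeasible fixed
coordinates raise typed errors naming the failing stage. Hexahedron
volumes use a fixed 6-tetrahedron split around the 0–6 diagonal so the
volume of a deformed cell is well defined and smooth.

## Known limitations

* Only rectangular lattices and chains; no L-shaped or perforated arrays.
* Each array is fitted independently; voxel-to-array assignment is the
  user's selection step.
* The simulator's spherical phantoms under-represent sulcal anatomy;
  envelope-dependent conclusions (projection comparisons) are qualitative.
* kCorr calibration transfers across geometries by interpolation; exotic
  geometries far outside the calibrated range should be recalibrated.
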