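# Methods

This note records the models behind each stage, the defaults that matter,
the numerical choices, and what the synthetic validation does and does not
establish.

## Problem setting

In neonates the cortex is 1–2 mm thick while voxels are 0.6–1 mm, so a
sulcus whose banks are separated by a fraction of a voxel of CSF contains
no pure CSF voxel: segmentations show the banks fused, and the GM/CSF
boundary inside the fold is unobservable. T1w contrast compounds this: GM
is brightest, WM is dark and close to CSF, and contrast varies regionally
with maturation. The package therefore (a) guarantees surface topology by
construction rather than relying on segmentation quality, (b) hypothesizes
the missing intra-sulcal boundary geometrically, and (c) lets the target
edge contrast vary across the surface during refinement.

## Digital topology

All voxel-level topology uses the complementary connectivity pairs: the
object 26-connected with 6-connected background for skeletonization, and
the dual 6/26 pair for pre-meshing topology correction. A voxel is simple
when both topological numbers of its 3×3×3 neighbourhood equal one; the
test is evaluated by integer flood fills over a 27-bit neighbourhood
encoding and is validated in the suite against a brute-force scipy
flood-fill oracle (10^5 random configurations plus exhaustive sparse
patterns). The nine-class voxel taxonomy (interior, isolated, border,
curve, curves, surface, surface-curve, surfaces, surfaces-curve) is the
standard C*/C̄ mapping; where class boundaries are debatable the oracle is
the source of truth.

The collapse before meshing runs under 6/26 because the marching-cubes
variant used (scikit-image's Lewiner tables) splits diagonal voxel
contacts — i.e. interprets the object as 6-connected. Matching pairs make
the meshed surface provably carry the corrected mask's topology; the
suite checks Euler characteristic 2 for masks with inserted handles and
cavities.

## WM surface

The enclosing ellipsoid is axis-aligned over the mask bounding box
(inflated by √3 so corners are covered, clipped to the volume). Erosion
removes simple points outside the mask ordered farthest-from-mask first
(Euclidean distance transform), which makes the collapse front advance
evenly. Marching cubes runs at level 0.5 on the binary corrected mask;
vertices are mapped to world mm through the NIfTI affine.

Coarsening is shortest-edge collapse to the midpoint, applied only when
the link condition holds (the endpoints share exactly two neighbours) and
no incident face flips; the default target is 30,000 vertices. Inflation
is iterative 1-ring Laplacian smoothing until every vertex's 1-ring mean
lies inside (a convexity proxy), followed by radial projection to the
unit sphere and tangential smoothing until no spherical triangle is
flipped (limits: 500 inflation and 200 untangling iterations).
Icosahedral resampling locates each subdivided-icosahedron vertex on the
spherical triangulation by exact closest-point search and pulls its
barycentric coordinates back to the original mesh; every subject at level
L shares the icosahedron's connectivity (level 6 = 81,920 triangles,
40,962 vertices per surface).

The spherical map presumes roughly convex, brain-like geometry. For the
box-like slab phantom the map's area distortion starves corners of
vertices, so slab-based validation uses the native marching-cubes mesh
(`resample_icosahedron=False`); closed phantoms exercise the spherical
path.

## CSF skeleton

The union of GM and CSF is restricted to the brain mask; the hull is the
border of the morphological closing (radius 2 voxels) of the brain mask
and is a skeleton member from the start (the gyral interface). Seeds for
the catchment basins are inner-boundary voxels whose WM-surface curvature
marks a fundus. Curvature comes from the implicit surface of the
Gaussian-smoothed characteristic function (σ = 1 mm): H from the standard
divergence formula (convex-outward positive; a digital ball of radius R
measures within 25% of 1/R), K from the Hessian adjugate quadratic form.
Default seeding is 'auto': the Gaussian-curvature rule (K > 0.05 mm⁻²
with H < 0, bowl-like fundi) falling back to strong concavity
(H < −0.15 mm⁻¹), which also catches extruded, cylinder-like fundi whose
K ≈ 0.

The watershed's rising water is realized as a priority queue keyed on
(water level, mean curvature): the level is the distance from the WM
boundary quantized to half a voxel, so fronts climbing opposite banks
advance in lock-step; within a level, flatter and concave voxels go
first. Removal requires simplicity (26/6) and spares hull, seeds, and
ridges. Ridges — the locus where floods from different banks meet — are
detected beforehand from the Euclidean feature transform: adjacent voxels
whose nearest-WM source points are separated by more than
max(2.5 voxels, 1.5 × flood depth) are fed by different banks; one voxel
per colliding pair (the deeper) is frozen, giving a one-voxel-thick
medial sheet. Detection is restricted to GM: where CSF voxels exist they
carry the boundary themselves. One-voxel sheets also survive without
freezing because piercing them would open a tunnel, which the
simple-point test forbids; the frozen ridge makes the sheet's position
exact rather than order-dependent. The mean-curvature eligibility
threshold is exposed but defaults to +∞: at voxel scale the eroding front
carries curvature of order 1 mm⁻¹ everywhere, and a finite default was
measured to stall erosion with thick residue; the ordering role the
threshold plays in the continuum formulation is already provided by the
level/curvature priority.

After erosion the remaining voxels are classified and deletable classes
pruned in simultaneous passes to a fixed point. The default deletable set
is {isolated, curve, curves}: under the oracle-consistent classification
the free rim of any bounded sheet is 'border', so deleting 'border' would
consume open sheets rim-inward; it remains user-selectable. The pipeline
protects hull/seed/ridge anchors during pruning.

Erosion audits (every N removals) confirm that the object's 26-connected
component count and Euler characteristic are constant throughout. On the
folded-slab phantom with invisible CSF, 100% of fundus-region skeleton
voxels lie within one voxel of the analytic inter-bank plane.

## Laplacian expansion

The 6-neighbour discrete Laplace equation is solved with Dirichlet
conditions 0 on WM and 1 on skeleton ∪ hull ∪ visible CSF (the latter
realizes "use the real boundary where it is observed"). Red-black SOR
with ω = 1.9 iterates to a maximal update below 1e-5; interior voxels
with no path to the outer boundary are excluded. The max-update residual
of an over-relaxed solver is not strictly monotone per sweep; it
decreases over 10-sweep windows and by five orders of magnitude overall.
Against the analytic radial harmonic between concentric shells the mean
error is 0.0195 potential units at 1 mm resolution, evaluated on interior
voxels more than one voxel from either Dirichlet set (the blocky
voxelized boundary dominates the adjacent layer).

Streamlines integrate the normalized trilinear gradient by midpoint RK2
with step 0.25 voxel until the potential reaches 1 − 0.02 or the point
enters the Dirichlet-1 set; for tracing, the value 1 is continued three
voxels past the boundary so the gradient never reverses inside the blocky
boundary shell. Zero-gradient pockets fall back to the vertex normal.
Streamlines exceeding 30 mm (no conducting path — e.g. the non-cortical
base of the open slab phantom) keep their starting position and are
flagged. Arrival radius on concentric shells is within 0.08 voxel of the
analytic outer boundary; the potential is nondecreasing along traces.

## Gradient refinement

Profiles are sampled every `search_step` mm within ±`search_distance`
along area-weighted vertex normals (defaults 0.5 / 5 mm; pial refinement
uses 0.25 / 1.5 mm), trilinearly interpolated, restricted to the brain
mask (samples outside are invalid — without this, at coarse steps the
GM→CSF and CSF→background edges of a thin CSF rim merge into one ramp
whose maximum is displaced), and blurred along the ray (σ = 1 sample).
The gradient noise floor is estimated from pooled second differences
(which vanish on plateaus and ramps); an edge must exceed twice that
floor.

Edge selection during deformation takes the *nearest* local maximum of
the score that is competitive (≥ 30% of the row's best) and sign-matching;
the score is the signed gradient (or |gradient| for `auto` polarity)
weighted by a Gaussian similarity between the sample intensity and the
vertex's target intensity. The target map is built at the start of each
resolution level from the detected edge intensities, diffused over the
mesh (10 conservative-Laplacian iterations), and held fixed within the
level — re-anchoring it every iteration lets the target chase the moving
surface into the background. Movement per iteration is the smoothed
offset field clipped at `step_size` (0.2 mm), half-stepped after the first
iteration to suppress half-sample oscillation; levels run coarse→fine
((5, 1), (3, 0.5), (1.5, 0.25) mm by default) and stop when the mean
displacement falls below 0.02 mm or grows three iterations in a row.

Properties measured on the noiseless shell: a mesh 2 mm inside the edge
converges to 0.001 mm mean radial error; with noise at 10% of the GM/CSF
contrast, 0.01 mm; both contrast polarities converge identically under
`auto`. Strict per-level monotonicity of the error can be broken by
~0.1 mm transients at intermediate resolutions; every level improves at
least six-fold on the start and the full schedule is best.

## Morphometry

Linked thickness uses the one-to-one correspondence created by the
expansion; nearest (exact point-to-triangle) and symmetric variants are
available. Surface smoothing is the symmetric graph-Laplacian step
v_i += (λ/d_max) Σ (v_j − v_i) with λ = 0.5, which conserves the mean
exactly on any mesh (plain 1-ring averaging does not, at valence-5
vertices) and equals 1-ring averaging on regular graphs. The iteration
count for a requested FWHM is 2(FWHM/2.355)² / (0.6 λ h̄²) with h̄ the
mean edge length; the 0.6 lattice constant was calibrated once against
the measured impulse spread on icospheres (empirical FWHM within 10% of
request for 6–15 mm). Sulcal depth is the distance to the brain-hull
surface — a proxy that is exact on closed, convex-hulled geometries and
saturates near the open faces of the slab phantom. Template selection is
the Pearson-correlation argmax over sulcal-depth maps with ties toward
the smaller (older-template) index; it is invariant to affine rescaling
of the input map.

## Phantoms: what they emulate, and what not

The generators define the validation conditions: 1 mm isotropic voxels,
2 mm cortex, neonatal intensity preset (CSF 40, GM 70, WM 48 a.u.),
partial volume by 2× supersampled box-averaging, optional Gaussian noise
(tests use 3 a.u. = 10% of the GM/CSF contrast), 2 mm visible CSF rim,
slit sulci 10 mm deep at 16 mm spacing with a 0.2 mm gap (invisible at
1 mm voxels). The folded slab uses slit-type sulci rather than sinusoidal
folds so the sulcal gap is exactly controllable and the inter-bank medial
surface is exactly the slit plane; the folded sphere uses sinusoidal
folds (amplitude 3 mm, wavelength 20 mm in tests — chosen so the 2 mm
normal offset of the inner surface remains an embedding, i.e. valleys
stay wider than twice the cortical thickness, otherwise constant-thickness
truth is geometrically impossible) to exercise closed-topology paths.
EDT-based labelling is corrected by half a supersampled cell for the
distance-to-centres vs distance-to-boundary bias.

Phantoms do not emulate bias fields, motion, anisotropic voxels,
within-tissue intensity gradients, or real gyral geometry. Passing tests
therefore establish the geometric and numerical correctness of the
machinery under controlled contrast and noise — not segmentation
robustness on clinical data, which depends on the upstream tissue
classifier that this package consumes as input.

## Problem sizes

The suite and the acceptance script run phantoms of 27–60³ voxels at
1 mm with icosahedron level 4 (5,120 triangles) and the slab chains on
native ~4–11 k-vertex meshes; level 6 (81,920 triangles) is exercised
structurally. These sizes were chosen so a full validation cycle
completes in a few minutes on a single CPU while every code path —
including the invisible-CSF regime — is covered.

## Known limitations

- The sphere map degrades on strongly non-convex or open objects (see WM
  surface above); hemisphere splitting uses a geometric midplane rather
  than a corpus-callosum segmentation.
- The slab phantom's open base produces flagged (zero-length) streamlines
  and a small number of mesh self-intersections at its sharp corners;
  both are confined to the non-cortical region and absent on closed
  phantoms.
- Skeleton placement inside wide, CSF-filled sulci is delegated to the
  CSF labels themselves; the medial-sheet hypothesis is only invoked
  where CSF is invisible.
- The depth-potential variant of sulcal depth is not implemented; the
  hull-distance proxy is the tested default.
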