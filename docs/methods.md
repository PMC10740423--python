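# Methods

`kneeforge` reimplements an automated pipeline for reconstructing the
proximal tibia and distal femur from knee CT, as used in preoperative
planning of total knee arthroplasty (TKA) with patient-specific
instruments (PSIs). This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic phantom does and
does not demonstrate.

## Pipeline model

The inference chain is

1. **Preprocessing** — raw scanner values are mapped to Hounsfield Units
   (HU) with the DICOM rescale slope/intercept, clipped to
   [−1024, 2500] HU (air to dense cortical bone), shifted to [0, 3524]
   and scaled to [0, 1]. Volumes are cropped to the labeled extent
   during training-set preparation. Two training-set geometries are
   supported: a fixed 192³ resample (lossy; trilinear for images,
   nearest-neighbour for labels) and overlapping fixed-size patches that
   preserve native resolution. Patch starts per axis are
   `round(i·(L−P)/(n−1))` with `n = ceil(L/P)`: the minimal number of
   patches with maximally even overlap and guaranteed coverage. Volumes
   smaller than the patch are symmetrically zero-padded and the padding
   stripped after stitching.
2. **Segmentation** — a 3-D convolutional network (below) classifies
   each voxel as background / tibia / femur, patch by patch. Per-patch
   class scores are softmax probabilities; overlapping patches are
   blended by the arithmetic mean (an unbiased tiling rule; a voxel
   covered once is copied exactly) and the argmax taken, ties to the
   lowest class id.
3. **Postprocessing** — per-class largest-connected-component filtering
   (26-connectivity) removes speckle false positives.
4. **Reconstruction** — marching cubes on the class indicator at
   iso-level 0.5, after padding with one background voxel so surfaces
   touching the volume border close. Vertices map to millimetres with
   the voxel-center convention `origin + index · spacing` (no half-voxel
   shift); this convention is what makes the voxelize/reconstruct round
   trip exact on interior voxels, and it is pinned by a test. Largest
   surface component retained; Taubin smoothing (λ = 0.5, ν = 0.53) is
   available but off by default because smoothing moves the surface away
   from the reference.

Per-stage wall times are recorded (preprocessing, segmentation,
postprocessing, per-bone reconstruction, overall) but never asserted —
they are hardware-dependent.

## Label generation: two algorithms

Training labels come from reference surface meshes (STL, mm).

**Slice-intersection + morphology (algorithm A).** For every axial
slice, mesh edges crossing the slice plane are intersected and the
crossing points rasterized (nearest pixel). If the point set forms one
closed 8-connected contour whose filling adds interior pixels, holes are
filled directly; otherwise the contour is repaired by dilation → closing
→ fill → erosion with an in-slice 3×3 structuring element (radii
configurable, default 1, erosion radius defaulting to the dilation
radius). The repair inflates boundaries by up to about one voxel and
**bridges narrow inter-bone gaps**, producing systematic
oversegmentation exactly where TKA planning is most sensitive (the
joint space).

**Exact voxelization (algorithm B).** A voxel is foreground iff its
center lies inside the watertight mesh. Containment is decided by
crossing parity along z-columns: each triangle deposits one crossing at
its plane's height in every column whose (y, x) sample falls inside the
triangle's axial projection; a center with an odd number of crossings
below it is inside. Column coordinates carry a ~1e-7-voxel jitter so
edges passing exactly through sample points are resolved consistently;
z-parallel facets deposit nothing (the ray grazes them). A column with
odd total parity indicates an open or self-intersecting surface and is
rejected with a diagnostic. No morphological operator touches the
result. An independent brute-force oracle (generalized winding number,
solid angles summed over all faces) verifies algorithm B exactly in the
tests; the two computations share no code path. Grids used in those
oracle comparisons carry an irrational sub-voxel origin offset because a
voxel center lying exactly on the surface has no well-defined side.

When two bones claim one voxel (possible only for defective inputs),
the class whose surface is nearest wins; ties go to the tibia. This is
a deterministic resolution rule, not an anatomical claim.

**Edge ground truth.** The edge decoder's target is the 1-voxel inner
morphological gradient: class mask minus its erosion by the 6-connected
ball (thickness configurable). It is the thinnest boundary layer that is
still a subset of the class foreground; volume-border voxels are not
marked because the out-of-volume side is not background. Edge maps are
per class, including a background channel, so the edge head mirrors the
segmentation head's channel layout.

## Networks

The edge-aware network (**CEL-UNet**) has a UNet encoder (two
convolutions of 3³ per level, per-channel instance standardization with
learned gain/bias, ReLU, 2× max pooling between levels) and **two
parallel decoders**: an edge decoder and a segmentation decoder, each
upsampling by nearest-neighbour doubling and concatenating the encoder
skip at its level. At every level the edge decoder's features are
additionally concatenated into the segmentation decoder's input
(edge → segmentation only, never the reverse) and fused by that level's
convolution block. Heads are 1×1×1 convolutions to the three classes.
The **baseline UNet** is the identical code path with the edge branch
disabled — so ablation identity (bit-for-bit equality at equal seed) is
a test, not a convention. Initialization is He-normal from per-section
seed streams (`numpy.random.SeedSequence.spawn`), which keeps the
encoder initialization identical between the two variants at equal seed.

Default desk scale: depth 4, base 16 channels, 32³ patches (about
2.2 M parameters); the full-scale configuration (depth 4, base 32,
160³ patches) is the same code. The implementation is a small
reverse-mode autodiff on numpy arrays (channel-last layout,
offset-sum convolutions: one GEMM per kernel offset), written for this
package; it is bit-reproducible for a fixed seed on one platform and is
verified against central finite differences in float64 for every
parameter tensor.

### Losses

* **Combined edge loss (CEL)**: `L = L_region + λ_edge · L_edge` with
  `L_region = (soft-Dice loss + cross-entropy)/2` on the segmentation
  head and `L_edge` the soft-Dice loss of the sigmoid edge head against
  the edge ground truth. Soft Dice uses the `(2Σpg+ε)/(Σp+Σg+ε)`
  form, ε = 1e-6. λ_edge defaults to 1. With λ_edge = 0 the loss is
  exactly the region term.
* **Distance cross-entropy (DCE)**: cross-entropy weighted by
  `w(v) = 1 + β·exp(−D(v)/τ)`, with `D` the Euclidean distance (voxels)
  to the nearest inter-class boundary of the target (6-neighbour
  definition, boundary voxels on both sides get D = 0). A uniform target
  has no boundary (D = ∞ convention, w ≡ 1). Defaults β = 5, τ = 3
  voxels.
* **Focal (FOC)**: `−(1−p_t)^γ log p_t`, γ = 2 by default; γ = 0 is
  plain cross-entropy exactly.

The exact decompositions and coefficients of the original combined and
distance losses are not fixed by our sources; the forms above are the
simplest constructions consistent with their names, and every
coefficient is exposed in `LossConfig`.

Training is Adam (lr 1e-3 default) on seeded mini-batches without
augmentation; an optional cosine decay (`lr_min`) and bone-weighted
patch sampling (`patch_dataset_from_volume`: weight ∝ bone fraction
plus a 0.05 floor) speed up desk-scale overfitting. Training patches
tile the *whole* volume, background-only patches included — otherwise
inference encounters pure-background patches whose per-channel
standardization statistics the network has never seen, which measurably
degrades whole-volume accuracy. Loss arithmetic follows the dtype of
its inputs (float64 targets give float64 losses), which is what makes
the γ=0 / β=0 identity checks meaningful at 1e-12.

## Surface metrics

Point-to-surface distance is the exact point-to-triangle minimum
(vertex, edge and face Voronoi regions all handled), accelerated by a
k-d tree over triangle centroids whose candidate radius is inflated by
the largest triangle circumradius — the accelerated result equals the
all-triangle brute force, asserted to 1e-9 in tests. Surface RMSE is
symmetric: area-uniform samples (default 4/mm², plus all vertices) are
drawn on both meshes, and the squared distances to the opposite surface
are combined area-weighted; using the same sampling seed on both sides
makes the value exactly swap-invariant. Hausdorff distance is the
maximum over both directed maxima, with the sampling density doubled
until the estimate moves < 1% (cap 4 doublings). Directed values are
also reported. Overlap metrics (Dice, Jaccard, precision, recall) come
from TP/FP/FN/TN counts; conventions for empty classes: both empty →
1.0 with a warning, exactly one empty → 0.0.

## PSI feasibility

Planning landmarks (named points grouped into contact areas A–C on the
tibia and D–E on the femur) are transferred to a predicted surface by
the minimal-distance criterion — the exact nearest surface point, not
the nearest vertex — and transfer distances are aggregated per area
(median, IQR). Resection planes are fitted to their four landmarks (two
frontal, two posterior) by total least squares (smallest principal
direction of the centered points; degenerate if the second singular
value vanishes). The angular deviation between reference and predicted
normals is projected onto the frontal (ML–CC) and sagittal (AP–CC)
anatomical planes: project both normals, normalize, take
`arccos |cosine|` — sign-insensitive by construction, 0–90°.
Anatomical axes default to the scanner frame (ML = x, AP = y, CC = z)
and are configurable for non-standard acquisitions. Projecting the
normals (rather than the rotation axis) matches how coronal/sagittal
alignment angles are reported clinically.

## The synthetic phantom

Real TKA datasets are proprietary, so every stage is exercised by a
seeded phantom: two bone-like solids built from signed-distance
primitives (spheres, capsules, capped cylinders; boolean union and
subtraction). The femur is two condylar spheres (r = 14 mm) joined by a
transverse bridge and shaft; the tibia is a plateau disk (r = 22 mm)
with two articular concavities, a shaft, a central intercondylar spine
(r = 6 mm), and seeded osteophyte bumps on the plateau rim. The
condyle centers are placed so the minimal clearance between the spine
and each condyle is **exactly** `joint_gap`; all other inter-body
clearances are ≥ 8 mm. Because the spine rises between the condyles,
axial slices through the joint contain cross-sections of both bones
separated in-plane by the gap — the configuration in which
morphology-based label generation bridges the joint space. The bundle
also provides the corridor mask (background voxels whose two surface
distances sum to at most `joint_gap` + 1 voxel), used to count
false-positive labels inside the joint space.

Ground truth is exact by construction: labels are the SDF sign at voxel
centers; meshes are marching cubes of the SDF on a refined grid
(default 2×; sphere-fixture meshes deviate < 0.001 mm from the analytic
surface in RMSE); landmarks are seed points projected to the mesh by
exact closest-point queries; cutting-plane landmark quadruples are
exactly coplanar. All geometry constants sit slightly off the voxel
lattice and its half/quarter subdivisions so no flat face or tangency
passes exactly through voxel centers or marching-cubes grid points —
exact-equality oracles are meaningless at boundary-degenerate
configurations. The CT is a three-level HU assignment (cortical shell
1200 HU over 2.5 mm, trabecular core 300 HU, soft tissue 50 HU —
typical clinical magnitudes), Gaussian-blurred (σ = 0.7 mm, a typical
scanner point-spread width) with additive Gaussian noise (σ = 20 HU).
Default grid: 96³ voxels at 1 mm; coarse tests use 48³ at 2 mm (same
geometry in mm).

**What the phantom does not show.** It is a geometric surrogate, not
anatomy: no statistical shape variability, no cartilage, no metal, no
field-of-view truncation, no scanner-specific artifacts. Passing the
phantom suite demonstrates that the pipeline's machinery is correct
(exact label generation, metric fidelity, learnability, end-to-end
plumbing), not that the network generalizes to clinical CT.

## Desk-scale experiments and problem sizes

Two seeded experiments run in the test suite and the acceptance script;
their sizes are chosen to keep a laptop-class single-core run
comfortable:

* **Overfit smoke**: depth 4 / base 16 / 32³-patch edge-aware network,
  one 96³ phantom, 250 Adam steps (batch 1, lr 5e-3 cosine-decayed to
  5e-4, bone-weighted sampling). This reaches voxel Dice ≥ 0.98 on both
  bones here; the pipeline's surfaces then sit within one voxel spacing
  of the phantom meshes in RMSE.
* **Edge-branch comparison**: depth 3 / base 8 networks on
  1-voxel-gap phantoms at 2 mm; the edge-aware network and a baseline
  UNet trained with the identical region loss (no edge supervision —
  the pure edge-branch ablation) get an equal budget of 150 steps on
  the same data (3 seeds) and are compared by false-positive rate
  inside the joint-gap corridor of 5 held-out phantoms, by median over
  seeds. The budget is set where both networks have reached their loss
  plateau: comparing half-trained networks measures optimization speed,
  not boundary behaviour.

These scales are the package's validation scale, not the scale of
clinical training, which requires hundreds of cases and GPU hardware.

## Known limitations

* The autodiff engine is single-threaded numpy; it is meant for
  correctness and desk-scale experiments, not production training.
* Algorithm A rasterizes intersection *points*; extremely coarse meshes
  can leave contour gaps larger than the default repair radii.
* DICOM reading assumes an axial series with uniform slice spacing and
  does not apply orientation matrices beyond slice ordering.
* Mesh self-intersection is detected only indirectly (odd crossing
  parity); a self-intersecting mesh whose parity stays even voxelizes
  without complaint.
* Empty-class metric conventions (1.0/0.0) are arbitrary at the
  margins; they are documented and tested rather than universal.
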