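# Methods

`orthotrack` implements a markerless, patient-specific pipeline for
real-time lung-tumor localization from a pair of orthogonal X-ray
projections: deformable augmentation of a planning 4D CT, synthesis of
digitally reconstructed radiographs (DRRs), 2D tumor segmentation with a
hybrid CNN-Transformer network, and regression of the two view masks to a
3D centroid. This note records the models, the parameters that matter,
the numerical choices, and what the bundled synthetic phantom does and
does not establish.

## Coordinate model

Voxel arrays are indexed `(ix, iy, iz)` with world axes fixed as
x = left-right (LR), y = anterior-posterior (AP), z = superior-inferior
(SI); all world units are millimetres. Grids are axis-aligned;
`world = origin + index * spacing`. The isocenter — the machine reference
point and origin of every reported tumor position — is the world position
of the grid center. Displacement fields are in mm and follow the
pull-back convention `warped(x) = source(x + phi(x))`; this single
convention is shared by registration, thin-plate-spline evaluation and
warping, so fields compose by simple voxelwise arithmetic.

## Synthetic 4D phantom

The phantom stands in for planning 4D CT studies (which are external
data): a body ellipsoid with rib-like bands, two lung ellipsoids, a
diaphragm dome, and a bright ellipsoidal tumor. Phase `k` of `n` places
the tumor at the end-exhale position plus a per-axis displacement
`A (1 - cos 2 pi k/n) / 2` — zero at end-exhale (phase 0, the
moving/reference image), maximal at end-inhale. Default amplitudes are
(LR, AP, SI) = (2, 3, 10) mm, the SI-dominant pattern typical of lower-lobe
lesions. The diaphragm dome rises and falls with the SI component, and a
seeded, smooth random "vessel" texture inside the lungs translates with
the same displacement. The texture is not decoration: piecewise-constant
lungs carry no intensity gradient away from boundaries, so no
intensity-driven registration could recover motion there; moving
parenchymal texture is exactly what makes real 4D CT registrable.
Per-phase i.i.d. noise (sigma 0.01 on a 0-0.6 intensity scale) is added
to intensities only — masks and ground-truth centroids stay exact, with
the rasterized tumor's center of mass tracking the analytic trajectory
to within half a voxel.

Presets: the default grid is 128 cube at 1 mm with a 15 mm tumor radius
(a "large" lesion; `small_tumor` uses 6 mm), and `tiny` is a 64 cube at
1 mm with an 8 mm tumor used for all CPU-scale studies and tests.

## Hybrid deformable augmentation

Training data are manufactured from the phase-0 volume and its tumor
mask:

1. **Inter-phase motion.** Phase 0 is registered to each other phase by
   multi-resolution demons registration (SimpleITK), giving dense fields
   `phi_i`. Random convex mixes `alpha phi_i + (1-alpha) phi_j`
   (`alpha` uniform in (0,1), `i != j` uniform over the nine fields)
   interpolate respiratory states between measured phases.
2. **Intra-phase variation.** A 3D thin-plate spline driven by N uniform
   random control points (N uniform in [20, 60]) inside the body region,
   each displaced in a uniform random direction by a uniform magnitude,
   models tumor/tissue changes within a phase.
3. **Hybrid fields.** `phi3 = w1 phi1 + w2 phi2` with `w1, w2` uniform in
   (0,1); fields combine by voxelwise vector *addition*, not composition
   — large-deformation diffeomorphism semantics are out of scope.

Each sample warps the volume (trilinear) and mask (nearest-neighbour) by
`phi3` and records the warped mask's center of mass as its exact
centroid label; samples whose tumor is pushed out of the grid are
redrawn (at most 10 times). One master seed spawns independent
substreams per sample, so datasets are bit-reproducible.

**Displacement range.** At full scale the control-point displacement
range is 0-30 mm, appropriate for a 350-450 mm thorax. The tiny preset
scales it to 8 mm (about one tumor radius): the intra-phase model is
meant to produce *small* shape variations, and 30 mm displacements on a
64 mm phantom would shred the anatomy rather than perturb it.

**Registration engine.** Fast symmetric-forces demons, three levels
(shrink 4/2/1, 100/80/50 iterations), with *update-field* smoothing
(sigma 2.5 voxels) rather than total-field smoothing: smoothing the
accumulated field each iteration progressively erases it on
piecewise-constant anatomy, while smoothing only the per-iteration
update (a fluid-like regularization) propagates displacement into flat
regions and converges. Images are pre-smoothed 1 mm at the finest level.
On the tiny phantom this recovers the known mean tumor displacement of
every phase pair to within 1 mm. A B-spline engine (mean-squares metric,
L-BFGS-B) is available behind the same contract.

**Thin-plate spline.** The regularized 3D TPS is solved in closed form:
kernel matrix `K_ij = phi(|p_i - p_j|)` with the 3D biharmonic radial
basis `phi(r) = -r` (the conditionally-positive-definite orientation —
the sign under which loading the kernel diagonal with `lambda` is the
classical smoothing spline), bordered by the affine block `[1 | p]`.
`lambda = 0` interpolates exactly; increasing `lambda` trades control
point fidelity for bending energy monotonically. The fit matches scipy's
`RBFInterpolator(kernel="linear", degree=1, smoothing=lambda)` to
machine precision, which the test suite uses as an independent oracle.
The bending energy integrates the squared second-order partials (three
pure and three mixed terms, each counted once) by central differences
over the interior, scaled by the voxel volume. `lambda` defaults to 0;
the augmentation never needs smoothing because the sampled
displacements are the deformation being simulated, not noisy data.

## DRR synthesis

A parallel-beam line integral: the detector at gantry angle `theta`
(measured in the axial plane from +y/AP toward +x/LR; beam direction
`(sin t, cos t, 0)`, detector u-axis `(cos t, -sin t, 0)`, v-axis +z)
integrates intensity along rays at a step of half the smallest voxel
spacing, with trilinear sampling. For a fixed (grid, geometry, angle)
the discretized integral is assembled once as a sparse matrix and
cached, making projection exactly linear, mass-conserving to within the
discretization, and fast for the hundreds of volumes the pipeline
projects. The default geometry is the orthogonal 45/135-degree pair on a
512x512 detector at 1x1 mm; the tiny preset uses 128x128 at 0.75 mm
(field of view 96 mm, covering the 64 mm phantom's axial diagonal).
Parallel beams were chosen because no source geometry is specified for
the reference results and parallel rays make the dual-view triangulation
exactly solvable; a cone-beam model is available behind the same
interface. Tumor silhouettes binarize the projected mask at > 0: any ray
that touches the tumor is foreground.

Test-time corruption maps an image affinely onto a display scale
(default [0, 255]), adds i.i.d. Gaussian noise of variance S^2, clips to
the scale and maps back; S^2 = 0 is bit-exact identity. An image with no
dynamic range is taken to be on the display scale already.

## Segmentation network

A TransUNet-style hybrid: a convolutional encoder (local features), a
Transformer bottleneck on the 1/16-resolution map (global context,
learned positional embeddings, pre-norm blocks), and a decoder with skip
connections at every scale down to the raw input, ending in a 1x1
convolution and sigmoid. The `full` preset follows the TransUNet design —
ResNet-50 stem plus first three bottleneck stages under a 12-layer,
12-head, 768-dim Transformer at 224x224. The `tiny` preset (3 stages of
8/16/32 channels, 2-layer 2-head 48-dim bottleneck, 128x128 input) is
the CPU-trainable configuration used in the bundled study.

Training minimizes `beta1 * Dice + beta2 * BCE` with beta = (0.6, 0.4)
and epsilon 1e-6, by SGD (lr 0.01, momentum 0.9, weight decay 1e-4,
batch 12). Inputs are z-score normalized per image; predictions are
thresholded at 0.5. The networks run on a small pure-numpy layer
toolkit written for this package (explicit backward passes,
finite-difference-checked in the tests); determinism is exact given the
seed because all arithmetic is plain numpy.

## 3D regression and the triangulation oracle

The regressor consumes the two view masks as a fixed-order 2-channel
stack. Each channel is area-resized (block averaging preserves
fractional occupancy, hence sub-pixel centroid information) and
normalized to unit mass — under unit-mass normalization the mask
centroid is an exactly linear functional of the input, so the network
starts within reach of the geometric solution and refines it with shape
information. The `full` preset is a ResNet-style backbone
(7x7 stride-2 stem, 3x3 stride-2 max pool, four residual stages, global
average pooling, 3-node head). The `tiny` preset keeps the 7x7 stem and
two residual stages but drops the stem pool (a strided linear path
preserves the fractional-mass signal) and flattens the final map instead
of averaging it: at low capacity, global pooling discards the spatial
information that sub-millimetre localization needs.

Training minimizes the mean squared 3D error (Adam, reduce-on-plateau).
The tiny schedule is lr 0.01 for 150 epochs with **consistent dual-view
translation augmentation**: each training pair is shifted by random
integer pixel offsets (independent in-plane offsets per view, one shared
vertical offset), which corresponds exactly to a unique 3D translation
of the tumor, and the label is moved by that translation. This matters
because hybrid weights `w1 in (0,1)` shrink inter-phase displacements,
leaving true trajectory extremes underrepresented; without the
augmentation the regressor regresses toward the mean at end-inhale
(errors of 1-2 mm, strongly seed-dependent), with it the trajectory
error is stable near 0.3 mm across seeds.

`triangulate_centroid` is a learning-free geometric companion, not part
of the learned method: for parallel-beam views 90 degrees apart, the two
in-plane mask-centroid coordinates give a 2x2 linear system for (x, y)
and the vertical centroids average to z. It serves as an exact oracle
for tests and as a fallback when no trained model is available. Its
intrinsic limit is that a silhouette centroid is not the projection of a
3D center of mass for irregular shapes (about 1 mm RMS discrepancy on
strongly TPS-deformed samples, about 0.1 mm on rigid ellipsoids).

## Evaluation

DSC and HD95 are computed on the 2D projected masks and averaged over
the two views; both-empty masks score DSC = IoU = 1 (vacuous agreement),
and frames with an empty predicted view are excluded from boundary
metric means but count as tracking failures. HD95 extracts boundary
pixels by erosion and takes the 95th percentile (linear interpolation
between order statistics) of nearest-neighbour distances, symmetrized by
the max; it agrees with an all-pairs brute-force oracle exactly.
Per-axis RMS errors combine as `sqrt((e_LR^2 + e_AP^2 + e_SI^2)/3)`.
The tracking success rate is the percentage of frames with 3D centroid
error at most a threshold **and** nonempty predicted masks in both
views; the threshold is not externally specified, so the package
defaults to 2 mm (a clinically cited margin scale) and always reports
the threshold alongside the rate. Phase-binned reports group frames
into the five 20% respiratory bins.

The noise-robustness sweep corrupts every test DRR at S^2 in
{0, 5, 15, 25} (seeded per level/frame/view) and re-runs the full
cascade. The ablation harness compares the cascade against a regressor
trained directly on grayscale DRR pairs (z-score normalized) on
identical frames.

## The bundled desk-scale study

`RunConfig.tiny()` wires the stages together at CPU scale: 64-cube
phantom (seed-controlled), 9 registrations, 200 augmented samples split
184/8/8 (the 0.92/0.04/0.04 ratios of the full-scale recipe), orthogonal
128x128 DRRs, tiny segmentation (18 epochs, ~5 min) and regression
(150 epochs, ~1 min) trained on the noiseless training split, then
evaluation on the phantom's 10-phase trajectory plus the held-out
augmented split. Problem sizes were chosen so the whole study runs in
roughly 10-15 minutes on one CPU core. Stages cache to disk keyed by
config-subtree hashes, so re-running an identical configuration reuses
registration, augmentation and trained models.

Typical results (seeds 1 and 17): held-out DSC 0.93-0.94, noiseless
trajectory RMSE 0.37-0.43 mm, mean 3D error under S^2 = 25 noise
0.75-0.86 mm with a 100% tracking success rate at 2 mm at every noise
level. Predicted masks are cleaned at inference (holes filled, largest
connected component kept — the single-target assumption), which
stabilizes the mask centroid under noise without touching the
noise-free training protocol.

## What the phantom does and does not show

The phantom gives exact, analytic ground truth and spans the geometric
and learning machinery end to end, so passing tests establish that the
augmentation algebra, projector, networks, and metrics do what they
claim under controlled conditions. It does not contain real CT
appearance: no Hounsfield calibration, no scatter/beam hardening or
detector blur, no cardiac motion or breathing hysteresis
(inhale/exhale asymmetry), no inter-patient anatomical variation, and
its tumor is a deformed ellipsoid rather than a spiculated lesion.
Accuracy numbers on the phantom therefore demonstrate correctness and
internal consistency of the method at desk scale, not clinical
performance.

## Known limitations

* Orthogonal (90-degree) view pairs only; arbitrary-angle or rotational
  geometries are out of scope.
* Field mixing is additive, not compositional; no folding/Jacobian
  checks are performed on hybrid fields.
* The full-scale presets (224x224 networks, 7500 samples, 100/50
  epochs) are defined and constructible but impractical to train in
  pure numpy; they exist for architecture fidelity and forward-pass use.
* DICOM ingestion and oblique direction matrices are unsupported
  (axis-aligned NIfTI/NRRD only).
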