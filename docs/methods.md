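# Methods

`fluordepth` reproduces, end to end and purely in silico, a training and
evaluation pipeline for deep-learning fluorescence depth mapping with
spatial frequency domain imaging (SFDI): synthetic "iceberg" tumor shapes,
a diffusion-theory image simulator, lookup-table (LUT) optical-property
inversion, a two-arm convolutional network that regresses per-pixel tumor
depth and fluorophore concentration, and the error statistics used to
compare shape models.  This note records the model assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Coordinate and imaging conventions

The tissue surface is the plane z = 0 and z increases downward into the
tissue; "protruding above the surface" means z < 0.  The simulation lattice
is 101 x 101 pixels at 0.5 mm/pixel laterally (50.5 mm field of view) and
spans z = -5 mm to +15 mm at 0.5 mm, so both protruding patient-style
meshes and the 10 mm maximum training depth fit.  A voxel is occupied iff
its center lies inside the tumor surface.

Images are acquired at six spatial frequencies fx = 0, 0.05, 0.10, 0.15,
0.20, 0.25 mm^-1; optical properties are inverted from the reflectance
pair at fx = 0 and 0.2 mm^-1.

## Tumor shape families

* **Cylinders** — axis along z, top flush with the surface; width
  U(10, 40) mm, depth U(1, 10) mm.
* **Spherical harmonics (SH)** — a 10 mm sphere perturbed radially by one
  real spherical harmonic Y_lm with l in {2..20} and m uniform in
  {-l..l} (the degree/order prescription in the source description is
  internally inconsistent for l < 10, so the full admissible m range is
  used).  The harmonic is normalized to unit maximum so the amplitude,
  drawn U(0.1, 0.3), directly bounds the relative perturbation and keeps
  the radius positive.  The shape is scaled per axis to target widths and
  depth (solved from a dense surface point cloud restricted to the part
  below the surface) and cut at z = 0.
* **Composite spherical harmonics (CSH)** — four SH radial functions merged
  as curvilinear quadrants delimited by two reciprocal curves x*y = c1 > 0
  and x*y = c2 < 0 (|c| ~ U(4, 50) mm^2), blended with a cosine ramp over a
  2 mm transition band so the merged surface has no seam; weights sum to
  one, so four identical quadrants reduce exactly to the single SH.  The
  merged shape is rotated about X and Y by U(-30, 30) deg (keeps the tumor
  surface-facing), about Z by U(-180, 180) deg, shifted downward by
  U(0, 2) mm (creating buried top-surface regions), scaled per axis to the
  target ranges and cut.  Scale factors are verified against the voxelized
  result and refined if quantization pushed the measured width/depth
  outside the training ranges.

Spherical harmonics are evaluated from separably built lookup tables
(associated Legendre profile x trig profile, 361 x 721 nodes) with bilinear
interpolation; for the degrees used (l <= 20) the interpolation error is
below one percent of the unit-normalized harmonic, well under the 0.5 mm
voxel quantization.

**Depth rule (iceberg convention).**  Per column the tumor spans
[ztop, zbot] (outer voxel faces, internal gaps filled): depth =
zbot - min(ztop, 0).  For flush or buried tops this is the distance from
the surface plane to the bottom surface; for protruding tops (patient-mesh
mode only) it is the full apex-to-base thickness.  Concentration targets
equal the tumor concentration on the footprint and, in the
background-fluorescence variant, the background level elsewhere (matching
exactly what the forward model emits).

**Patient-mesh surrogates.**  The clinical tongue-tumor contours behind the
original study are not publicly available.  `synthetic_tumor_mesh` builds
watertight surrogates (perturbed, flattened icospheres that protrude
slightly above the surface) so the mesh augmentation, protrusion-preserving
voxelization and out-of-range handling are exercised by the same code paths
a real contour would take.  Results on surrogates characterize the
pipeline, not the clinical cohort.  Mesh voxelization uses vertical-ray
crossing parity computed directly against the triangles (axis-parallel
rays need no general ray-tracing backend).

## Forward optics

A homogeneous semi-infinite medium in the diffusion approximation with a
partial-current (extrapolated) boundary, refractive index n = 1.4
(effective reflection coefficient from the standard index-mismatch
polynomial).  Training optics: mu_a ~ U(0.0015, 0.015) mm^-1,
mu_s' ~ U(0.75, 2) mm^-1; test optics fixed at (0.0045, 1.0) mm^-1.

* **Reflectance** Rd(fx) = 3 A a' / ((mu_eff'/mu_tr + 1)(mu_eff'/mu_tr + 3A)),
  with mu_eff'(fx) = sqrt(mu_eff^2 + (2 pi fx)^2) and
  A = (1 - R_eff)/(2(1 + R_eff)).  Reflectance images are spatially flat
  before noise: optical properties are per-sample constants, and tumor
  optical contrast in reflectance is out of scope.
* **Excitation fluence** phi(z; fx): the 1-D modulated planar-source
  diffusion solution with the same boundary condition (removable
  singularity at mu_eff' = mu_tr handled analytically).
* **Emission escape** E(rho, z): dipole image-source kernel across the
  extrapolated boundary z_b = 2D(1 + R_eff)/(1 - R_eff), evaluated at the
  emission wavelength, which is taken equal to the excitation wavelength
  (single-property simplification; only relative fluorescence units are
  meaningful, and they cancel between simulation and training).
* **Fluorescence** — first-Born sum over tumor voxels
  F = eta * sum mu_af phi E dV with PpIX quantum efficiency eta = 0.046 and
  mu_af = epsilon_c * C (epsilon_c = 0.02 mm^-1 per ug/mL, a configurable
  units constant).  The escape kernel is fx-independent, so each depth
  slice costs one lateral FFT convolution shared by all six frequencies.
  The per-slice excitation weight is the 5-point Gauss average of phi over
  the slice, which makes the depth quadrature effectively exact (a midpoint
  sample would bias thin-slab values by a few percent at mu_tr = 2 mm^-1).
  The kernel is truncated where it falls below 1e-6 of its on-axis value.
  The background-fluorescence variant sets mu_af to bg_fraction * that
  value in all healthy-tissue voxels (z >= 0) inside the simulated volume.

Each closed form is validated against an independent numerical reference
(`fluordepth.reference`): a finite-difference two-point boundary-value
solve of the diffusion equation for phi and Rd, and adaptive quadrature for
the escape integral and the laterally-infinite-slab limit of the Born sum.
Agreement is below 0.5-1 % across the training property box; these checks
run in the test suite and in the acceptance script.

**Noise.**  "Poisson additive noise" is read as shot noise: each image is
scaled so its peak corresponds to the photon budget (default 1e4 expected
counts), Poisson-sampled, and rescaled.  Seeded runs are bit-reproducible.

## LUT inversion

A 200 x 200 tabulation of (mu_a, mu_s') -> (Rd0, Rd0.2) over a domain
slightly wider than the training box (0.001-0.02 / 0.6-2.4 mm^-1), so
shot-noise scatter still inverts without clamping.  Injectivity is verified
at build time: every node's nearest neighbour in measurement space must be
one of its grid neighbours (a fold would bring distant property pairs close
together).  Inversion is Delaunay-triangulated linear interpolation in
measurement space; points outside the convex hull are clamped to the
nearest tabulated node and flagged.  Forward-then-invert round-trips
recover both properties to well under 1 % (noiseless).

## Network and training

Two input arms: per-pixel optical properties (2 channels) and the
six-frequency fluorescence stack.  The property arm applies convolutions
2 -> 32 -> 112 and a residual block (two convolutions + skip); the
fluorescence arm applies one volumetric 3 x 3 x 6 convolution spanning the
whole frequency axis (after the reshape this is algebraically a 2-D
convolution over six channels; 32 filters), convolutions 32 -> 96 -> 112
and a residual block; the concatenated 224 channels pass through a
separable convolution (depthwise 3 x 3 + pointwise to 112) and a residual
block, then split into two reducing heads 112 -> 24 -> 16 -> 1.  All
convolutions are 3 x 3, stride 1, zero-padded, so every layer preserves
101 x 101; the committed schedule has exactly 920,514 trainable
parameters.  The figure-level filter counts of the original architecture
are not recoverable from text, so the schedule was chosen to satisfy the
architectural description and that parameter count exactly.

Hidden activations are leaky rectifiers (slope 0.1) and the final head
convolution is linear, with physical non-negativity enforced by a clamp at
prediction time: with hard rectifiers the heads can saturate into an
all-zero state early in training and never recover (observed reproducibly
on overfit probes at this scale); the leak keeps a gradient path open and
changes no parameter counts.

Layers, backpropagation and Adam are implemented directly on numpy
(float32, channels-last, nine-shift matmul convolutions); gradients are
verified against central finite differences.  The default recipe follows
the committed training protocol: Adam, initial learning rate 5e-5 with
x0.95 exponential decay per epoch, batch 16, at most 100 epochs, early
stopping on validation loss (patience 10, best-weight restore), 90/10
train/validation split, equally weighted MSE on depth/10 mm and
concentration/10 ug/mL (commensurate heads).  Inputs are normalized by the
training property ranges (min-max) and by the training set's 99th
percentile fluorescence value.

**CPU-scale runs.**  The full-scale recipe assumes ~1e4 samples and tens of
thousands of Adam steps on a GPU.  The packaged cylinder self-test
(`fluordepth.model.cylinder_selftest`) instead trains a narrow-width
variant of the same topology (~24,500 parameters) on 800 samples with
random 32-pixel square crops (the network is fully convolutional, so
crop-trained weights apply verbatim to full frames), batch 4, initial
learning rate 1.5e-3 with x0.985 decay, and 100 epochs (~20,000 Adam
steps).  Two variance-reduction steps stabilize the result: stochastic
weight averaging (the returned weights are the mean of all epoch-end
weights from epoch 60 on; single late checkpoints fluctuate noticeably in
held-out error) and flip-averaged prediction (the mean over the four
lateral mirror images, which is exact for the mirror-symmetric physics).
These problem sizes are package choices for desk-scale reproduction; they
trade final accuracy for tractability, and the error statistics they
produce should be read as upper bounds on what the full-scale recipe
achieves.  A direct physics fit (optimizing depth and concentration of a
known cylinder through the forward model) recovers depth to ~0.1 mm even
for 9-10 mm tumors, so residual network error at depth reflects training
maturity, not an information limit of the images.

## Evaluation

Per-sample error is the mean absolute per-pixel difference over the
ground-truth footprint (configurable: union-of-footprints or full image).
Cohorts report mean +/- sample SD (divisor n-1).  Paired model comparisons
use the two-sided Wilcoxon signed-rank test, exact for n < 25 (the original
analysis does not name its test; the signed-rank choice is robust to the
heavy-tailed error distributions seen here, and a paired t-test is
available behind a flag).

## Phantom preprocessing

Experimental images (0.1 mm/pixel) are center-cropped/padded to exactly
505 x 505: pad pixels are i.i.d. uniform on [mean - SD, mean + SD] of the
non-fluorescent background ("values within one standard deviation of the
mean" read as a randomized draw; a constant-mean fallback is provided),
seeded per channel group.  Box downsampling is the exact non-overlapping
5 x 5 block mean to 101 x 101 at 0.5 mm/pixel, applied uniformly to
reflectance, fluorescence and property-map channels.

## What the synthetic data does not capture

Monte-Carlo-accurate transport near sources and boundaries (diffusion
theory only), heterogeneous intratumoral fluorophore distributions,
infiltrative microscopic boundary features (finger-like protrusions, tumor
buds), tissue surface topography, instrument effects (filter leakage,
calibration error, electronic noise), and tumor-vs-background optical
contrast in reflectance.  Passing tests demonstrate internal consistency of
the simulator, inversion, and learning pipeline under these assumptions,
not clinical performance.

## Numerical choices and degenerate inputs

* LUT measurement-space interpolation is deterministic; out-of-hull pixels
  clamp to the nearest node with a flag rather than extrapolate.
* All-zero images pass through the noise model unchanged; an all-zero
  reflectance stack inverts to a fully flagged property map.
* A CSH whose transform pushes it entirely above the surface is redrawn
  (bounded retries) and an empty cut raises an explicit error.
* Non-star-convex columns after rotation use the filled span
  [min occupied z, max occupied z] for depth.
* Ray-parity mesh voxelization jitters query columns by 1e-7 mm to avoid
  rays passing exactly through mesh edges; odd crossing counts (grazing
  hits) drop the unpaired crossing.
* Seeds: every stochastic step (shape draws, optics draws, noise, weight
  init, batch shuffling, crop placement) flows from explicit
  `numpy.random.Generator` seeds; repeated runs are bit-identical.
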