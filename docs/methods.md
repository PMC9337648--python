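# Methods

`thyrus` simulates and analyses a thyroid volumetry observer study in which
each volunteer is measured two ways: conventionally, with 2D ultrasound
calipers and the clinical ellipsoid formula, and volumetrically, by
compounding tracked 2D ultrasound sweeps into a 3D volume, segmenting the
lobes with a convolutional network, and counting voxels.  Everything runs
on synthetic phantoms with analytically known volume, so accuracy and
observer agreement can be measured against exact ground truth.

## Lobe phantoms

A lobe is an implicit surface in its local frame: a superellipsoid with
semi-axes (a, b, c) (width/2, depth/2, length/2, mm) and exponent e,

ρ(u) = (|x'/a|ᵉ + |y/b|ᵉ + |z/c|ᵉ)^(1/e),  x' = x − bend·a·(z/c)²,

deformed by a quadratic bend of the long axis and by smooth radial bumps
added to the unit radius (Gaussian profiles on the direction sphere, radius
0.25–0.6, amplitude −0.10…0.12).  The surface is {ρ = 1 + Σ bumps}.  With
no bend/bumps and e = 2 this is exactly an ellipsoid, which anchors the
volume oracle: the fine-grid voxel count matches (4/3)π·abc to ~10⁻⁵
relative.

The stored `true_volume` is always a numerical voxelization at 0.1 mm pitch
(voxel-centre rule), not a formula, so bent/bumpy lobes carry exact truth
too.  Cohort sampling draws the total thyroid volume from a truncated
normal — mean 7.4 ml, SD 3.05 ml, bounds [2.8, 16.7] ml, the published
population moments — splits it 45–55% between lobes, samples shape ratios
around healthy proportions (length ≈ 2.2–3.2× width, depth ≈ width,
e ∈ [1.9, 2.4]), and similarity-scales the lobe to the target volume.
Caliper ground truth (maximal principal-axis extents) is computed by a
coarse interior scan refined by 1-D root finding on the implicit function,
accurate to ≪0.1 mm.

## Tracked sweeps and the appearance model

A sweep translates the probe superior→inferior at the observer's speed
with a slow sinusoidal hand wobble (defaults 0.8 mm, 1.5°).  Default
acquisition constants are the study hardware's: 89 fps video, 668×599 px
frames with 0.0753 × 0.0751 mm pixels, and tracker noise of 1.40 mm RMS in
position and 0.50° RMS in angle.  Pose noise is zero-mean Gaussian per
axis with SD RMS/√3, so the 3-D error norm has the specified RMS;
simulated at 10⁴ frames the empirical RMS reproduces both numbers within
Monte-Carlo error.  Desk-scale runs keep the physics and the 89 fps frame rate and coarsen
only the pixel grid (96×96 px at 0.35 mm); keeping the true frame rate
matters because neighbouring frames' independent tracker errors average
out during compounding.

Frames are planar resamplings of an appearance model with constant tissue
means: hypoechoic lobe interior (0.25), bright capsule rim (0.85, a
0.6 mm-thick inner shell obtained by subtracting a shrunken copy of the
phantom), mid-level background (0.45) with smooth random texture, mild
exponential depth attenuation (0.01/mm), and multiplicative Rayleigh
speckle (unit mean, lightly correlated).  This is deliberately the
cheapest model that makes segmentation non-trivial: no wave propagation,
shadowing, refraction, or anisotropy.  Images are rendered from the *true*
poses while the sweep records the *noisy* poses, so tracking error
corrupts 3D reconstruction exactly as in a real acquisition.  Ground-truth
per-frame masks (true plane–phantom intersections) ride along for
training and evaluation only.

What passing tests on this generator do and do not show: they validate the
geometry, reconstruction, learning and statistics machinery end to end
under realistic noise magnitudes, but say nothing about echo texture
realism, pathology (nodules, cysts), isthmus handling, or scanner-specific
image characteristics.

## Compounding

Forward splatting: each pixel deposits its intensity at its world position
into a voxel grid whose axes follow the mean frame orientation; a voxel's
value is the weight-normalized mean of its deposits (nearest-voxel kernel,
or a separable Gaussian applied to the deposit sums, which is the same
kernel-weighted mean with voxel-quantized weights).  The pipeline default
is an anisotropic Gaussian elongated along the sweep direction
(σ = 1.4 mm, nearest in-plane): successive frames observe the same
anatomy with independent tracker errors, so averaging ~10–20 frames per
voxel slab shrinks the effective pose error by ~√n while in-plane detail
is preserved.  Isotropic Gaussian kernels serve the grid-convergence
studies, where continuous weights avoid occupancy ties at binary
thresholds.  The weight
volume doubles as a coverage map; interior gaps (uncovered voxels inside
the morphological closing of the coverage) are filled by normalized
averaging over a (2r+1)³ window, r = 2 voxels by default.  Default
reconstruction spacing is 0.3 mm isotropic (≈4× the native pixel pitch);
pipeline desk runs use 0.4 mm.  On noise-free mask sweeps the compounded,
0.5-thresholded reconstruction recovers the analytic voxelization with
Dice > 0.99 and a volume error that falls as the grid is refined
(0.6 → 0.3 → 0.15 mm).

## Preprocessing

Volumes are reoriented so the slicing axis runs superior–inferior: signed
permutations of the direction matrix are applied exactly (bit-equal
values); anything else is resampled once, linearly, onto a world-aligned
grid at the same spacing.  The operation is idempotent.  Each axial slice
is then cropped to a square window about the volume's in-plane intensity
centroid and scaled to the network size (default 64×64 at desk scale; the
window defaults to a fixed 28 mm so a lobe fills a useful fraction of the
field of view).  The crop/zoom is recorded in an invertible geometry
object; predicted masks are restored to the source grid by nearest-
neighbour resampling through that geometry (round-trip Dice ≥ 0.98 on
smooth masks).  Slices are normalized per-slice to zero mean/unit variance
before entering the network.

## Segmentation network

The architecture is the QuickNAT-style 2-class encoder–decoder: four
encoder dense blocks (three available via config), a convolutional
bottleneck, four decoders, and a 1×1 softmax classifier.  Each dense block
is three BN→ReLU→conv layers (5×5, 5×5, 1×1) whose intermediate feature
maps are concatenated; each encoder feeds a 2×2 max-pooling whose argmax
indices drive the matching decoder's index unpooling, and skip connections
concatenate encoder features into the decoders.  Channel width is 16 at
desk scale (configurable).  Dropout 0.5 is applied to pooled encoder
outputs and the bottleneck — the rate is the study recipe's; the placement
(off the skip connections) is this package's choice.

The stack is implemented directly in NumPy (float32, channels-last) with
manual backpropagation; convolutions run as k² shifted-view GEMMs over a
zero-padded buffer, which avoids im2col gathers entirely.  Gradients are
verified against finite differences in the tests.

Loss = 1·(1 − soft-Dice over foreground) + 1·(edge-weighted pixel-wise
cross-entropy), ε = 10⁻⁶ smoothing; equal weights are the study recipe.
Edge weights are 1 + λ (λ = 2) within r = 2 px of the mask's morphological
gradient.  Augmentation: random vertical flips (p = 0.5) and elastic
deformations (smoothed-random-displacement, α = 10 px, σ = 4 px, p = 0.5),
identical field on image (linear) and mask (nearest).  Optimizer: Adam,
batch 4, at most 20 epochs with early stopping after 5 epochs without
validation-Dice improvement; training is deterministic given the seed, and
the best-validation weights (including batch-norm statistics) are restored.

**Learning rate.**  The full-scale recipe pairs lr = 10⁻⁵ with ~14,000
training slices × 20 epochs ≈ 7·10⁴ Adam steps.  Because Adam's update
magnitude is ≈ lr per step, the total optimizer displacement is lr ×
steps ≈ 0.7.  A desk-scale run has ~10³ steps, so the package's default
lr = 5·10⁻⁴ is chosen to preserve that displacement (0.7/10³ ≈ 6·10⁻⁴,
rounded down); at 10⁻⁵ a desk run provably cannot leave the
initialization region within 20 epochs.  The full-scale value remains a
single config field away.

## Volumetry

2D: volume = 0.48 · width · depth · length with extents in cm — the
clinical correction factor replacing the exact ellipsoid π/6 ≈ 0.524, so
the formula underestimates a perfect ellipsoid by exactly
0.48/(π/6) = 0.9167.  No isthmus term.  3D: foreground-voxel count ×
voxel volume.  Totals are plain sums of the two lobes (unrounded); the
phantom generator produces no isthmus by default, matching the lobe-wise
pipeline.

## Observer model and statistics

Three observer profiles emulate experience grades: multiplicative caliper
biases 1.00 / 0.98 / 1.10 (the last reproducing the least-experienced
reader's overestimation), lognormal caliper noise with 5–8% relative SD,
and sweep speeds 10–14 mm/s.  All randomness descends from one master
seed via tagged seed-splitting, so any single sweep or caliper read can
be regenerated in isolation.

Statistics use sample SDs (n−1) and α = 0.05 per test, uncorrected:

* intraobserver variability: per-volunteer CV% of the repeats (100·SD/mean),
  summarized mean ± SD across volunteers.  The originally cited
  intraobserver formula is not reprinted in the source study, so CV is the
  package's documented interpretation; table 1's 2D-vs-3D p-value uses a
  paired t-test on per-volunteer averaged repeat sets, equally an
  interpretation, and both are flagged as such here rather than asserted
  as the original computation.
* interobserver agreement: for each observer pair, Bland–Altman mean
  difference, sample SD, ±1.96·SD limits of agreement, and a two-sided
  paired t-test (first scan series per observer).
* reference comparison: each observer's first-series totals vs the
  analytic reference volume (the MRI stand-in), paired t-test; a
  zero-variance difference yields an explicit degenerate result.
* group split: partition by volunteers seen/unseen during network
  training, to expose segmentation bias.

Both `bland_altman` and `paired_t_test` are closed-form implementations
verified in the tests against independent references (scipy's
`ttest_rel`, direct formulas) to 10⁻⁹, and the paired t-test's simulated
null rejection rate is checked to be 5% within Monte-Carlo error.

## Problem sizes and numerical choices

Desk-scale defaults — 8–10 volunteers, 96×96 px frames at 0.35 mm,
0.4 mm voxels, 64×64 network slices, 16 slices per lobe for training —
are chosen so a full simulate→train→evaluate cycle runs in minutes on one
CPU core while leaving every algorithmic component identical to a
full-scale run.  Voxel-centre conventions and 0-based indices are used
for all grid↔world mappings; volumes convert mm³→ml in exactly one place.
Ties in 2×2 max-pooling resolve to the first maximum (argmax order);
binary masks threshold probabilities at 0.5 by argmax.  Degenerate inputs
(empty sweeps, empty splits, non-positive extents, zero-variance
differences) raise explicit errors or flagged results rather than
propagating NaNs.

## Known limitations

* The appearance model is piecewise-constant with speckle; no physical
  wave simulation, nodules, or cysts.  An isthmus bridge can be enabled
  (`CohortParams.isthmus`): it is rendered into the images but never into
  the lobe-wise ground-truth masks, matching the no-isthmus-correction
  convention; it is off by default.
* Compounding equivalence with the commercial software used in the
  original workflow is not claimed; the splatting algorithm is this
  package's own.
* The network is trained and evaluated on the same synthetic appearance
  family; transfer to real scanner images is out of scope.
* Single-view (axial) slicing only; no multi-view aggregation.
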