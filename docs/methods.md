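# Methods

This note documents the models, parameter choices and numerical decisions
behind `mediseg`, and what the synthetic experiments do and do not show.

## Problem setting

Anterior mediastinal lesions (thymoma, lymphoma and related masses) sit
between the two lungs, in front of the heart and great vessels. On CT
they show low contrast against adjacent soft tissue, irregular shape and
variable position, which makes direct voxel-wise segmentation hard. The
package's central design idea is to use the lungs — which are trivially
separable from tissue by an intensity threshold — as an anatomical
anchor: crop the CT to the lung bounding box, so the network's input is
dominated by the region that can actually contain the lesion, and the
scanner bed and outside air never reach the network.

## Lung segmentation

A chest CT is binarized at **−300 HU**: voxels strictly above the cutoff
are tissue (1), all others air (0). Voxels exactly at −300 HU are
assigned to the air side; the binarization rule is strict inequality, and
putting the boundary on the air side keeps the tissue mask conservative.
The air mask (inverted tissue mask) is decomposed into connected
components; components touching any face of the volume are removed —
this deletes the outside air and the air around the scanner-bed plate in
one step. Of the remaining *interior* air components, those smaller than
`min_component_voxels` (default 64) are treated as noise, and the largest
`keep_top_k` (default 2, the two lungs) are kept.

Connectivity is face-only (6-neighbourhood) by default: corner
connectivity can leak through one-voxel-thin chest walls and merge lung
air with outside air. Both schemes are supported and tested against
breadth-first-search flood-fill oracles.

One step of the classical recipe is ambiguous when read literally:
subtracting interior air from the tissue mask yields tissue, not lungs.
The implemented interpretation is *lungs = interior air* — the inverted
threshold mask minus its border-connected components, then size
filtering. This reproduces the intended output (a lung mask) and is the
only composition of the stated steps that does.

The crop is the tight bounding box of the lung mask, expanded by a
configurable per-axis margin (default 0) and clamped to the volume. The
affine is updated so retained voxels keep their world coordinates.

## Preprocessing

Cropped volumes are clamped into a truncation window (default
**[−1000, 400] HU**, covering air through soft tissue and excluding
metal/contrast extremes), resized to a fixed grid — trilinear for images,
nearest-neighbour for masks so they stay binary — and max–min normalized
to [0, 1]. Normalization happens after truncation, so the window defines
the effective dynamic range. Variable slice counts reach the target
depth by interpolation, not padding: padding would shift the anatomy's
relative position, which the cascade's coarse stage depends on. The crop
box and original shape are recorded in a JSON sidecar so predictions can
be mapped back to the original voxel grid.

All resampling in the package (preprocessing and in-network) uses one
separable implementation with per-axis interpolation matrices
(pixel-centre convention, no corner alignment). This guarantees exact
output shapes, bit-reproducibility, and — critical for training — an
exact adjoint for the backward pass. The small interpolation matrices
are cached per (input length, output length) pair.

## Network

Each stage is a 3D residual U-Net:

- **Residual block**: `out = shortcut(x) + F(x)` with
  `F = conv(3×3×3) → instance norm → ReLU → conv(3×3×3) → instance norm`;
  the shortcut is identity when channel counts match, else a 1×1×1
  projection.
- **Downsampling**: stride-2 3×3×3 convolution; every spatial dimension
  is exactly halved (odd dimensions are rejected with the axis named).
- **Upsampling**: trilinear doubling followed by a 1×1×1 projection.
- **Head**: 1×1×1 convolution to class logits at full input resolution,
  softmax over classes.
- **Attention gates** on each skip connection: the skip feature `x` is
  projected by a stride-2 1×1×1 convolution to an intermediate width
  (half of x's channels), summed with a 1×1×1 projection of the gating
  signal `g` (the decoder feature one level coarser), passed through
  ReLU, reduced to one channel, squashed by a sigmoid to coefficients
  α ∈ [0,1], trilinearly upsampled to x's grid, and applied as
  `x̂ = x · α`. Forcing α ≡ 1 makes the gated network identical to the
  ungated one with shared weights (a tested equivalence).

Normalization is per-channel instance norm (3D training uses batch
size 1, where batch statistics are meaningless). Activations are ReLU.
Weights are Kaiming fan-in initialized from a seeded generator, so two
models built with the same seed are bit-identical.

Default channel schedule: base 32, growth ×2, 4 levels (a standard U-Net
schedule); the scaled-down configurations used in tests and the
acceptance script use base 4 with 3 levels, which is enough capacity for
the phantom task while keeping CPU runtimes in minutes.

### Cascade

Stage 1 receives the input trilinearly downsampled by `coarse_factor`
(default 2) and produces a coarse probability map, which is upsampled
back to full resolution and renormalized onto the probability simplex
(trilinear interpolation preserves non-negativity but the per-voxel
clip at 1e−7 requires renormalization to keep sums exactly 1). The
bridged signal concatenated with the high-resolution image for stage 2
is this probability map (`bridge="probabilities"`, the default): it
makes stage 2's input width independent of backbone internals and keeps
the cascade differentiable end to end. Bridging argmax labels is
supported (`bridge="labels"`) but non-differentiable, so the bridge is
then treated as constant during backpropagation. The two stages share
every hyperparameter except input channels, enforced at construction.

## Training

Both stages are optimized jointly: the loss is the equal-weight sum of
the summed weighted cross-entropy of the stage-2 output against the
target and of the stage-1 coarse output against the target
nearest-neighbour-downsampled to the coarse grid. Gradients reach stage
1 both through its own term and through the bridged probabilities
(renormalization → trilinear adjoint → softmax Jacobian).

Defaults follow the standard protocol for this architecture: **Adam,
learning rate 1e−4, 300 epochs, batch size 1**, no augmentation, no
learning-rate schedule. Per-voxel weights `w(x)` in the cross-entropy
default to 1 for both classes; `TrainConfig.class_weights` exposes them
because the lesion occupies ~1% of the cropped volume and upweighting the
foreground class (the scaled-down experiments use weight 5) speeds up
learning on small targets considerably. Probabilities are clipped at
1e−7 before the logarithm.

Validation uses a seeded 80/20 shuffle split; datasets too small to
split validate on the training cases (which makes the single-case run a
pure memorization measurement). Checkpoints (best-by-validation-Dice
and final) are `.npz` archives embedding both configs; save → load →
predict is bit-identical.

The networks run on a self-contained numpy layer library with
hand-written backpropagation: 3D convolution as im2col matrix
multiplication (input gradients via the transposed convolution, i.e.
zero-dilation plus correlation with the flipped kernel), instance norm
with the standard normalization backward, and the resampling adjoints
described above. Every gradient path was verified against central finite
differences in float64 (worst relative deviation at the
finite-difference noise floor). Production arithmetic is float32;
probability/loss arithmetic is float64.

## Evaluation

The Dice coefficient uses the squared-denominator form
`D = 2Σpᵢgᵢ/(Σpᵢ²+Σgᵢ²)`, which equals the classical `2|A∩B|/(|A|+|B|)`
on binary inputs (tested on random pairs). The both-empty case (0/0) is
defined as 1: agreeing on emptiness is perfect agreement. Reported
evaluation Dice is computed on the argmax-binarized prediction mapped
back to the *original* voxel grid (nearest-neighbour resize into the
recorded crop box, pasted into a zero volume), and headline numbers are
means over per-case Dice values, with the per-case column reported
alongside.

## Synthetic phantoms

The phantom emulates exactly the features the pipeline's assumptions
touch: air background (−1000 HU), an elliptic-cylinder soft-tissue body
(+40 HU), two ellipsoidal lungs (−800 HU) strictly inside the body with
a tissue shell around them, a scanner-bed plate (+200 HU) below the body
and separated from it by air, and an ellipsoidal lesion (+45 HU) in the
inter-lung gap. Air and lung fall below −300 HU, tissue classes above
it, so the noiseless threshold image equals the generative tissue truth
exactly. The 5 HU lesion/body contrast is deliberately low (≈0.4% of
the default truncation window after normalization): localizing the
lesion requires context (the lung silhouettes), not a bright blob.
Noise is additive Gaussian (default SD 20 HU, typical of soft-tissue
CT noise), clipped to the 12-bit CT range [−1024, 3071]. Dataset
generation jitters the lesion centre (additive Gaussian, SD 0.02 of the
axis length) and semi-axes (SD 0.01), with rejection of placements that
violate the anatomy, and derives every per-sample seed from one root
seed.

What the phantom does **not** model: reconstruction kernels, beam
hardening, streak artifacts, anatomical shape variation of the
mediastinum, airways/trachea, or intensity inhomogeneity. Passing
phantom tests therefore demonstrates the pipeline's logic (thresholding,
morphology, geometry bookkeeping, optimization machinery) — not clinical
segmentation accuracy.

## Scaled-down experiment sizes

The learning experiments are sized for a single CPU:

- **Memorization**: one noise-free phantom (96×96×48), lung-cropped and
  preprocessed to 64×64×16; cascade base 4 / 3 levels; Adam at 1e−3 with
  class weights (1, 5); 200 iterations. Best training Dice reaches
  ≈0.96, crossing 0.95 around iteration 150. The learning rate is 1e−3
  rather than the 1e−4 default because a 200-iteration budget at 1e−4
  moves Adam-updated weights by at most ~0.02, too little to memorize;
  this is a property of the scaled-down budget, not of the architecture.
- **Lung-crop ablation**: 20 phantoms at 96×96×48 (4 train / 16 held
  out), preprocessed to a 16×16×8 network grid either with the lung crop
  or with a whole-volume crop, 80 epochs, 3 seeds. The network grid is
  chosen where the crop's mechanism — relatively enlarging the region of
  interest — is the dominant, well-resolved effect: pushing the *ground
  truth itself* through the geometry gives attainable mean Dice ≈0.76
  with the crop but only ≈0.52 without it (the uncropped lesion
  quantizes to a few voxels), and trained models land at ≈0.46–0.60 vs
  ≈0.33–0.47. The ordering (crop ≥ no crop) is stable per seed and on
  the mean across independent seed sets; the absolute values are far
  below clinical numbers, as expected from 4 training volumes and a
  4-channel network.

## Known limitations

- The lung segmenter assumes lungs are interior air components: it will
  fail on volumes where lungs touch the scan boundary (incomplete scan
  coverage) and does not separate airways from parenchyma.
- DICOM ingestion assumes an axial series with uniform slice spacing and
  does not handle gantry tilt or 4D series; DICOM writing is out of
  scope.
- The numpy execution substrate is single-threaded BLAS-bound; it is
  suitable for desk-scale experiments and testing, not for training at
  256×256×32 clinical resolution.
- Dice on probability inputs uses the squared-denominator form directly;
  it is an evaluation metric here, never a training loss.
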